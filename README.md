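# dqs — dynamical quorum sensing toolkit

Tools for analysing how populations of cells that communicate through a
shared, dissipative signal start to oscillate collectively. The package
covers the full chain from single-cell measurements to population-level
predictions:

* **`dqs.response_core`** — frequency-resolved response spectra with fixed
  phase conventions, Kramers–Krönig reconstruction, adaptation-error and
  kernel extraction from step responses, active (phase-leading) bands,
  cell-to-signal energy flux and fluctuation–dissipation (FDT) ratios.
* **`dqs.onset_solver`** — the phase-matching and gain conditions that fix
  the onset frequency and critical cell density; finite-amplitude
  (describing-function) frequency shifts; the maximum signal relaxation time
  compatible with oscillations; a one-call pipeline from a measured step
  response to a predicted oscillation period.
* **`dqs.circuits`** — Euler–Maruyama simulators for two single-cell models
  (a weakly nonlinear adaptive circuit and the excitable FitzHugh–Nagumo
  circuit) plus ensemble estimators (common random numbers) of their step
  and sine responses and correlation spectra.
* **`dqs.population`** — N circuits coupled through the signal field,
  oscillation detection, density sweeps, Hopf-exponent fits and the upper
  (oscillation-death) bifurcation.
* **`dqs.glycolysis_reduced`** — a condensed anaerobic-glycolysis cell with
  ATP and redox homeostasis, clamped-signal phase diagram, and a cell
  suspension coupled through a diffusible metabolite showing both the onset
  and the high-density quenching (inverse DQS) of collective oscillations.
* **`dqs.io_cli`** — CSV/JSON round-tripping, reproducible synthetic
  fixtures with ground-truth sidecars, and the `dqs` command line.

## Command line

```bash
dqs fixtures --kind adaptive_step --omega-star 1.0 --out step   # step.csv + step.json
dqs analyze-step --step step.csv --tau-s 0 --out onset.json     # period prediction
dqs respond --epsilon 0.1 --out spectrum.csv                    # analytic spectrum
dqs onset --spectrum spectrum.csv --tau-s 1 --alpha1 0.5 --alpha2 0.5
dqs simulate --model fhn --duration 300 --out traj.csv
dqs sweep --model cubic --nbar-min 1.2 --nbar-max 2.6 --steps 8 --out sweep
dqs glyco-sweep --d 0.4 --rho-min 0.5 --rho-max 1.0 --steps 6 --out glyco
```

Exit codes: 0 success, 2 configuration/usage error, 3 numerical failure.
Every run writes a JSON provenance record (parameters, seed, version).

## Library example

```python
import numpy as np
from dqs.circuits import CubicCircuitParams
from dqs.onset_solver import solve_onset
from dqs.response_core import SignalModel, analytic_cubic_response

params = CubicCircuitParams(epsilon=0.1, alpha2=0.5)
spectrum = analytic_cubic_response(params, np.geomspace(1e-4, 1.5, 4000))
onset = solve_onset(spectrum, SignalModel(gamma=1, K=1, alpha1=0.5),
                    alpha2=params.alpha2)
print(onset.omega_o, onset.Nbar_o, onset.period)
```

## Conventions

Spectra use the time factor `exp(-i*omega*t)`, so `R(omega) =
∫₀^∞ R(t) exp(+i*omega*t) dt` and the phase `phi = -arg R` is positive when
the response leads the stimulus. The over-damped medium has
`R_s = 1/(K - i*gamma*omega)` and always lags by less than a quarter turn.
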
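"""Reduced glycolytic circuit and the coupled cell-suspension model.

The single cell condenses anaerobic glycolysis into five reactions:

* ``v_upper`` — upper glycolysis: invests one ATP, reduces NAD to NADH and
  produces a triose-pool intermediate; Hill-inhibited by ATP (the negative
  feedback that drives the oscillation) and limited by available NAD;
* ``v_pyk``   — condensed lower branch (PYK): converts the intermediate and
  ADP into two ATP plus pyruvate;
* ``v_pdc``   — pyruvate decarboxylation to acetaldehyde (ACE), the
  extracellular signal; a saturable fraction of this flux feeds the
  diffusible ACE pool;
* ``v_adh``   — NADH re-oxidation driven by the ACE level (redox sensing);
* ``v_load``  — saturable ATP consumption by the rest of the cell.

Adenine (ATP+ADP) and pyridine (NAD+NADH) pools are conserved.  A small
basal ATP source keeps the starved state finite (avoids the ATP-investment
deadlock).  Intracellular ACE couples cells across the membrane at
permeability ``D``; the shared pool is degraded at rate ``k_ex`` and fed in
proportion to the cell volume fraction ``rho``.

Clamped at a fixed intracellular ACE level the circuit shows a single
oscillatory window with adaptive (homeostatic) response on both wings; the
adaptation error grows with distance from the window.  In suspension,
intermediate permeability produces a density band of oscillations that is
quenched again at an upper critical density (inverse dynamical quorum
sensing), while low permeability drives intracellular ACE far above the
window and suppresses oscillations at every density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

from .circuits import Trajectory
from .errors import InvalidModelError, NumericalError
from .response_core import ResponseSpectrum, SignalModel, StepResponse, adaptation_error

__all__ = [
    "GlycoParams",
    "SuspensionParams",
    "GlycoState",
    "STATE_NAMES",
    "RegimeCall",
    "GlycoSweep",
    "simulate_cell_clamped",
    "classify_regime",
    "simulate_suspension",
    "suspension_density_sweep",
    "cell_linear_response",
    "suspension_signal_model",
    "predicted_upper_quench",
]

STATE_NAMES = ("atp", "adp", "triose", "pyr", "nadh", "nad")


@dataclass(frozen=True)
class GlycoParams:
    """Rate constants and pool sizes of the condensed glycolytic circuit.

    ``feedback`` scales the ATP concentration inside the Hill inhibition
    term; 0 turns the homeostatic feedback off entirely.  ``ace_balance``
    selects the reading of the intracellular ACE budget: ``"synthesis"``
    (default) feeds a saturable fraction ``k_in`` of the PDC flux into the
    diffusible pool (ADH consumption is channelled), ``"degradation"``
    treats ``k_in`` as a first-order intracellular sink with the full PDC
    flux as source and stoichiometric ADH consumption.  The wording in the
    literature supports both; both are exposed.
    """

    k_upper: float = 40.42
    k_pyk: float = 26.58
    k_pdc: float = 9.72
    k_adh: float = 0.3
    k_load: float = 2.75
    K_I: float = 1.37
    Km_atp: float = 0.72
    Km_load: float = 0.13
    hill: int = 4
    basal: float = 0.002
    pdc_sat: float = 2.0
    k_in: float = 0.5
    feedback: float = 1.0
    adenine_total: float = 4.0
    nad_total: float = 2.0
    ace_balance: str = "synthesis"

    def __post_init__(self):
        rates = (self.k_upper, self.k_pyk, self.k_pdc, self.k_adh,
                 self.k_load, self.k_in, self.basal, self.pdc_sat)
        if any(r < 0 for r in rates):
            raise InvalidModelError("rate constants must be non-negative")
        if self.adenine_total <= 0 or self.nad_total <= 0:
            raise InvalidModelError("conserved pools must be positive")
        if self.ace_balance not in ("synthesis", "degradation"):
            raise InvalidModelError("ace_balance must be 'synthesis' or 'degradation'")


@dataclass(frozen=True)
class SuspensionParams:
    """Cell suspension: density, membrane permeability, medium clearance."""

    rho: float
    D: float
    k_ex: float = 0.3
    cell: GlycoParams = field(default_factory=GlycoParams)
    n_cells: int = 8
    jitter: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise InvalidModelError("rho must lie in [0, 1]")
        if self.D < 0 or self.k_ex < 0:
            raise InvalidModelError("D and k_ex must be non-negative")
        if self.n_cells < 1:
            raise InvalidModelError("n_cells must be at least 1")


@dataclass(frozen=True)
class GlycoState:
    """Named concentration vector of one cell (plus ACE levels)."""

    atp: float
    adp: float
    triose: float
    pyr: float
    nadh: float
    nad: float
    ace_in: float = 0.0
    ace_ex: float = 0.0


def _fluxes(atp, adp, triose, pyr, nadh, nad, ace, p: GlycoParams):
    inhibition = 1.0 + (p.feedback * atp / p.K_I) ** p.hill
    v_upper = p.k_upper * (atp / (p.Km_atp + atp)) * nad / inhibition
    v_pyk = p.k_pyk * triose * adp
    v_pdc = p.k_pdc * pyr
    v_adh = p.k_adh * ace * nadh
    v_load = p.k_load * atp / (p.Km_load + atp)
    return v_upper, v_pyk, v_pdc, v_adh, v_load


def _cell_rhs(y, ace, p: GlycoParams):
    """Time derivatives of the six metabolic states at a given ACE level."""
    atp, adp, triose, pyr, nadh, nad = y
    v1, v2, v3, v4, v5 = _fluxes(atp, adp, triose, pyr, nadh, nad, ace, p)
    d_atp = p.basal * adp / p.adenine_total - v1 + 2.0 * v2 - v5
    d_nadh = v1 - v4
    return np.array([d_atp, -d_atp, v1 - v2, v2 - v3, d_nadh, -d_nadh])


def _ace_production(y, ace_in, p: GlycoParams) -> float:
    v3 = p.k_pdc * y[3]
    if p.ace_balance == "synthesis":
        return p.k_in * v3 / (1.0 + v3 / p.pdc_sat)
    v4 = p.k_adh * ace_in * y[4]
    return v3 - v4 - p.k_in * ace_in


_Y0 = np.array([2.0, 2.0, 0.2, 0.2, 1.0, 1.0])


def _integrate(fun, t_span, y0, n_points: int, args=()):
    """Stiff-safe integration: LSODA with a BDF fallback."""
    t_eval = np.linspace(t_span[0], t_span[1], n_points)
    last = None
    for method in ("LSODA", "BDF"):
        sol = solve_ivp(fun, t_span, y0, args=args, method=method,
                        rtol=1e-8, atol=1e-11, t_eval=t_eval)
        if sol.success and sol.t[-1] >= t_span[1] * (1 - 1e-9):
            return sol
        last = sol
    raise NumericalError(
        f"integration failed at t={last.t[-1] if last.t.size else t_span[0]:.3f}; "
        f"state={last.y[:, -1] if last.y.size else y0}")


def _sustained_amplitude(t, x, frac_late=0.75, frac_mid=0.5):
    late = t > frac_late * t[-1]
    mid = (t > frac_mid * t[-1]) & ~late
    a_late = float(x[late].max() - x[late].min())
    a_mid = float(x[mid].max() - x[mid].min()) if mid.any() else 0.0
    return a_late, a_mid


def _is_limit_cycle(t, x, amp_tol=0.02) -> tuple[bool, float]:
    a_late, a_mid = _sustained_amplitude(t, x)
    return (a_late > amp_tol and a_late > 0.7 * a_mid), a_late


def simulate_cell_clamped(params: GlycoParams, ace_in0: float,
                          duration: float = 1500.0,
                          n_points: int = 4000) -> Trajectory:
    """Integrate one cell with the intracellular ACE level held fixed.

    The trajectory metadata records the attractor classification
    (``"limit_cycle"`` or ``"fixed_point"``) based on the sustained ATP
    oscillation amplitude over the trailing quarter of the run.
    """
    if ace_in0 < 0:
        raise InvalidModelError("ace_in0 must be non-negative")
    sol = _integrate(lambda t, y: _cell_rhs(y, ace_in0, params),
                     (0.0, duration), _Y0, n_points)
    osc, amp = _is_limit_cycle(sol.t, sol.y[0])
    data = {name: sol.y[i] for i, name in enumerate(STATE_NAMES)}
    return Trajectory(sol.t, data,
                      {"ace_in0": ace_in0, "params": params,
                       "attractor": "limit_cycle" if osc else "fixed_point",
                       "atp_amplitude": amp})


@dataclass(frozen=True)
class RegimeCall:
    """Dynamical regime of the clamped cell at one ACE level."""

    regime: str                    # oscillatory | adaptive | non-adaptive
    adaptation_ratio: float        # |plateau| / |peak| of the PYR step response
    epsilon_hat: float             # plateau per unit relative step
    peak: float


def classify_regime(params: GlycoParams, ace_in0: float,
                    step_factor: float = 1.2, duration: float = 1500.0,
                    adaptive_threshold: float = 0.7) -> RegimeCall:
    """Oscillatory / adaptive / non-adaptive classification at one ACE level.

    Outside the oscillatory window, a relative ACE step of ``step_factor``
    is applied from the settled fixed point and the pyruvate (signal sender)
    response is reduced to its plateau-to-peak ratio via the generic
    adaptation-error estimator.  Small ratios mean accurate homeostatic
    adaptation; the ratio grows with distance from the oscillatory window.
    """
    base = simulate_cell_clamped(params, ace_in0, duration=duration)
    if base.meta["attractor"] == "limit_cycle":
        return RegimeCall("oscillatory", math.nan, math.nan, math.nan)
    y0 = np.array([base.data[k][-1] for k in STATE_NAMES])
    sol = _integrate(lambda t, y: _cell_rhs(y, ace_in0 * step_factor, params),
                     (0.0, duration / 2), y0, 4000)
    dev = sol.y[3] - y0[3]
    step = StepResponse(sol.t, dev, step_size=ace_in0 * (step_factor - 1.0) or 1.0)
    peak = float(np.max(np.abs(dev)))
    try:
        eps_hat = adaptation_error(step)
    except Exception:
        eps_hat = float(np.mean(dev[-len(dev) // 5:])) / step.step_size
    plateau = abs(eps_hat * step.step_size)
    ratio = plateau / peak if peak > 0 else 1.0
    # an unresponsive (saturated) circuit is not adaptive, however small the
    # residual; require a minimal transient relative to the operating level
    responsive = peak > 0.02 * max(abs(y0[3]), 1e-6) * (step_factor - 1.0)
    regime = "adaptive" if (responsive and ratio < adaptive_threshold) \
        else "non-adaptive"
    return RegimeCall(regime, ratio, eps_hat, peak)


# ---------------------------------------------------------------------------
# Suspension
# ---------------------------------------------------------------------------

def _high_flux_state(params: GlycoParams, ace: float = 5.0) -> np.ndarray:
    """Settled cell state at a high clamped ACE level (fermenting branch)."""
    sol = _integrate(lambda t, y: _cell_rhs(y, ace, params),
                     (0.0, 2000.0), _Y0, 200)
    return sol.y[:, -1]


def _suspension_rhs(t, y, sp: SuspensionParams):
    p, n = sp.cell, sp.n_cells
    cells = y[:7 * n].reshape(n, 7)
    atp, adp, triose, pyr, nadh, nad, ace_in = cells.T
    ace_ex = y[-1]
    v1, v2, v3, v4, v5 = _fluxes(atp, adp, triose, pyr, nadh, nad, ace_in, p)
    d_atp = p.basal * adp / p.adenine_total - v1 + 2.0 * v2 - v5
    d_nadh = v1 - v4
    if p.ace_balance == "synthesis":
        prod = p.k_in * v3 / (1.0 + v3 / p.pdc_sat)
    else:
        prod = v3 - v4 - p.k_in * ace_in
    out = np.empty_like(y)
    dc = out[:7 * n].reshape(n, 7)
    dc[:, 0] = d_atp
    dc[:, 1] = -d_atp
    dc[:, 2] = v1 - v2
    dc[:, 3] = v2 - v3
    dc[:, 4] = d_nadh
    dc[:, 5] = -d_nadh
    dc[:, 6] = prod + sp.D * (ace_ex - ace_in)
    out[-1] = sp.rho * sp.D * float(np.mean(ace_in - ace_ex)) \
        - sp.k_ex * ace_ex
    return out


def simulate_suspension(sp: SuspensionParams, duration: float = 4000.0,
                        n_points: int = 6000) -> Trajectory:
    """Integrate ``n_cells`` identical cells coupled through extracellular ACE.

    Initial conditions start every cell on the high-flux (fermenting) branch
    with multiplicative jitter to break symmetry.  Records per-cell ATP,
    the population means, and the shared ACE level.
    """
    rng = np.random.default_rng(sp.seed)
    ref = np.concatenate([_high_flux_state(sp.cell), [2.0]])
    y0 = np.empty(7 * sp.n_cells + 1)
    for j in range(sp.n_cells):
        y0[7 * j:7 * j + 7] = ref * (1.0 + sp.jitter * rng.uniform(-1, 1, 7))
    y0[-1] = 1.0
    sol = _integrate(lambda t, y: _suspension_rhs(t, y, sp),
                     (0.0, duration), y0, n_points)
    data = {"ace_ex": sol.y[-1],
            "ace_in_mean": sol.y[6::7][:sp.n_cells].mean(axis=0),
            "atp_mean": sol.y[0::7][:sp.n_cells].mean(axis=0)}
    for j in range(min(sp.n_cells, 4)):
        data[f"atp_{j}"] = sol.y[7 * j]
        data[f"ace_in_{j}"] = sol.y[7 * j + 6]
    return Trajectory(sol.t, data, {"sp": sp})


@dataclass(frozen=True)
class GlycoSweep:
    """Per-density records of a suspension sweep."""

    rho: np.ndarray
    cell_amplitude: np.ndarray     # mean per-cell ATP oscillation amplitude
    signal_amplitude: np.ndarray   # extracellular ACE amplitude
    ace_in_mean: np.ndarray
    ace_ex_mean: np.ndarray
    oscillatory: np.ndarray

    @property
    def lower_onset(self) -> float | None:
        osc = self.oscillatory
        if not osc.any() or osc[0]:
            return None
        i = int(np.argmax(osc))
        return 0.5 * (self.rho[i - 1] + self.rho[i])

    @property
    def upper_quench(self) -> float | None:
        osc = self.oscillatory
        if not osc.any() or osc[-1]:
            return None
        last = np.where(osc)[0][-1]
        return 0.5 * (self.rho[last] + self.rho[last + 1])


def suspension_density_sweep(sp_template: SuspensionParams, rho_grid,
                             duration: float = 4000.0,
                             amp_tol: float = 0.02) -> GlycoSweep:
    """Simulate the suspension over an increasing density grid.

    A grid point is oscillatory when the mean per-cell ATP amplitude over
    the trailing quarter of the run exceeds ``amp_tol`` and is sustained.
    Reports the lower onset and, when present, the upper quenching density
    (inverse dynamical quorum sensing), plus the time-averaged
    intra/extracellular ACE levels.
    """
    rho_grid = np.asarray(rho_grid, dtype=float)
    if np.any(np.diff(rho_grid) <= 0):
        raise InvalidModelError("rho grid must be strictly increasing")
    n = rho_grid.size
    cell_amp = np.empty(n)
    sig_amp = np.empty(n)
    ci = np.empty(n)
    ce = np.empty(n)
    osc = np.zeros(n, dtype=bool)
    for i, rho in enumerate(rho_grid):
        sp = replace(sp_template, rho=float(rho))
        traj = simulate_suspension(sp, duration=duration)
        t = traj.time
        late = t > 0.75 * t[-1]
        amps = []
        for j in range(min(sp.n_cells, 4)):
            x = traj.data[f"atp_{j}"]
            a_late, a_mid = _sustained_amplitude(t, x)
            amps.append(a_late if a_late > 0.7 * a_mid else 0.0)
        cell_amp[i] = float(np.mean(amps))
        sig = traj.data["ace_ex"]
        sig_amp[i] = float(sig[late].max() - sig[late].min())
        ci[i] = float(traj.data["ace_in_mean"][late].mean())
        ce[i] = float(sig[late].mean())
        osc[i] = cell_amp[i] > amp_tol
    return GlycoSweep(rho_grid, cell_amp, sig_amp, ci, ce, osc)


# ---------------------------------------------------------------------------
# Density-dependent linear response and the quench prediction
# ---------------------------------------------------------------------------

def _reduced_cell_rhs(y5: np.ndarray, ace_ex: float, D: float,
                      p: GlycoParams) -> np.ndarray:
    """Cell dynamics with conserved pools eliminated.

    State (atp, triose, pyr, nadh, ace_in); adp and nad follow from the
    pool totals.  Eliminating the conserved directions keeps the Jacobian
    non-singular, so fixed-point continuation and stability analysis are
    well conditioned.
    """
    atp, tri, pyr, nadh, ace = y5
    y = np.array([atp, p.adenine_total - atp, tri, pyr, nadh,
                  p.nad_total - nadh])
    d = _cell_rhs(y, ace, p)
    d_ace = _ace_production(y, ace, p) + D * (ace_ex - ace)
    return np.array([d[0], d[2], d[3], d[4], d_ace])


def _operating_point(sp: SuspensionParams) -> np.ndarray | None:
    """Fermenting fixed point (atp, triose, pyr, nadh, ace_in, ace_ex).

    Newton solves from a family of seeds spanning the ACE axis; among the
    converged non-negative roots the one with the highest intracellular ACE
    (the fermenting branch) is returned.  May be dynamically unstable —
    that is exactly what the onset analysis needs.
    """
    p = sp.cell

    def full(z):
        y5, ace_ex = z[:5], z[5]
        d5 = _reduced_cell_rhs(y5, ace_ex, sp.D, p)
        d_ex = sp.rho * sp.D * (y5[4] - ace_ex) - sp.k_ex * ace_ex
        return np.concatenate([d5, [d_ex]])

    best = None
    for ace0 in (0.05, 0.3, 0.6, 1.0, 1.5, 2.0, 3.0, 5.0):
        ex0 = sp.rho * sp.D * ace0 / (sp.rho * sp.D + sp.k_ex)
        z0 = np.array([1.5, 0.05, 0.25, 1.7, ace0, ex0])
        root, _, ier, _ = fsolve(full, z0, full_output=True)
        if ier != 1 or np.any(~np.isfinite(root)) or np.any(root < -1e-6):
            continue
        if np.max(np.abs(full(root))) > 1e-8:
            continue
        if best is None or root[4] > best[4]:
            best = root
    return best


def cell_linear_response(params: GlycoParams, ace_ex: float, D: float,
                         omega, y_cell: np.ndarray | None = None) -> ResponseSpectrum:
    """Frequency-resolved response of intracellular ACE to the shared signal.

    Linearises the reduced cell (metabolism plus its free ACE pool with
    membrane exchange at permeability ``D``) around the operating point for
    the given extracellular ACE level and evaluates
    ``R(omega) = e_ace^T (-i*omega*I - J)^{-1} b`` with ``b`` the forcing
    through the membrane term.  The Jacobian is taken by central finite
    differences; its leading eigenvalue (``meta["max_real_eig"]``) flags
    whether the operating point sits inside the cell's own instability.
    """
    if y_cell is None:
        sol = _integrate(lambda t, y: _reduced_cell_rhs(y, ace_ex, D, params),
                         (0.0, 6000.0), np.array([2.0, 0.2, 0.2, 1.0, ace_ex]),
                         100)
        y_cell = fsolve(lambda y: _reduced_cell_rhs(y, ace_ex, D, params),
                        sol.y[:, -1])
    y_cell = np.asarray(y_cell, dtype=float)[:5]
    n = 5
    J = np.empty((n, n))
    for k in range(n):
        h = 1e-7 * max(abs(y_cell[k]), 1.0)
        yp, ym = y_cell.copy(), y_cell.copy()
        yp[k] += h
        ym[k] -= h
        J[:, k] = (_reduced_cell_rhs(yp, ace_ex, D, params)
                   - _reduced_cell_rhs(ym, ace_ex, D, params)) / (2 * h)
    b = np.zeros(n)
    b[4] = D
    om = np.asarray(omega, dtype=float)
    vals = np.empty(om.size, dtype=complex)
    eye = np.eye(n)
    for i, w in enumerate(om):
        vals[i] = np.linalg.solve(-1j * w * eye - J, b)[4]
    max_eig = float(np.max(np.linalg.eigvals(J).real))
    return ResponseSpectrum(om, vals, meta={"ace_ex": ace_ex, "D": D,
                                            "max_real_eig": max_eig})


def suspension_signal_model(sp: SuspensionParams) -> SignalModel:
    """Medium response of the shared ACE pool at density rho.

    ``d(ace_ex)/dt = -(rho*D + k_ex)*ace_ex + rho*D*mean(ace_in)``, i.e. an
    over-damped mode with stiffness ``rho*D + k_ex`` and per-population
    forcing ``rho*D`` (cell count absorbed into the density weight).
    """
    return SignalModel(gamma=1.0, K=sp.rho * sp.D + sp.k_ex,
                       alpha1=sp.rho * sp.D)


def predicted_upper_quench(sp_template: SuspensionParams, rho_grid,
                           omega=None) -> float | None:
    """Quenching density predicted from density-dependent response functions.

    For each density the cell response is linearised around the
    density-dependent operating point and combined with the medium response.
    The oscillatory state survives when either (a) the cell response
    diverges — the operating point is on the unstable side of the internal
    Hopf bifurcation, the dominant effect when ACE accumulation carries the
    cell out of its oscillatory window — or (b) a phase-matched frequency
    exists with coupling gain >= 1 (adaptation-driven relay through the
    shared pool).  The predicted quench is the midpoint between the last
    density satisfying either condition and the first that satisfies
    neither.
    """
    from .onset_solver import phase_matching

    rho_grid = np.asarray(rho_grid, dtype=float)
    if omega is None:
        omega = np.geomspace(1e-3, 30.0, 800)
    ok = np.zeros(rho_grid.size, dtype=bool)
    for i, rho in enumerate(rho_grid):
        sp = replace(sp_template, rho=float(rho))
        z = _operating_point(sp)
        if z is None:
            continue
        spec = cell_linear_response(sp.cell, z[5], sp.D, omega,
                                    y_cell=z[:5])
        sig = suspension_signal_model(sp)
        if spec.meta["max_real_eig"] > 1e-9:
            ok[i] = True
            continue
        for w in phase_matching(spec, sig):
            rs = 1.0 / (sig.K - 1j * sig.gamma * w)
            if sig.alpha1 * abs(spec.interp(w) * rs) >= 1.0:
                ok[i] = True
                break
    if not ok.any() or ok[-1]:
        return None
    last = np.where(ok)[0][-1]
    return 0.5 * (rho_grid[last] + rho_grid[last + 1])
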
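"""Self-consistency conditions for the onset of collective oscillations.

At the onset, the coupled system first admits a non-decaying oscillatory mode
when ``N * alpha1 * R_a(omega) * R_s(omega) = 1``.  Split into phase and
gain, the onset frequency solves the phase-matching condition
``phi_a(omega) = -phi_s(omega)`` (the cell's lead cancels the medium's lag)
and the critical cell count follows from the gain condition
``|R_a * R_s| = 1/(alpha1 * N_o)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import DivergentDensityError, InvalidModelError
from .response_core import (
    ResponseSpectrum,
    SignalModel,
    StepResponse,
    adaptation_error,
    analytic_cubic_response,
    kernel_to_spectrum,
    omega_star,
    step_to_response_kernel,
)

__all__ = [
    "OnsetResult",
    "RenormalisedSpectrum",
    "StepOnsetReport",
    "phase_matching",
    "onset_density",
    "solve_onset",
    "onset_from_step",
    "renormalised_response",
    "renormalised_matching",
    "max_signal_time",
]


@dataclass(frozen=True)
class OnsetResult:
    """Onset frequency and critical density with solver diagnostics."""

    omega_o: float
    Nbar_o: float
    N_o: float
    root_multiplicity: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def period(self) -> float:
        """Oscillation period 2*pi/omega_o at onset."""
        return 2.0 * math.pi / self.omega_o


@dataclass(frozen=True)
class RenormalisedSpectrum:
    """Finite-amplitude (first-harmonic) response of the cubic circuit."""

    amplitude: float
    spectrum: ResponseSpectrum


def _phase_mismatch(activity: ResponseSpectrum, tau_s: float):
    """Callable g(omega) = phi_a + phi_s on the interpolated spectrum."""

    def g(w):
        return -np.angle(activity.interp(w)) - np.arctan(w * tau_s)

    return g


def phase_matching(activity: ResponseSpectrum, signal: SignalModel,
                   refine_tol: float = 1e-8) -> list[float]:
    """All frequencies where the cell's phase lead cancels the medium's lag.

    Sign changes of ``phi_a(omega) + phi_s(omega)`` between grid nodes are
    refined by bisection on the interpolated spectrum.  ``omega = 0`` is
    never reported (static instability is excluded); an empty list is the
    no-onset outcome, distinct from solver failure (which raises).
    """
    g = _phase_mismatch(activity, signal.tau_s)
    om = activity.omega
    gi = g(om)
    roots: list[float] = []
    for i in range(om.size - 1):
        g0, g1 = gi[i], gi[i + 1]
        if g0 * g1 < 0 and max(abs(g0), abs(g1)) > 1e-12:
            root = brentq(g, om[i], om[i + 1],
                          xtol=refine_tol * om[i], rtol=4 * np.finfo(float).eps)
            roots.append(float(root))
    return roots


def onset_density(activity: ResponseSpectrum, signal: SignalModel,
                  omega_o: float, alpha2: float) -> tuple[float, float]:
    """Critical coupling and cell count at a phase-matched frequency.

    ``N_o = 1/(alpha1 * |R_a(omega_o) * R_s(omega_o)|)``;
    ``Nbar_o = N_o * alpha1 * alpha2``.
    """
    ra = activity.interp(omega_o)
    rs = 1.0 / (signal.K - 1j * signal.gamma * omega_o)
    gain = abs(ra * rs)
    if gain == 0:
        raise DivergentDensityError("|R_a R_s| = 0: no finite onset density")
    n_o = 1.0 / (signal.alpha1 * gain)
    return n_o * signal.alpha1 * alpha2, n_o


def solve_onset(activity: ResponseSpectrum, signal: SignalModel,
                alpha2: float = 1.0,
                refine_tol: float = 1e-8) -> OnsetResult | None:
    """Full onset solution: phase matching plus the gain condition.

    When several phase-matched frequencies exist, the one with the smallest
    critical cell count is designated as the onset (first instability on
    increasing density).  Returns None when no phase-matched frequency
    exists (no-onset outcome).
    """
    roots = phase_matching(activity, signal, refine_tol=refine_tol)
    if not roots:
        return None
    best = None
    for w in roots:
        nbar_o, n_o = onset_density(activity, signal, w, alpha2)
        if best is None or n_o < best[2]:
            best = (w, nbar_o, n_o)
    w, nbar_o, n_o = best
    ra = activity.interp(w)
    rs = 1.0 / (signal.K - 1j * signal.gamma * w)
    residual = abs(n_o * signal.alpha1 * ra * rs - 1.0)
    return OnsetResult(
        omega_o=w, Nbar_o=nbar_o, N_o=n_o, root_multiplicity=len(roots),
        diagnostics={"all_roots": roots, "residual": residual,
                     "tau_s": signal.tau_s})


@dataclass(frozen=True)
class StepOnsetReport:
    """Pipeline output: step record -> kernel -> spectrum -> onset."""

    onset: OnsetResult | None
    period: float | None
    spectrum: ResponseSpectrum
    epsilon_hat: float
    adaptation_ok: bool


def onset_from_step(step: StepResponse, signal: SignalModel,
                    alpha2: float = 1.0, smoothing_window: int = 5,
                    polyorder: int = 2,
                    omega: np.ndarray | None = None) -> StepOnsetReport:
    """Predict onset frequency/density/period from a measured step response.

    Composes kernel extraction (smoothed differentiation), the finite-window
    Fourier transform and the two onset conditions.  The reported period is
    in the time units of the step record.  ``epsilon_hat`` is the kernel
    integral (zero-frequency response); ``adaptation_ok`` flags whether it is
    small (< 50%) relative to the peak spectral amplitude.
    """
    kernel = step_to_response_kernel(step, window=smoothing_window,
                                     polyorder=polyorder)
    if omega is None:
        t_end = step.time[-1]
        w_max = math.pi / (10.0 * step.dt)
        w_min = max(2.0 * math.pi / t_end, 1e-6 * w_max)
        omega = np.geomspace(w_min, w_max, 3000)
    spectrum = kernel_to_spectrum(kernel, omega)
    eps_hat = kernel.integral()
    peak = float(np.max(spectrum.amplitude))
    adaptation_ok = abs(eps_hat) < 0.5 * peak
    onset = solve_onset(spectrum, signal, alpha2=alpha2)
    period = onset.period if onset is not None else None
    return StepOnsetReport(onset=onset, period=period, spectrum=spectrum,
                           epsilon_hat=eps_hat, adaptation_ok=adaptation_ok)


def renormalised_response(params, A: float, omega) -> RenormalisedSpectrum:
    """First-harmonic (describing-function) response at oscillation amplitude A.

    For an activity oscillating with amplitude ``A`` the cubic term acts, to
    first harmonic, as an extra linear stiffness: the unit coefficient of the
    activity decay becomes ``1 + (3/4)*c3*A^2``.  ``A = 0`` reduces exactly
    to the linear spectrum.  This is an approximation; it is flagged in the
    spectrum metadata.
    """
    if A < 0:
        raise InvalidModelError("amplitude must be non-negative")
    kappa = 1.0 + 0.75 * params.c3 * A ** 2
    spec = analytic_cubic_response(params, omega, linear_coeff=kappa)
    spec.meta["approximation"] = "first-harmonic balance"
    spec.meta["amplitude"] = A
    return RenormalisedSpectrum(amplitude=A, spectrum=spec)


def renormalised_matching(params, A: float, signal: SignalModel,
                          n_grid: int = 4000) -> float | None:
    """Predicted oscillation frequency at finite amplitude A.

    Crossing of the renormalised cell phase with the (unrenormalised) medium
    phase lag; the medium stays linear so its phase is amplitude independent.
    """
    w_star = omega_star(params)
    om = np.geomspace(w_star * 1e-4, w_star * 1.2, n_grid)
    spec = renormalised_response(params, A, om).spectrum
    roots = phase_matching(spec, signal)
    return max(roots) if roots else None


def max_signal_time(params, rel_tol: float = 1e-4, n_grid: int = 4000) -> float:
    """Largest signal relaxation time still allowing phase matching.

    Found by bisection on ``tau_s``.  For zero adaptation error the phase
    lead approaches pi/2 at low frequency and matching is always possible:
    returns ``inf``.
    """
    if params.epsilon == 0:
        return math.inf
    w_star = omega_star(params)
    om = np.geomspace(w_star * 1e-5, w_star * 1.2, n_grid)
    spec = analytic_cubic_response(params, om)
    phi_a = spec.phase

    def has_root(tau_s: float) -> bool:
        return bool(np.any(phi_a - np.arctan(om * tau_s) > 1e-12))

    lo = 0.0
    hi = max(params.tau_y, params.tau_a)
    while has_root(hi):
        lo = hi
        hi *= 2.0
        if hi > 1e12:
            return math.inf
    while (hi - lo) > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if has_root(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
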
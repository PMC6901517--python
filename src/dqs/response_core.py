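"""Frequency-resolved response functions and their thermodynamic properties.

Conventions
-----------
All spectra in this package use the time factor ``exp(-i*omega*t)``, so the
one-sided Fourier transform of a causal kernel is ``R(omega) = integral_0^inf
R(t) exp(+i*omega*t) dt``.  The phase shift is defined as
``phi = -arg(R(omega))``: the response to a stimulus ``cos(omega*t)`` is
``|R| * cos(omega*t + phi)``, so ``phi > 0`` means the response *leads* the
stimulus and ``phi < 0`` means it lags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter, welch

from .errors import (
    InsufficientDataError,
    InvalidModelError,
    NoActiveBandError,
    NonStationaryError,
)

CONVENTION = "x(t)~exp(-i*w*t); R(w)=int_0^inf R(t)exp(+i*w*t)dt; phi=-arg(R)"

__all__ = [
    "CONVENTION",
    "ResponseSpectrum",
    "StepResponse",
    "SignalModel",
    "CorrelationSpectrum",
    "ResponseKernel",
    "KKResult",
    "signal_response",
    "analytic_cubic_response",
    "omega_star",
    "quality_factor",
    "phase_of",
    "kramers_kronig",
    "adaptation_error",
    "step_to_response_kernel",
    "kernel_to_spectrum",
    "active_band",
    "energy_flux",
    "fdt_ratio",
    "power_spectrum",
]


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InvalidModelError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class ResponseSpectrum:
    """Complex linear response evaluated on a positive frequency grid.

    Parameters
    ----------
    omega : ndarray
        Angular frequencies (rad per unit time), strictly increasing, > 0.
    value : ndarray of complex
        Response at each frequency (activity per unit signal).
    convention_tag : str
        Identifier of the Fourier/phase convention; fixed across the package.
    meta : dict
        Free-form provenance (estimator warnings, truncation errors, ...).
    """

    omega: np.ndarray
    value: np.ndarray
    convention_tag: str = CONVENTION
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        omega = _as_float_array(self.omega, "omega")
        value = np.asarray(self.value, dtype=complex)
        if value.shape != omega.shape:
            raise InvalidModelError("omega and value must have matching shapes")
        if omega.size and (np.any(omega <= 0) or np.any(np.diff(omega) <= 0)):
            raise InvalidModelError("omega must be strictly increasing and positive")
        object.__setattr__(self, "omega", omega)
        object.__setattr__(self, "value", value)

    @property
    def amplitude(self) -> np.ndarray:
        """|R(omega)| >= 0."""
        return np.abs(self.value)

    @property
    def phase(self) -> np.ndarray:
        """phi(omega) = -arg(R); positive phase = lead."""
        return -np.angle(self.value)

    @property
    def real(self) -> np.ndarray:
        return self.value.real

    @property
    def imag(self) -> np.ndarray:
        return self.value.imag

    def interp(self, omega):
        """Linear interpolation of the complex response at ``omega``."""
        om = np.asarray(omega, dtype=float)
        re = np.interp(om, self.omega, self.value.real)
        im = np.interp(om, self.omega, self.value.imag)
        return re + 1j * im


@dataclass(frozen=True)
class StepResponse:
    """Noise-averaged activity after a step stimulus, baseline subtracted.

    ``time`` starts at 0 (step onset) on a uniform grid; ``activity`` is the
    ensemble-averaged activity minus the pre-stimulus stationary mean.
    """

    time: np.ndarray
    activity: np.ndarray
    step_size: float = 1.0
    stderr: np.ndarray | None = None

    def __post_init__(self):
        time = _as_float_array(self.time, "time")
        activity = _as_float_array(self.activity, "activity")
        if time.shape != activity.shape:
            raise InvalidModelError("time and activity must have matching shapes")
        if time.size < 2:
            raise InsufficientDataError("step response needs at least 2 samples")
        if abs(time[0]) > 1e-12:
            raise InvalidModelError("time grid must start at 0")
        dt = np.diff(time)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise InvalidModelError("time grid must be uniform and increasing")
        if self.step_size == 0:
            raise InvalidModelError("step_size must be nonzero")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "activity", activity)
        if self.stderr is not None:
            se = _as_float_array(self.stderr, "stderr")
            if se.shape != time.shape:
                raise InvalidModelError("stderr must match the time grid")
            object.__setattr__(self, "stderr", se)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass(frozen=True)
class SignalModel:
    """Over-damped medium: gamma*ds/dt = -K*s + alpha1*sum_j a_j + noise.

    ``tau_s = gamma/K`` is the signal relaxation time.  ``T_s`` is the noise
    strength of the medium (0 for a noise-free signal field).
    """

    gamma: float
    K: float
    alpha1: float = 1.0
    T_s: float = 0.0

    def __post_init__(self):
        if self.gamma <= 0 or self.K <= 0:
            raise InvalidModelError("gamma and K must be positive")
        if self.alpha1 <= 0:
            raise InvalidModelError("alpha1 must be positive")
        if self.T_s < 0:
            raise InvalidModelError("T_s must be non-negative")

    @property
    def tau_s(self) -> float:
        return self.gamma / self.K

    @classmethod
    def from_tau_s(cls, tau_s: float, K: float = 1.0, alpha1: float = 1.0,
                   T_s: float = 0.0) -> "SignalModel":
        """Build a model with a prescribed relaxation time (gamma = tau_s*K).

        ``tau_s = 0`` is mapped to a numerically negligible relaxation time
        (1e-12) to represent the fast-clearance limit while keeping gamma > 0.
        """
        if tau_s < 0:
            raise InvalidModelError("tau_s must be non-negative")
        tau = max(tau_s, 1e-12)
        return cls(gamma=tau * K, K=K, alpha1=alpha1, T_s=T_s)


@dataclass(frozen=True)
class CorrelationSpectrum:
    """One-sided power spectral density on a positive frequency grid.

    Normalised so that for an equilibrium (passive) variable the
    fluctuation-dissipation identity reads ``2*T*imag(R) = omega * C``.
    """

    omega: np.ndarray
    value: np.ndarray

    def __post_init__(self):
        omega = _as_float_array(self.omega, "omega")
        value = _as_float_array(self.value, "value")
        if value.shape != omega.shape:
            raise InvalidModelError("omega and value must have matching shapes")
        if np.any(value < 0):
            raise InvalidModelError("spectral density must be non-negative")
        object.__setattr__(self, "omega", omega)
        object.__setattr__(self, "value", value)


@dataclass(frozen=True)
class ResponseKernel:
    """Causal time-domain response kernel R(t), t >= 0."""

    time: np.ndarray
    value: np.ndarray

    def __post_init__(self):
        time = _as_float_array(self.time, "time")
        value = _as_float_array(self.value, "value")
        if time.shape != value.shape:
            raise InvalidModelError("time and value must have matching shapes")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "value", value)

    def integral(self) -> float:
        """Zero-frequency (real) response: integral of the kernel."""
        return float(np.trapezoid(self.value, self.time))


# ---------------------------------------------------------------------------
# Analytic spectra
# ---------------------------------------------------------------------------

def signal_response(model: SignalModel, omega) -> ResponseSpectrum:
    """Medium response 1/(K - i*gamma*omega).

    The phase ``-arctan(omega*tau_s)`` lies in (-pi/2, 0) for every
    omega > 0: an over-damped medium always lags.
    """
    om = _as_float_array(omega, "omega")
    value = 1.0 / (model.K - 1j * model.gamma * om)
    return ResponseSpectrum(om, value)


def analytic_cubic_response(params, omega, linear_coeff: float = 1.0) -> ResponseSpectrum:
    """Linear response of the two-node adaptive circuit with weak cubic term.

    Obtained by linearising ``tau_a*da/dt = -a - c3*a^3 + y + alpha2*s`` and
    ``tau_y*dy/dt = -a - eps*y`` around the quiescent state:

        R(omega) = alpha2 / (kappa - i*omega*tau_a + 1/(eps - i*omega*tau_y))

    with ``kappa = 1`` for the bare circuit.  ``linear_coeff`` allows a
    renormalised coefficient (first-harmonic balance at finite amplitude).
    The imaginary part changes sign at ``omega_star(params)``.
    """
    tau_a, tau_y, eps = params.tau_a, params.tau_y, params.epsilon
    alpha2 = params.alpha2
    if tau_a <= 0 or tau_y <= 0:
        raise InvalidModelError("tau_a and tau_y must be positive")
    if eps < 0:
        raise InvalidModelError("epsilon must be non-negative")
    if eps ** 2 * tau_a / tau_y >= 1.0:
        raise NoActiveBandError(
            "epsilon^2 * tau_a/tau_y >= 1: no phase-leading window exists")
    om = _as_float_array(omega, "omega")
    denom = linear_coeff - 1j * om * tau_a + 1.0 / (eps - 1j * om * tau_y)
    return ResponseSpectrum(om, alpha2 / denom)


def omega_star(params) -> float:
    """Sign-change frequency of the imaginary response of the cubic circuit.

    ``omega* = (tau_a*tau_y)^(-1/2) * (1 - eps^2*tau_a/tau_y)^(1/2)``.
    """
    tau_a, tau_y, eps = params.tau_a, params.tau_y, params.epsilon
    if tau_a <= 0 or tau_y <= 0:
        raise InvalidModelError("tau_a and tau_y must be positive")
    disc = 1.0 - eps ** 2 * tau_a / tau_y
    if disc < 0:
        raise NoActiveBandError(
            "epsilon^2 * tau_a/tau_y > 1: no phase-leading window exists")
    return math.sqrt(disc / (tau_a * tau_y))


def quality_factor(params) -> float:
    """Q = tau_a * omega*, the relative sharpness of the response peak."""
    return params.tau_a * omega_star(params)


def phase_of(spectrum: ResponseSpectrum) -> np.ndarray:
    """phi(omega) = -arg(R); positive = lead, negative = lag."""
    return spectrum.phase


# ---------------------------------------------------------------------------
# Kramers-Kronig reconstruction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KKResult:
    """Real part reconstructed from the imaginary part via causality."""

    omega: np.ndarray
    real: np.ndarray
    error_estimate: np.ndarray
    accuracy_warning: bool


def kramers_kronig(omega, imag, rtol: float = 0.02) -> KKResult:
    """Reconstruct real(R) from imag(R) through the dispersion integral.

    Evaluates ``real(R)(w) = (2/pi) * PV int_0^inf imag(R)(w1) * w1 /
    (w1^2 - w^2) dw1`` on the supplied grid.  The principal value is handled
    by subtracting the singular constant ``imag(R)(w)*w`` from the numerator
    (the remainder is regular) and integrating the subtracted pole in closed
    form.  Contributions outside the grid are estimated by a ~1/w1 tail and a
    linear (odd) head and folded into ``error_estimate``.

    The estimate is returned on the *interior* grid (endpoints dropped: the
    subtracted-pole integral is singular when the evaluation point sits on a
    grid edge).  Raises no error on a coarse/narrow grid; instead
    ``accuracy_warning`` is set when the out-of-grid estimate exceeds
    ``rtol`` of the result scale.
    """
    om_full = _as_float_array(omega, "omega")
    im_full = _as_float_array(imag, "imag")
    if om_full.size < 8:
        raise InsufficientDataError("Kramers-Kronig needs at least 8 grid points")
    if np.any(om_full <= 0) or np.any(np.diff(om_full) <= 0):
        raise InvalidModelError("omega must be strictly increasing and positive")
    a, b = om_full[0], om_full[-1]
    om, im = om_full, im_full
    g = im * om                       # numerator of the dispersion integrand
    dg = np.gradient(g, om)
    real = np.empty_like(om)
    err = np.empty_like(om)
    for k, wk in enumerate(om):
        if k == 0 or k == om.size - 1:
            real[k] = np.nan
            err[k] = np.inf
            continue
        denom = om ** 2 - wk ** 2
        h = np.empty_like(om)
        mask = np.abs(denom) > 1e-300
        h[mask] = (g[mask] - g[k]) / denom[mask]
        h[~mask] = dg[k] / (2.0 * wk)      # regular limit at the pole
        core = np.trapezoid(h, om)
        # closed-form PV of the subtracted pole over [a, b]
        pole = g[k] / (2.0 * wk) * math.log(
            ((b - wk) * (wk + a)) / ((b + wk) * (wk - a)))
        # tail beyond b: imag(R) ~ c/w1  => integrand ~ c/(w1^2 - wk^2)
        c_tail = im[-1] * b
        tail = c_tail / (2.0 * wk) * math.log((b + wk) / (b - wk))
        # head below a: imag(R) ~ slope*w1 (odd function)
        slope = im[0] / a
        head = slope * (a + wk / 2.0 * math.log((wk - a) / (wk + a)))
        real[k] = 2.0 / math.pi * (core + pole + tail + head)
        err[k] = 2.0 / math.pi * (abs(tail) + abs(head))
    real, err, om = real[1:-1], err[1:-1], om[1:-1]
    scale = float(np.max(np.abs(real))) or 1.0
    warning = bool(np.max(err) > rtol * scale)
    return KKResult(om, real, err, warning)


# ---------------------------------------------------------------------------
# Step-response analysis
# ---------------------------------------------------------------------------

def adaptation_error(step: StepResponse, window_frac: float = 0.2) -> float:
    """Residual long-time response per unit step (the adaptation error).

    Averages ``activity/step_size`` over the trailing ``window_frac`` of the
    record.  Stationarity of the tail is checked by comparing the means of
    its two halves; a difference beyond twice the combined standard error
    (plus a small absolute floor for noise-free data) raises
    :class:`NonStationaryError`.

    By causality this plateau equals the integral of the response kernel,
    i.e. the zero-frequency real response.
    """
    n = step.time.size
    n_win = max(int(round(window_frac * n)), 4)
    tail = step.activity[n - n_win:] / step.step_size
    half = n_win // 2
    first, second = tail[:half], tail[half:]
    se = math.sqrt(np.var(first) / max(first.size, 1)
                   + np.var(second) / max(second.size, 1))
    peak = float(np.max(np.abs(step.activity))) / abs(step.step_size)
    atol = 1e-6 * max(peak, 1e-12)
    if abs(float(np.mean(first) - np.mean(second))) > 2.0 * se + atol:
        raise NonStationaryError(
            "trailing window is not stationary; record too short for a plateau")
    return float(np.mean(tail))


def step_to_response_kernel(step: StepResponse, window: int = 5,
                            polyorder: int = 2) -> ResponseKernel:
    """Kernel R(t) = d(activity)/dt / step_size via smoothed differentiation.

    A local polynomial (Savitzky-Golay) filter of the given window and order
    provides the smoothed derivative in one pass; R(t < 0) = 0 by
    construction since the record starts at the step onset.
    """
    if step.time.size < 5:
        raise InsufficientDataError("kernel estimation needs at least 5 samples")
    window = int(window)
    if window % 2 == 0:
        window += 1
    window = max(window, polyorder + 1 + (polyorder % 2))
    window = min(window, step.time.size if step.time.size % 2 else step.time.size - 1)
    deriv = savgol_filter(step.activity, window_length=window, polyorder=polyorder,
                          deriv=1, delta=step.dt, mode="interp")
    return ResponseKernel(step.time, deriv / step.step_size)


def kernel_to_spectrum(kernel: ResponseKernel, omega) -> ResponseSpectrum:
    """Finite-window Fourier transform of a causal kernel (trapezoid rule).

    ``R(omega) = int_0^T R(t) exp(+i*omega*t) dt``.  If the kernel has not
    decayed below 1% of its peak at the window end, a truncation warning and
    an error bound ``2*|R(T)|/omega`` are attached to ``meta``.
    """
    om = _as_float_array(omega, "omega")
    t = kernel.time
    value = np.empty(om.size, dtype=complex)
    block = max(1, 2_000_000 // max(t.size, 1))   # bound the outer product
    for i in range(0, om.size, block):
        phase = np.exp(1j * np.outer(om[i:i + block], t))
        value[i:i + block] = np.trapezoid(phase * kernel.value[None, :], t, axis=1)
    peak = float(np.max(np.abs(kernel.value))) or 1.0
    tail = float(np.abs(kernel.value[-1]))
    meta = {
        "truncation_warning": tail > 0.01 * peak,
        "truncation_error": (2.0 * tail / np.maximum(om, 1.0 / t[-1])).max(),
    }
    return ResponseSpectrum(om, value, meta=meta)


# ---------------------------------------------------------------------------
# Active band, energy flux, FDT
# ---------------------------------------------------------------------------

def active_band(spectrum: ResponseSpectrum) -> list[tuple[float, float]]:
    """Maximal frequency intervals where imag(R) < 0 (phase-leading response).

    Interval edges between grid nodes are located by linear interpolation of
    the imaginary part.  Returns an empty list for a passive spectrum.
    """
    om, im = spectrum.omega, spectrum.value.imag
    neg = im < 0
    bands: list[tuple[float, float]] = []
    i = 0
    n = om.size
    while i < n:
        if not neg[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and neg[j + 1]:
            j += 1
        if i == 0:
            lo = om[0]
        else:
            lo = om[i - 1] + (om[i] - om[i - 1]) * im[i - 1] / (im[i - 1] - im[i])
        if j == n - 1:
            hi = om[-1]
        else:
            hi = om[j] + (om[j + 1] - om[j]) * im[j] / (im[j] - im[j + 1])
        bands.append((float(lo), float(hi)))
        i = j + 1
    return bands


def energy_flux(alpha1: float, spectrum: ResponseSpectrum, signal_power,
                omega):
    """Average power transferred from one cell to the signal at ``omega``.

    ``Wdot = -alpha1 * omega * imag(R_a(omega)) * <|s(omega)|^2>``, positive
    exactly when the activity leads the signal (imag(R_a) < 0).
    """
    om = np.asarray(omega, dtype=float)
    power = np.asarray(signal_power, dtype=float)
    if np.any(om <= 0):
        raise InvalidModelError("omega must be positive")
    if np.any(power < 0):
        raise InvalidModelError("signal power must be non-negative")
    im = np.interp(om, spectrum.omega, spectrum.value.imag)
    out = -alpha1 * om * im * power
    return float(out) if out.ndim == 0 else out


def fdt_ratio(response: ResponseSpectrum, correlation: CorrelationSpectrum,
              T: float) -> np.ndarray:
    """omega*C(omega) / (2*T*imag(R)); equals 1 for equilibrium dynamics.

    Grid points where imag(R) vanishes are returned as NaN.
    """
    if not np.allclose(response.omega, correlation.omega, rtol=1e-9, atol=0):
        raise InvalidModelError("response and correlation grids must match")
    if T <= 0:
        raise InvalidModelError("noise strength T must be positive")
    im = response.value.imag
    out = np.full_like(im, np.nan)
    ok = im != 0
    out[ok] = correlation.omega[ok] * correlation.value[ok] / (2.0 * T * im[ok])
    return out


def power_spectrum(series, dt: float, n_segments: int = 8,
                   overlap: float = 0.5) -> CorrelationSpectrum:
    """Segment-averaged one-sided PSD of a stationary series.

    Normalised as the spectral amplitude per unit observation time in angular
    frequency, so that an equilibrium variable at noise strength T satisfies
    ``2*T*imag(R) = omega*C`` exactly (Lorentzian for an over-damped mode).
    """
    x = _as_float_array(series, "series")
    if x.size < 2 * n_segments:
        raise InsufficientDataError("record too short for the segment count")
    nperseg = int(x.size / (1 + (n_segments - 1) * (1 - overlap)))
    freq, psd = welch(x, fs=1.0 / dt, nperseg=nperseg,
                      noverlap=int(nperseg * overlap), detrend="constant")
    # welch one-sided density in Hz -> two-sided density in angular frequency
    omega = 2.0 * math.pi * freq[1:]
    value = psd[1:] / 2.0
    return CorrelationSpectrum(omega, value)
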
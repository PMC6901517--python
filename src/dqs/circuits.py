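"""Stochastic simulators for single-cell circuits and response estimation.

Two circuit families are provided:

* a weakly nonlinear two-node adaptive circuit,
  ``tau_a*da/dt = -a - c3*a^3 + y + alpha2*s + eta_a``,
  ``tau_y*dy/dt = -a - eps*y + eta_y``;
* the excitable FitzHugh-Nagumo (FHN) circuit,
  ``tau_a*da/dt = a - a^3/3 - y + alpha2*s + eta_a``,
  ``tau_y*dy/dt = a - eps*y + a0 + eta_y``.

Noise terms are Gaussian and white with ``<eta_x(t) eta_x(t')> =
2*T*tau_x*delta(t-t')``, so ``T`` acts as a dimensionless temperature.
Integration is Euler-Maruyama (additive noise; weak order 1 suffices).
Ensemble response estimates use common random numbers: stimulated and
unstimulated copies share every noise increment, which removes most of the
shared fluctuation from the difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigError, InvalidModelError
from .response_core import (
    CorrelationSpectrum,
    ResponseSpectrum,
    StepResponse,
    power_spectrum,
)

__all__ = [
    "CubicCircuitParams",
    "FHNParams",
    "SimConfig",
    "Trajectory",
    "StepProtocol",
    "SineProtocol",
    "ExternalSignal",
    "signal_series",
    "simulate_cubic",
    "simulate_fhn",
    "fhn_resting_state",
    "cubic_step_plateau",
    "estimate_step_response",
    "estimate_sine_response",
    "correlation_spectrum",
]


@dataclass(frozen=True)
class CubicCircuitParams:
    """Constants of the two-node adaptive circuit with cubic saturation."""

    tau_a: float = 1.0
    tau_y: float = 1.0
    epsilon: float = 0.1
    c3: float = 1.0
    alpha2: float = 1.0
    T: float = 0.01

    def __post_init__(self):
        if self.tau_a <= 0 or self.tau_y <= 0:
            raise InvalidModelError("tau_a and tau_y must be positive")
        if self.epsilon < 0 or self.c3 < 0 or self.T < 0:
            raise InvalidModelError("epsilon, c3 and T must be non-negative")


@dataclass(frozen=True)
class FHNParams:
    """Constants of the excitable FHN circuit (excitable regime: tau_y > tau_a)."""

    tau_a: float = 1.0
    tau_y: float = 5.0
    epsilon: float = 0.1
    alpha2: float = 1.0
    a0: float = 1.5
    T: float = 0.1

    def __post_init__(self):
        if not (self.tau_y > self.tau_a > 0):
            raise InvalidModelError("excitable regime requires tau_y > tau_a > 0")
        if self.epsilon < 0 or self.T < 0:
            raise InvalidModelError("epsilon and T must be non-negative")


@dataclass(frozen=True)
class SimConfig:
    """Integration setup.  ``duration`` includes the ``transient``."""

    dt: float
    duration: float
    seed: int = 0
    n_realizations: int = 1
    transient: float = 0.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if self.duration <= self.transient:
            raise ConfigError("duration must exceed the transient")
        if self.n_realizations < 1:
            raise ConfigError("n_realizations must be at least 1")


def check_dt(dt: float, *timescales: float) -> None:
    """Enforce the stability bound dt <= min(timescale)/50."""
    bound = min(timescales) / 50.0
    if dt > bound * (1 + 1e-12):
        raise ConfigError(f"dt={dt} exceeds stability bound {bound}")


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled time series of one simulation."""

    time: np.ndarray
    data: dict
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for k, v in self.data.items():
            if not np.all(np.isfinite(v)):
                raise InvalidModelError(f"trajectory variable {k!r} is not finite")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def after(self, t0: float) -> "Trajectory":
        """Trajectory restricted to time >= t0 (transient removal)."""
        keep = self.time >= t0
        return Trajectory(self.time[keep] - t0,
                          {k: np.asarray(v)[..., keep] for k, v in self.data.items()},
                          dict(self.meta))


# ---------------------------------------------------------------------------
# Signal protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StepProtocol:
    size: float
    t_on: float = 0.0


@dataclass(frozen=True)
class SineProtocol:
    amplitude: float
    omega: float
    t_on: float = 0.0


@dataclass(frozen=True)
class ExternalSignal:
    values: np.ndarray


def signal_series(protocol, time: np.ndarray) -> np.ndarray:
    """Evaluate a signal protocol on a time grid (None -> zeros)."""
    if protocol is None:
        return np.zeros_like(time)
    if isinstance(protocol, StepProtocol):
        return np.where(time >= protocol.t_on, protocol.size, 0.0)
    if isinstance(protocol, SineProtocol):
        s = protocol.amplitude * np.cos(protocol.omega * (time - protocol.t_on))
        return np.where(time >= protocol.t_on, s, 0.0)
    if isinstance(protocol, ExternalSignal):
        vals = np.asarray(protocol.values, dtype=float)
        if vals.shape != time.shape:
            raise ConfigError("external signal must match the time grid")
        return vals
    raise ConfigError(f"unknown signal protocol {protocol!r}")


# ---------------------------------------------------------------------------
# Drift terms and the Euler-Maruyama core
# ---------------------------------------------------------------------------

def _drift_cubic(a, y, s, p: CubicCircuitParams):
    da = (-a - p.c3 * a ** 3 + y + p.alpha2 * s) / p.tau_a
    dy = (-a - p.epsilon * y) / p.tau_y
    return da, dy


def _drift_fhn(a, y, s, p: FHNParams):
    da = (a - a ** 3 / 3.0 - y + p.alpha2 * s) / p.tau_a
    dy = (a - p.epsilon * y + p.a0) / p.tau_y
    return da, dy


_DRIFTS: dict = {"cubic": _drift_cubic, "fhn": _drift_fhn}


def _initial_state(kind: str, params, shape) -> tuple[np.ndarray, np.ndarray]:
    if kind == "fhn":
        a_fp = fhn_resting_state(params)
        y_fp = (a_fp + params.a0) / params.epsilon if params.epsilon > 0 else a_fp - a_fp ** 3 / 3.0
        return np.full(shape, a_fp), np.full(shape, y_fp)
    return np.zeros(shape), np.zeros(shape)


def _integrate(kind: str, params, dt: float, n_steps: int, s_vals, rng,
               a, y, record: bool = True):
    """Euler-Maruyama loop over ``n_steps``; state arrays updated in place.

    ``s_vals`` is either None or an array of length n_steps+1 (node values).
    Returns (a_hist, y_hist) with shape (n_steps+1,) + state shape when
    ``record`` else (a, y) final states.
    """
    drift = _DRIFTS[kind]
    na = math.sqrt(2.0 * params.T * dt / params.tau_a)
    ny = math.sqrt(2.0 * params.T * dt / params.tau_y)
    noisy = params.T > 0
    if record:
        a_hist = np.empty((n_steps + 1,) + a.shape)
        y_hist = np.empty((n_steps + 1,) + a.shape)
        a_hist[0], y_hist[0] = a, y
    for k in range(n_steps):
        s = 0.0 if s_vals is None else s_vals[k]
        da, dy = drift(a, y, s, params)
        a = a + dt * da
        y = y + dt * dy
        if noisy:
            a = a + na * rng.standard_normal(a.shape)
            y = y + ny * rng.standard_normal(y.shape)
        if record:
            a_hist[k + 1], y_hist[k + 1] = a, y
    if record:
        return a_hist, y_hist
    return a, y


def _simulate(kind: str, params, sim: SimConfig, protocol) -> Trajectory:
    check_dt(sim.dt, params.tau_a, params.tau_y)
    n_steps = int(round(sim.duration / sim.dt))
    time = np.arange(n_steps + 1) * sim.dt
    s_vals = signal_series(protocol, time)
    rng = np.random.default_rng(sim.seed)
    a0, y0 = _initial_state(kind, params, ())
    a_hist, y_hist = _integrate(kind, params, sim.dt, n_steps, s_vals, rng,
                                np.asarray(a0, dtype=float), np.asarray(y0, dtype=float))
    return Trajectory(time, {"a": a_hist, "y": y_hist, "s": s_vals},
                      {"kind": kind, "params": params, "seed": sim.seed,
                       "transient": sim.transient})


def simulate_cubic(params: CubicCircuitParams, sim: SimConfig,
                   protocol=None) -> Trajectory:
    """Single realization of the cubic adaptive circuit under a signal protocol."""
    return _simulate("cubic", params, sim, protocol)


def simulate_fhn(params: FHNParams, sim: SimConfig, protocol=None) -> Trajectory:
    """Single realization of the FHN circuit under a signal protocol."""
    return _simulate("fhn", params, sim, protocol)


def fhn_resting_state(params: FHNParams) -> float:
    """Noise-free resting activity: root of eps*(a - a^3/3) = a + a0.

    For small adaptation error the root is close to ``-a0``.
    """
    eps, a0 = params.epsilon, params.a0

    def h(a):
        return eps * (a - a ** 3 / 3.0) - a - a0

    lo, hi = -abs(a0) - 5.0, abs(a0) + 5.0
    return float(brentq(h, lo, hi, xtol=1e-12))


def cubic_step_plateau(params: CubicCircuitParams, step_size: float = 1.0) -> float:
    """Noise-free long-time activity of the cubic circuit under a held step.

    Solves the coupled fixed point ``a*(1 + 1/eps) + c3*a^3 = alpha2*step``
    (for eps > 0); this is the deterministic value of the adaptation plateau.
    """
    eps = params.epsilon
    if eps == 0:
        return 0.0
    target = params.alpha2 * step_size

    def h(a):
        return a * (1.0 + 1.0 / eps) + params.c3 * a ** 3 - target

    bound = abs(target) + 1.0
    return float(brentq(h, -bound, bound, xtol=1e-14))


# ---------------------------------------------------------------------------
# Ensemble response estimators (common random numbers)
# ---------------------------------------------------------------------------

def _paired_difference(kind: str, params, sim: SimConfig, s_vals: np.ndarray):
    """Mean and standard error of a_stim - a_unstim over paired realizations.

    Both ensembles start from a shared equilibrated state and consume
    identical noise increments.  Returns (time, mean, stderr).
    """
    check_dt(sim.dt, params.tau_a, params.tau_y)
    n_rec = int(round((sim.duration - sim.transient) / sim.dt))
    n_tr = int(round(sim.transient / sim.dt))
    n_paths = sim.n_realizations
    rng = np.random.default_rng(sim.seed)
    a, y = _initial_state(kind, params, (n_paths,))
    a, y = _integrate(kind, params, sim.dt, n_tr, None, rng, a, y, record=False)

    drift = _DRIFTS[kind]
    na = math.sqrt(2.0 * params.T * sim.dt / params.tau_a)
    ny = math.sqrt(2.0 * params.T * sim.dt / params.tau_y)
    noisy = params.T > 0
    a1, y1 = a.copy(), y.copy()
    a2, y2 = a.copy(), y.copy()
    diff = np.empty((n_rec + 1, n_paths))
    diff[0] = 0.0
    for k in range(n_rec):
        da1, dy1 = drift(a1, y1, s_vals[k], params)
        da2, dy2 = drift(a2, y2, 0.0, params)
        a1 = a1 + sim.dt * da1
        y1 = y1 + sim.dt * dy1
        a2 = a2 + sim.dt * da2
        y2 = y2 + sim.dt * dy2
        if noisy:
            xi_a = rng.standard_normal(n_paths)
            xi_y = rng.standard_normal(n_paths)
            a1 += na * xi_a
            a2 += na * xi_a
            y1 += ny * xi_y
            y2 += ny * xi_y
        diff[k + 1] = a1 - a2
    time = np.arange(n_rec + 1) * sim.dt
    mean = diff.mean(axis=1)
    if n_paths > 1:
        stderr = diff.std(axis=1, ddof=1) / math.sqrt(n_paths)
    else:
        stderr = np.zeros_like(mean)
    return time, mean, stderr


def estimate_step_response(kind: str, params, sim: SimConfig,
                           step_size: float = 0.1) -> StepResponse:
    """Noise-averaged response to a step of ``step_size`` applied at t = 0.

    The pre-stimulus transient (``sim.transient``) equilibrates the ensemble;
    the returned record starts at the step onset with the unstimulated
    ensemble mean already subtracted (paired realizations).
    """
    n_rec = int(round((sim.duration - sim.transient) / sim.dt))
    s_vals = np.full(n_rec + 1, step_size)
    time, mean, stderr = _paired_difference(kind, params, sim, s_vals)
    # a zero-size step is a valid null protocol; normalisation is arbitrary
    return StepResponse(time, mean, step_size=step_size or 1.0, stderr=stderr)


def estimate_sine_response(kind: str, params, sim: SimConfig,
                           omegas: Sequence[float], amplitude: float = 0.1,
                           n_periods: int = 20, n_transient_periods: int = 5,
                           check_linearity: bool = False) -> ResponseSpectrum:
    """Measured response spectrum from sinusoidal stimulation.

    For each frequency the ensemble-averaged paired difference is fitted by
    least squares to ``C*cos(w*t) + S*sin(w*t)`` over ``n_periods`` whole
    periods after discarding ``n_transient_periods``; the complex response is
    ``(C + i*S)/amplitude`` under the package phase convention.

    With ``check_linearity`` the measurement is repeated at half amplitude;
    if any |R| changes by more than 5% a ``nonlinearity_warning`` is attached
    to ``meta``.
    """
    omegas = np.sort(np.asarray(omegas, dtype=float))
    if np.any(omegas <= 0):
        raise InvalidModelError("stimulus frequencies must be positive")

    def measure(amp):
        values = np.empty(omegas.size, dtype=complex)
        for i, w in enumerate(omegas):
            period = 2.0 * math.pi / w
            t_meas = n_periods * period
            t_tr = n_transient_periods * period
            cfg = replace(sim, duration=sim.transient + t_tr + t_meas,
                          transient=sim.transient, seed=sim.seed + 1000 * i)
            n_rec = int(round((t_tr + t_meas) / cfg.dt))
            rec_time = np.arange(n_rec + 1) * cfg.dt
            s_vals = amp * np.cos(w * rec_time)
            t, mean, _ = _paired_difference(kind, params, cfg, s_vals)
            keep = t >= t_tr
            tk, dk = t[keep], mean[keep]
            basis = np.column_stack([np.cos(w * tk), np.sin(w * tk)])
            (C, S), *_ = np.linalg.lstsq(basis, dk, rcond=None)
            values[i] = (C + 1j * S) / amp
        return values

    values = measure(amplitude)
    meta: dict = {"amplitude": amplitude}
    if check_linearity:
        half = measure(amplitude / 2.0)
        rel = np.abs(np.abs(half) - np.abs(values)) / np.maximum(np.abs(values), 1e-300)
        meta["nonlinearity_warning"] = bool(np.any(rel > 0.05))
        meta["linearity_max_rel_change"] = float(np.max(rel))
    return ResponseSpectrum(omegas, values, meta=meta)


def correlation_spectrum(traj: Trajectory, variable: str,
                         n_segments: int = 8) -> CorrelationSpectrum:
    """Segment-averaged power spectrum of one trajectory variable.

    The transient recorded in ``traj.meta`` is discarded first.  Normalised
    so the fluctuation-dissipation ratio is 1 for equilibrium dynamics.
    """
    t0 = traj.meta.get("transient", 0.0)
    tr = traj.after(t0)
    return power_spectrum(tr.data[variable], tr.dt, n_segments=n_segments)
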
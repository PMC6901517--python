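import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dqs.errors import (
    InvalidModelError,
    NoActiveBandError,
    NonStationaryError,
)
from dqs.circuits import CubicCircuitParams
from dqs.response_core import (
    CorrelationSpectrum,
    ResponseKernel,
    ResponseSpectrum,
    SignalModel,
    StepResponse,
    active_band,
    adaptation_error,
    analytic_cubic_response,
    energy_flux,
    fdt_ratio,
    kernel_to_spectrum,
    kramers_kronig,
    omega_star,
    phase_of,
    power_spectrum,
    quality_factor,
    signal_response,
    step_to_response_kernel,
)

OMEGA = np.geomspace(1e-3, 50.0, 2000)


# ---------------------------------------------------------------------------
# types and invariants
# ---------------------------------------------------------------------------

class TestTypes:
    def test_spectrum_requires_increasing_positive_grid(self):
        with pytest.raises(InvalidModelError):
            ResponseSpectrum(np.array([0.0, 1.0]), np.array([1.0, 1.0 + 0j]))
        with pytest.raises(InvalidModelError):
            ResponseSpectrum(np.array([2.0, 1.0]), np.array([1.0, 1.0 + 0j]))

    def test_spectrum_phase_in_principal_branch(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal(50) + 1j * rng.standard_normal(50)
        spec = ResponseSpectrum(np.linspace(0.1, 5, 50), vals)
        assert np.all(spec.phase > -math.pi) and np.all(spec.phase <= math.pi)
        assert np.all(spec.amplitude >= 0)

    def test_step_response_grid_checks(self):
        with pytest.raises(InvalidModelError):
            StepResponse(np.array([1.0, 2.0]), np.zeros(2))  # not from 0
        with pytest.raises(InvalidModelError):
            StepResponse(np.array([0.0, 1.0, 3.0]), np.zeros(3))  # non-uniform

    def test_signal_model_validation(self):
        with pytest.raises(InvalidModelError):
            SignalModel(gamma=-1.0, K=1.0)
        with pytest.raises(InvalidModelError):
            SignalModel(gamma=1.0, K=0.0)
        m = SignalModel(gamma=2.0, K=4.0)
        assert m.tau_s == pytest.approx(0.5)

    def test_signal_model_from_tau_s(self):
        m = SignalModel.from_tau_s(0.35, K=2.0)
        assert m.tau_s == pytest.approx(0.35)
        fast = SignalModel.from_tau_s(0.0)
        assert 0 < fast.tau_s < 1e-9

    def test_correlation_spectrum_nonnegative(self):
        with pytest.raises(InvalidModelError):
            CorrelationSpectrum(np.array([1.0, 2.0]), np.array([1.0, -0.1]))


# ---------------------------------------------------------------------------
# signal response
# ---------------------------------------------------------------------------

class TestSignalResponse:
    def test_zero_frequency_limit(self):
        m = SignalModel(gamma=1.0, K=1.0)
        spec = signal_response(m, np.array([1e-9]))
        assert spec.value[0] == pytest.approx(1.0, abs=1e-6)
        assert spec.phase[0] == pytest.approx(0.0, abs=1e-6)

    def test_unit_frequency_values(self):
        # direct evaluation of 1/(K - i*gamma*w) at K=gamma=w=1
        m = SignalModel(gamma=1.0, K=1.0)
        spec = signal_response(m, np.array([1.0]))
        assert spec.phase[0] == pytest.approx(-math.pi / 4)
        assert spec.amplitude[0] == pytest.approx(1.0 / math.sqrt(2))

    @settings(max_examples=50, deadline=None)
    @given(gamma=st.floats(0.01, 100), K=st.floats(0.01, 100),
           w=st.floats(1e-6, 1e6))
    def test_phase_always_lags_within_quarter_turn(self, gamma, K, w):
        spec = signal_response(SignalModel(gamma=gamma, K=K), np.array([w]))
        assert -math.pi / 2 < spec.phase[0] < 0


# ---------------------------------------------------------------------------
# cubic circuit spectrum
# ---------------------------------------------------------------------------

def printed_form(params, omega):
    """Published closed form of the adaptive-circuit spectrum (test oracle)."""
    eps, ta, ty, a2 = params.epsilon, params.tau_a, params.tau_y, params.alpha2
    ws = math.sqrt((1 - eps ** 2 * ta / ty) / (ta * ty))
    denom = (1.0
             + eps / (eps ** 2 + (ty * omega) ** 2)
             + 1j * ta * ws * ((ws / omega) - (omega / ws))
             / (1.0 + (eps / (ty * omega)) ** 2))
    return a2 / denom


class TestCubicSpectrum:
    def test_matches_printed_closed_form(self, unit_cubic):
        spec = analytic_cubic_response(unit_cubic, OMEGA)
        assert np.allclose(spec.value, printed_form(unit_cubic, OMEGA),
                           rtol=1e-12)

    def test_omega_star_trivial(self):
        p = CubicCircuitParams(epsilon=0.0)
        assert omega_star(p) == pytest.approx(1.0)

    def test_omega_star_degenerate_limit(self):
        p = CubicCircuitParams(epsilon=1.0 - 1e-9)
        assert omega_star(p) == pytest.approx(0.0, abs=1e-4)

    def test_omega_star_generic(self):
        p = CubicCircuitParams(tau_a=1.0, tau_y=5.0, epsilon=0.1)
        expected = math.sqrt((1 - 0.01 * 1 / 5) / 5)   # 0.44677...
        assert omega_star(p) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.44677, rel=1e-4)
        assert quality_factor(p) == pytest.approx(expected)

    def test_imag_sign_change_at_omega_star(self, unit_cubic):
        ws = omega_star(unit_cubic)
        assert ws == pytest.approx(math.sqrt(0.99))
        spec = analytic_cubic_response(
            unit_cubic, np.array([0.999 * ws, 1.001 * ws]))
        assert spec.value.imag[0] < 0 < spec.value.imag[1]

    def test_zero_frequency_limit_is_adaptation_error(self, unit_cubic):
        spec = analytic_cubic_response(unit_cubic, np.array([1e-8]))
        eps = unit_cubic.epsilon
        assert spec.value[0].real == pytest.approx(eps / (1 + eps), rel=1e-4)
        assert abs(spec.value[0].imag) < 1e-6

    def test_no_active_band_error(self):
        p = CubicCircuitParams(tau_a=4.0, tau_y=1.0, epsilon=0.6)
        with pytest.raises(NoActiveBandError):
            analytic_cubic_response(p, OMEGA)

    def test_phase_lead_below_omega_star(self, unit_cubic):
        ws = omega_star(unit_cubic)
        spec = analytic_cubic_response(unit_cubic, np.array([0.3 * ws]))
        assert phase_of(spec)[0] > 0


class TestPhaseOf:
    def test_real_positive_is_zero(self):
        spec = ResponseSpectrum(np.array([1.0]), np.array([1.0 + 0j]))
        assert phase_of(spec)[0] == pytest.approx(0.0)

    def test_single_pole_lags(self):
        spec = ResponseSpectrum(np.array([1.0]), np.array([1.0 / (1 - 1j)]))
        assert phase_of(spec)[0] == pytest.approx(-math.pi / 4)


# ---------------------------------------------------------------------------
# Kramers-Kronig
# ---------------------------------------------------------------------------

class TestKramersKronig:
    def test_zero_imag_gives_zero_real(self):
        res = kramers_kronig(OMEGA, np.zeros_like(OMEGA))
        assert np.allclose(res.real, 0.0)

    def test_single_pole_pair(self):
        tau = 1.0
        om = np.geomspace(1e-3, 1e3, 3000)
        res = kramers_kronig(om, om * tau / (1 + (om * tau) ** 2))
        true = 1.0 / (1 + (res.omega * tau) ** 2)
        inner = (res.omega > 1e-2) & (res.omega < 1e2)
        err = np.max(np.abs(res.real - true)[inner]) / true.max()
        assert err < 0.02
        assert not res.accuracy_warning

    def test_cubic_spectrum_reconstruction(self, unit_cubic):
        om = np.geomspace(1e-3, 500.0, 4000)
        spec = analytic_cubic_response(unit_cubic, om)
        res = kramers_kronig(om, spec.value.imag)
        inner = (res.omega > 1e-2) & (res.omega < 50.0)
        scale = np.max(np.abs(spec.value.real))
        err = np.max(np.abs(res.real - spec.value.real[1:-1])[inner]) / scale
        assert err < 0.02

    def test_narrow_grid_sets_warning(self):
        om = np.linspace(0.5, 2.0, 32)
        res = kramers_kronig(om, om / (1 + om ** 2))
        assert res.accuracy_warning


# ---------------------------------------------------------------------------
# step-response analysis
# ---------------------------------------------------------------------------

def relaxation_step(tau=1.0, dt=0.01, t_end=20.0):
    t = np.arange(0.0, t_end + dt / 2, dt)
    return StepResponse(t, 1.0 - np.exp(-t / tau), step_size=1.0)


class TestAdaptationError:
    def test_perfectly_adaptive_pulse_is_zero(self):
        t = np.arange(0.0, 40.0, 0.01)
        activity = t * np.exp(-t)          # integral of (1-t)e^-t kernel
        step = StepResponse(t, activity)
        assert adaptation_error(step) == pytest.approx(0.0, abs=1e-10)

    def test_matches_zero_frequency_spectrum(self):
        # identity: plateau equals the kernel integral / real response at 0
        t = np.arange(0.0, 40.0, 0.01)
        step = StepResponse(t, 0.1 * (1 - np.exp(-t)) + 0.9 * t * np.exp(-t))
        kern = step_to_response_kernel(step)
        spec = kernel_to_spectrum(kern, np.array([1e-6, 1e-5]))
        assert adaptation_error(step) == pytest.approx(
            spec.value[0].real, abs=2e-3)

    def test_nonstationary_tail_raises(self):
        t = np.arange(0.0, 10.0, 0.01)
        with pytest.raises(NonStationaryError):
            adaptation_error(StepResponse(t, t.copy()))


class TestKernelExtraction:
    def test_relaxation_kernel(self):
        step = relaxation_step(tau=1.0)
        kern = step_to_response_kernel(step)
        expect = np.exp(-step.time)
        inner = slice(5, -5)
        assert np.max(np.abs(kern.value - expect)[inner]) < 5e-3

    def test_zero_activity_gives_zero_kernel(self):
        t = np.arange(0.0, 5.0, 0.01)
        kern = step_to_response_kernel(StepResponse(t, np.zeros_like(t)))
        assert np.allclose(kern.value, 0.0)

    def test_too_short_record(self):
        from dqs.errors import InsufficientDataError
        t = np.arange(0.0, 0.04, 0.01)
        with pytest.raises(InsufficientDataError):
            step_to_response_kernel(StepResponse(t, np.zeros_like(t)))


class TestKernelToSpectrum:
    def test_exponential_kernel_closed_form(self):
        t = np.arange(0.0, 30.0, 0.005)
        kern = ResponseKernel(t, np.exp(-t))
        om = np.geomspace(0.05, 10.0, 50)
        spec = kernel_to_spectrum(kern, om)
        expect = 1.0 / (1.0 - 1j * om)
        assert np.max(np.abs(spec.value - expect) / np.abs(expect)) < 0.01
        assert not spec.meta["truncation_warning"]

    def test_zero_kernel(self):
        t = np.arange(0.0, 5.0, 0.01)
        spec = kernel_to_spectrum(ResponseKernel(t, np.zeros_like(t)),
                                  np.array([0.5, 1.0]))
        assert np.allclose(spec.value, 0.0)

    def test_undecayed_kernel_warns(self):
        t = np.arange(0.0, 1.0, 0.01)
        spec = kernel_to_spectrum(ResponseKernel(t, np.exp(-t)),
                                  np.array([1.0]))
        assert spec.meta["truncation_warning"]


# ---------------------------------------------------------------------------
# active band, energy flux, FDT
# ---------------------------------------------------------------------------

class TestActiveBand:
    def test_passive_single_pole_has_no_band(self):
        spec = ResponseSpectrum(OMEGA, 1.0 / (1.0 - 1j * OMEGA))
        assert active_band(spec) == []

    def test_cubic_band_ends_at_omega_star(self, unit_cubic):
        spec = analytic_cubic_response(unit_cubic, OMEGA)
        bands = active_band(spec)
        assert len(bands) == 1
        assert bands[0][1] == pytest.approx(omega_star(unit_cubic), rel=1e-3)

    def test_adaptive_kernel_band_nonempty(self):
        # kernel with small integral relative to its peak response
        t = np.arange(0.0, 60.0, 0.01)
        kern = ResponseKernel(t, (1.0 - 0.98 * t) * np.exp(-t))
        spec = kernel_to_spectrum(kern, OMEGA)
        assert len(active_band(spec)) >= 1

    @pytest.mark.parametrize("tau1,tau2", [(0.5, 2.0), (1.0, 5.0), (0.2, 1.0)])
    def test_adaptation_implies_band(self, tau1, tau2):
        # property: near-adapting kernels (integral << peak |R|) must have a
        # phase-leading window — numerical instance of the causality argument
        t = np.arange(0.0, 80.0, 0.01)
        k = np.exp(-t / tau1) / tau1 - 0.95 * np.exp(-t / tau2) / tau2
        spec = kernel_to_spectrum(ResponseKernel(t, k), OMEGA)
        integral = np.trapezoid(k, t)
        assert abs(integral) < 0.1 * spec.amplitude.max()
        assert len(active_band(spec)) >= 1


class TestEnergyFlux:
    def test_zero_phase_no_flux(self):
        spec = ResponseSpectrum(np.array([0.5, 1.0, 2.0]),
                                np.array([1.0, 2.0, 3.0], dtype=complex))
        assert energy_flux(1.0, spec, 1.0, 1.0) == pytest.approx(0.0)

    def test_zero_at_omega_star(self, unit_cubic):
        spec = analytic_cubic_response(unit_cubic, OMEGA)
        ws = omega_star(unit_cubic)
        assert energy_flux(1.0, spec, 1.0, ws) == pytest.approx(0.0, abs=1e-4)

    def test_positive_in_lead_region(self, unit_cubic):
        spec = analytic_cubic_response(unit_cubic, OMEGA)
        ws = omega_star(unit_cubic)
        assert energy_flux(1.0, spec, 0.7, 0.5 * ws) > 0
        assert energy_flux(1.0, spec, 0.7, 2.0 * ws) < 0

    def test_sign_follows_phase_everywhere(self, unit_cubic):
        spec = analytic_cubic_response(unit_cubic, OMEGA)
        w = OMEGA[5:-5:17]
        flux = energy_flux(0.8, spec, 1.3, w)
        phi = -np.angle(spec.interp(w))
        assert np.all(np.sign(flux) == np.sign(phi))


class TestFdtRatio:
    def test_equilibrium_lorentzian_is_one(self):
        # exact one-sided Lorentzian against the analytic response
        m = SignalModel(gamma=1.0, K=1.0)
        om = np.linspace(0.1, 10.0, 200)
        T = 0.7
        corr = CorrelationSpectrum(om, 2 * T * m.gamma
                                   / (m.K ** 2 + (m.gamma * om) ** 2))
        ratio = fdt_ratio(signal_response(m, om), corr, T)
        assert np.allclose(ratio, 1.0, atol=1e-12)

    def test_zero_imag_is_masked(self):
        om = np.array([1.0, 2.0])
        resp = ResponseSpectrum(om, np.array([1.0 + 0j, 1.0 + 1j]))
        corr = CorrelationSpectrum(om, np.array([1.0, 1.0]))
        ratio = fdt_ratio(resp, corr, 1.0)
        assert np.isnan(ratio[0]) and np.isfinite(ratio[1])

    def test_grid_mismatch_raises(self):
        resp = ResponseSpectrum(np.array([1.0]), np.array([1j]))
        corr = CorrelationSpectrum(np.array([2.0]), np.array([1.0]))
        with pytest.raises(InvalidModelError):
            fdt_ratio(resp, corr, 1.0)


class TestPowerSpectrum:
    def test_ou_lorentzian(self, rng):
        # exact AR(1) discretisation of an equilibrium over-damped mode
        tau, T, dt, n = 1.0, 0.5, 0.05, 200_000
        a = math.exp(-dt / tau)
        sigma = math.sqrt(T * (1 - a * a))   # stationary variance T
        x = np.empty(n)
        x[0] = 0.0
        xi = rng.standard_normal(n)
        for k in range(1, n):
            x[k] = a * x[k - 1] + sigma * xi[k]
        c = power_spectrum(x[n // 20:], dt, n_segments=16)
        sel = c.omega < 0.5 / dt
        # exact two-sided PSD of the sampled AR(1) process (test oracle);
        # it reduces to the Lorentzian 2*T*tau/(1+(tau*w)^2) for w*dt -> 0
        exact = sigma ** 2 * dt / (1 - 2 * a * np.cos(c.omega * dt) + a ** 2)
        lorentz = 2 * T * tau / (1 + (tau * c.omega) ** 2)
        assert np.allclose(exact[c.omega < 0.2 / tau],
                           lorentz[c.omega < 0.2 / tau], rtol=0.01)
        ratio = c.value[sel] / exact[sel]
        # welch bins are weakly correlated; allow a conservative margin
        assert abs(np.mean(ratio) - 1.0) < max(
            5 * np.std(ratio) / math.sqrt(sel.sum()), 0.02)
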
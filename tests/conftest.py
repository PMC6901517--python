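import numpy as np
import pytest

from dqs.circuits import CubicCircuitParams, FHNParams
from dqs.response_core import SignalModel


@pytest.fixture(scope="session")
def headline_cubic() -> CubicCircuitParams:
    """Cubic circuit constants of the coupled-population case study."""
    return CubicCircuitParams(tau_a=1.0, tau_y=1.0, epsilon=0.1, c3=1.0,
                              alpha2=0.5, T=0.01)


@pytest.fixture(scope="session")
def unit_cubic() -> CubicCircuitParams:
    """Cubic circuit with alpha2 = 1 (single-cell response studies)."""
    return CubicCircuitParams(tau_a=1.0, tau_y=1.0, epsilon=0.1, c3=1.0,
                              alpha2=1.0, T=0.01)


@pytest.fixture(scope="session")
def fhn_params() -> FHNParams:
    """FHN constants of the excitable case study."""
    return FHNParams(tau_a=1.0, tau_y=5.0, epsilon=0.1, alpha2=1.0,
                     a0=1.5, T=0.1)


@pytest.fixture(scope="session")
def headline_signal() -> SignalModel:
    """Signal medium of the coupled-population case study (tau_s = 1)."""
    return SignalModel(gamma=1.0, K=1.0, alpha1=0.5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
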
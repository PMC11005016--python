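import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")

from nileach.core import (
    ControlState,
    DeviceReleaseParams,
    Physiology,
    steady_state_rates,
)
from nileach.synthetic import DEFAULT_UPTAKE0


@pytest.fixture(scope="session")
def phys() -> Physiology:
    return Physiology()


@pytest.fixture(scope="session")
def control() -> ControlState:
    return ControlState()


@pytest.fixture(scope="session")
def ss_rates(control, phys):
    """Pulse-free rate set holding the control state stationary."""
    return steady_state_rates(control, phys, DEFAULT_UPTAKE0)


@pytest.fixture(scope="session")
def device() -> DeviceReleaseParams:
    """Reference device with an easily hand-checked plateau of 1100 ng."""
    return DeviceReleaseParams(alpha=100.0, tau=5.0, a_surf=11.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240325)
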
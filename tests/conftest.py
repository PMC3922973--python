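import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from whalesat import SimulationConfig, simulate_scene

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def surface_config() -> SimulationConfig:
    """Default study conditions with whales basking at the surface."""
    return SimulationConfig(seed=11, depth_range_m=(0.0, 0.0))


@pytest.fixture(scope="session")
def surface_scene(surface_config):
    return simulate_scene(surface_config)


@pytest.fixture(scope="session")
def quiet_config() -> SimulationConfig:
    """Noise-free surface-whale conditions (deterministic geometry)."""
    return SimulationConfig(
        seed=2,
        depth_range_m=(0.0, 0.0),
        water_noise_sd=0.0,
        pan_noise_sd=0.0,
        surface_texture_amplitude_dn=0.0,
    )


@pytest.fixture(scope="session")
def quiet_scene(quiet_config):
    return simulate_scene(quiet_config)


@pytest.fixture(scope="session")
def small_scene():
    """A small scene for I/O and geometry tests."""
    cfg = SimulationConfig(seed=9, ms_shape=(64, 64), n_whales=5)
    return simulate_scene(cfg)
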
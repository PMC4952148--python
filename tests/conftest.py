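import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import venoxim as vx

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def coefs():
    return vx.DEFAULT_COEFFICIENTS


@pytest.fixture(scope="session")
def clean_config():
    """Noiseless default scenario: SaO2 98 %, SvO2 75 %, pulse 1.2 Hz, stim 4 Hz."""
    return vx.SimulationConfig(noise_sd=0.0)


@pytest.fixture(scope="session")
def noisy_config():
    """Default scenario with default measurement noise and a fixed seed."""
    return vx.SimulationConfig(seed=12345)


@pytest.fixture(scope="session")
def clean_ppg(clean_config):
    return vx.simulate_ppg(clean_config)


@pytest.fixture(scope="session")
def clean_result(clean_ppg):
    return vx.run_pipeline(clean_ppg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20261001)
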
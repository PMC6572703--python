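import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from onebox import GeneratorConfig, generate_ground_truth

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def short_cycle_config():
    """Short-cycle spraying day (5-10 min bursts, ACH 25, V 248.6 m^3),
    noise-free so forward/inverse identities hold exactly."""
    return GeneratorConfig(seed=42, noise_cv=0.0, bg_cv=0.0)


@pytest.fixture(scope="session")
def short_cycle_truth(short_cycle_config):
    return generate_ground_truth(short_cycle_config)


@pytest.fixture(scope="session")
def noisy_truth():
    """Same day with instrument noise and background jitter at defaults."""
    return generate_ground_truth(GeneratorConfig(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(7)
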
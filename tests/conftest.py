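import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from mibgquant.phantom import PhantomConfig, make_myocardial_volume

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_config() -> PhantomConfig:
    return PhantomConfig(noise=False)


@pytest.fixture(scope="session")
def clean_shell_config() -> PhantomConfig:
    """Noiseless phantom with no extra-cardiac background in the volume."""
    return PhantomConfig(noise=False, body_volume=0.0, liver_volume=0.0)


@pytest.fixture(scope="session")
def unit_shell_volume(clean_shell_config):
    return make_myocardial_volume(clean_shell_config, 1.0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
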
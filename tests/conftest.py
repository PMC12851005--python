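import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rdtherm.synthetic import FixtureConfig, generate_structure_series

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_config() -> FixtureConfig:
    return FixtureConfig(seed=1)


@pytest.fixture(scope="session")
def fixture_series(fixture_config):
    """The default 12-temperature synthetic structure series (seed 1)."""
    return generate_structure_series(fixture_config)


@pytest.fixture(scope="session")
def model_100K(fixture_series):
    return fixture_series[0]


@pytest.fixture(scope="session")
def model_393K(fixture_series):
    return fixture_series[-1]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
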
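import pytest
from hypothesis import HealthCheck, settings

from drugeff import FixtureConfig, generate_universe

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_universe():
    """One synthetic universe at the default configuration, shared across
    tests that only read it."""
    return generate_universe(FixtureConfig())


@pytest.fixture(scope="session")
def default_config():
    return FixtureConfig()
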
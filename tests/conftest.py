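import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def survey():
    """One default synthetic survey, shared across tests."""
    from haarisk.simulate import GeneratorConfig, generate_concentrations

    return generate_concentrations(GeneratorConfig(seed=123))
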
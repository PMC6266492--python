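import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study():
    from ecofoot import study_fixtures

    return study_fixtures()


@pytest.fixture(scope="session")
def study_table(study):
    from ecofoot import study_annual_table

    return study_annual_table(study)
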
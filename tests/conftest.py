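import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from argprev.simulate import make_fixtures  # noqa: E402


@pytest.fixture(scope="session")
def fixture_tables():
    return make_fixtures()


@pytest.fixture(scope="session")
def published(fixture_tables):
    return fixture_tables[0]


@pytest.fixture(scope="session")
def unpublished(fixture_tables):
    return fixture_tables[1]


@pytest.fixture(scope="session")
def all_records(fixture_tables):
    published, unpublished = fixture_tables
    return list(published) + list(unpublished)
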
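import pytest
from hypothesis import HealthCheck, settings

from formswitch import (
    build_paper_fixture,
    decide_cohort,
    review_report,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_fixture():
    return build_paper_fixture(verify=False)


@pytest.fixture(scope="session")
def paper_decisions(paper_fixture):
    patients, kb, overrides = paper_fixture
    return decide_cohort(patients, kb, overrides)


@pytest.fixture(scope="session")
def paper_review(paper_fixture):
    patients, kb, _ = paper_fixture
    return review_report(patients, kb)
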
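import pytest

from ngtube_dta import CohortParams, generate_cohort, trial_fixture


@pytest.fixture(scope="session")
def fixture_dataset():
    """The deterministic marginal-count dataset (376 gastric + 38 lung)."""
    return trial_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    """A default synthetic cohort, fixed seed."""
    return generate_cohort(CohortParams(), seed=12345)
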
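import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from oncotier import CohortConfig, load_bundled_kb, simulate_cohort, study_cohort_fixture
from oncotier.synthetic import build_toy_genome


@pytest.fixture(scope="session")
def kb():
    return load_bundled_kb()


@pytest.fixture(scope="session")
def fixture30():
    return study_cohort_fixture()


@pytest.fixture(scope="session")
def toy_genome():
    return build_toy_genome()


@pytest.fixture(scope="session")
def cohort():
    """Default-condition synthetic cohort, fixed seed, shared read-only."""
    return simulate_cohort(CohortConfig(seed=11))
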
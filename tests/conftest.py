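import numpy as np
import pytest

from scentinel.cohort import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Seed-fixed cohort at the study's group sizes, with reference-test items."""
    return simulate_cohort(CohortSpec(seed=20210327, include_nih=True))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
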
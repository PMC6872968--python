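import numpy as np
import pytest

from dfnc.cohort import default_ground_truth, make_paradigm, simulate_cohort
from dfnc.windows import make_taper


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def paradigm():
    return make_paradigm()


@pytest.fixture(scope="session")
def ground_truth():
    return default_ground_truth(seed=0)


@pytest.fixture(scope="session")
def taper():
    return make_taper(20, 3.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Six subjects, two tasks, full time series — shared across tests."""
    return simulate_cohort(
        n_subjects=6,
        paradigm=make_paradigm(),
        ground_truth=default_ground_truth(seed=0),
        seed=7,
    )
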
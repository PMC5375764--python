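import numpy as np
import pytest

from aegdi.evaluation import simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cohort5():
    """Five subjects, two sessions (fresh orientations), 60 cycles each."""
    return simulate_cohort(5, 2, 60, seed=2)


@pytest.fixture(scope="session")
def gallery5(cohort5):
    return [c for c in cohort5 if c.session == 0]


@pytest.fixture(scope="session")
def probe5(cohort5):
    return [c for c in cohort5 if c.session == 1]
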
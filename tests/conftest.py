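import numpy as np
import pytest

from gaitclust.synthetic import NoiseParams, generate_cohort, make_nd_reference


@pytest.fixture(scope="session")
def nd_reference():
    return make_nd_reference(seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """A cheap 8-participant cohort (2 per archetype) for pipeline tests."""
    return generate_cohort(sizes=(2, 2, 2, 2), seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    """The default 37-participant cohort (5, 12, 12, 8)."""
    return generate_cohort(seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
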
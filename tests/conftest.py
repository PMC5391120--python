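import numpy as np
import pytest
from hypothesis import settings

from llpspeller import MixingMatrix, make_default_grid
from llpspeller.paradigm import generate_trial

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    return make_default_grid()


@pytest.fixture(scope="session")
def study_mixing():
    return MixingMatrix.study_default()


@pytest.fixture(scope="session")
def study_trial(grid):
    """One seeded study trial schedule (68 events)."""
    return generate_trial(grid, rng=np.random.default_rng(1234), trial_id=0)
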
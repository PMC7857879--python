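import numpy as np
import pytest
from hypothesis import settings

import tumorca as tc

settings.register_profile("suite", derandomize=True, max_examples=40,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture
def params():
    """Default (shipped) parameter set."""
    return tc.ModelParams()


@pytest.fixture
def small_params():
    """A small, fast lattice for unit-level runs."""
    return tc.ModelParams(ncell=21, n_iter=15, rmax=8.0)


@pytest.fixture
def rng_streams():
    return tc.RngStreams.from_seed(1234)


def make_tumor_square(n=15, half=2, center=None):
    """A filled (2*half+1)^2 block of mutant PCs on an otherwise normal grid."""
    grid = tc.CellGrid.blank(n, center)
    ci, cj = grid.center
    grid.states[ci - half:ci + half + 1, cj - half:cj + half + 1] = tc.PROLIFERATIVE
    grid.mutant[grid.states == tc.PROLIFERATIVE] = True
    return grid


@pytest.fixture
def tumor_square():
    return make_tumor_square()
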
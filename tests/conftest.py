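import numpy as np
import pytest

from divsearch import make_grid, make_inverted_sphere_surface


@pytest.fixture
def grid2d():
    """The canonical two-drug grid: 21 levels per drug, 441 cocktails."""
    return make_grid(2, 20)


@pytest.fixture
def sphere2d(grid2d):
    """Unimodal test surface with its unique optimum at the grid center."""
    return make_inverted_sphere_surface(grid2d, (10, 10))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
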
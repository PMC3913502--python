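import numpy as np
import pytest

from anisofd.grid import RegularGrid, TensorField, make_cube_grid
from anisofd.models import build_smooth_probe


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_grid():
    return make_cube_grid(2.0, 8)


@pytest.fixture
def probe8(small_grid):
    return build_smooth_probe(small_grid)


@pytest.fixture
def random_spd_field(small_grid, rng):
    """Random smooth positive-definite tensor field on the 8^3 grid."""
    return _random_spd_field(small_grid, rng)


def _random_spd_field(grid, rng):
    shape = grid.shape
    lam = 0.5 + rng.random(shape + (3,))
    g = rng.standard_normal(shape + (3, 3))
    q, r = np.linalg.qr(g)
    q = q * np.sign(np.einsum("...ii->...i", r))[..., None, :]
    t = np.einsum("...ij,...j,...kj->...ik", q, lam, q)
    return TensorField.from_tensors(grid, t)
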
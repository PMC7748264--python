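import numpy as np
import pytest

from nscpatterns.geometry import build_hemisphere, distance_matrix
from nscpatterns.synthetic import generate_hemisphere


@pytest.fixture(scope="session")
def grid3():
    """Flat 3x3 grid, 10 um spacing: the hand-enumeration substrate."""
    xs, ys = np.meshgrid(np.arange(3) * 10.0, np.arange(3) * 10.0)
    coords = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(9)])
    h = build_hemisphere(coords)
    return h, distance_matrix(h), coords


@pytest.fixture(scope="session")
def disc1200():
    """Medium flat synthetic hemisphere shared across slow tests."""
    h = generate_hemisphere(n_cells=1200, seed=101)
    return h, distance_matrix(h)


@pytest.fixture(scope="session")
def disc2000():
    h = generate_hemisphere(n_cells=2000, seed=202)
    return h, distance_matrix(h)


def grid_index(coords, x, y):
    return int(np.where((coords[:, 0] == x) & (coords[:, 1] == y))[0][0])
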
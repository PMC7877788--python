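import numpy as np
import pytest

from plsforest.gridding import GridSpec
from plsforest.synthetic_data import SurfaceSim, simulate_cells


@pytest.fixture(scope="session")
def grid30():
    return GridSpec(x0=0.0, y0=0.0, nx=30, ny=30, cell_size=8000.0)


@pytest.fixture(scope="session")
def cells30(grid30):
    """One realization of the default cell-level generative model."""
    cells, truth = simulate_cells(SurfaceSim(grid=grid30, seed=7))
    return cells, truth


@pytest.fixture(scope="session")
def small_basis_problem():
    """50 scattered cells, k=16 basis, fixed weights/data for fit oracles."""
    rng = np.random.default_rng(3)
    coords = rng.uniform(0, 100, (50, 2))
    z = rng.normal(2.0, 1.0, 50)
    w = rng.integers(1, 40, 50).astype(float)
    return coords, z, w
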
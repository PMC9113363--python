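import numpy as np
import pytest

from bsde import ExpressionHistogram, HistogramGrid


@pytest.fixture
def unit_grid():
    """Three bins with representatives at 0, 1, 2."""
    return HistogramGrid(np.array([-0.5, 0.5, 1.5, 2.5]), np.array([0.0, 1.0, 2.0]))


@pytest.fixture
def ten_bin_grid():
    bp = np.linspace(0.0, 5.0, 11)
    return HistogramGrid(bp, 0.5 * (bp[:-1] + bp[1:]))


def make_hist(grid, mass, n_cells=10):
    mass = np.asarray(mass, dtype=float)
    return ExpressionHistogram(grid, mass / mass.sum(), n_cells=n_cells)


def random_hist(grid, rng, sparsity=0.0):
    """Random histogram; optionally zero out some bins to exercise sparse mass."""
    mass = rng.dirichlet(np.ones(grid.n_bins))
    if sparsity:
        drop = rng.random(grid.n_bins) < sparsity
        if drop.all():
            drop[rng.integers(grid.n_bins)] = False
        mass[drop] = 0.0
        mass /= mass.sum()
    return ExpressionHistogram(grid, mass, n_cells=100)
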
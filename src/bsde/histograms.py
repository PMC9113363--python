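"""Per-subject expression histograms on a shared breakpoint grid.

All optimal-transport computation in this package operates on normalized
histograms of log-transformed counts. Subjects being compared must share a
single grid of breakpoints so that their histograms live on a common support;
the grid is built once per gene from the pooled (case + control) values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HistogramGrid",
    "ExpressionHistogram",
    "transform_counts",
    "make_common_grid",
    "build_histogram",
    "DegenerateRangeError",
]

#: relative headroom added above the maximum value so it falls inside the last bin
_GRID_DELTA = 1e-3


class DegenerateRangeError(ValueError):
    """Raised when all pooled values coincide and no grid can be built."""


@dataclass(frozen=True)
class HistogramGrid:
    """Shared binning of the transformed-expression axis.

    Parameters
    ----------
    breakpoints
        Strictly increasing array of length ``n_bins + 1``, in log(count+1)
        units. The first breakpoint is at most 0 so that zero counts
        (which transform to 0) are always representable.
    representatives
        Length ``n_bins`` support points, one strictly inside each bin; these
        are the locations mass is transported between, entering the squared
        Euclidean cost.
    """

    breakpoints: np.ndarray
    representatives: np.ndarray

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        rep = np.asarray(self.representatives, dtype=float)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "representatives", rep)
        if bp.ndim != 1 or bp.size < 3:
            raise ValueError("need at least 2 bins (3 breakpoints)")
        if not np.all(np.diff(bp) > 0):
            raise ValueError("breakpoints must be strictly increasing")
        if rep.shape != (bp.size - 1,):
            raise ValueError("need exactly one representative per bin")
        if not (np.all(rep > bp[:-1]) and np.all(rep < bp[1:])):
            raise ValueError("representatives must lie strictly inside their bins")
        if bp[0] > 0:
            raise ValueError("first breakpoint must be <= 0 (the zero-count transform)")

    @property
    def n_bins(self) -> int:
        return self.breakpoints.size - 1

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HistogramGrid):
            return NotImplemented
        return np.array_equal(self.breakpoints, other.breakpoints) and np.array_equal(
            self.representatives, other.representatives
        )

    def __hash__(self) -> int:  # frozen dataclass with arrays: hash by identity-ish bytes
        return hash((self.breakpoints.tobytes(), self.representatives.tobytes()))


@dataclass(frozen=True)
class ExpressionHistogram:
    """Normalized mass of one subject's cells over a shared grid.

    ``mass`` sums to 1 whenever ``n_cells > 0``; a subject with no cells of
    the target type yields ``n_cells == 0`` with undefined (all-NaN) mass and
    must be excluded from any transport computation.
    """

    grid: HistogramGrid
    mass: np.ndarray
    n_cells: int = field(default=0)

    def __post_init__(self) -> None:
        m = np.asarray(self.mass, dtype=float)
        object.__setattr__(self, "mass", m)
        if m.shape != (self.grid.n_bins,):
            raise ValueError("mass length must equal the number of bins")
        if self.n_cells > 0:
            if np.any(m < 0):
                raise ValueError("mass entries must be nonnegative")
            if abs(m.sum() - 1.0) > 1e-9:
                raise ValueError("mass must sum to 1")

    @property
    def is_empty(self) -> bool:
        return self.n_cells == 0


def transform_counts(counts) -> np.ndarray:
    """Map raw counts through the variance-stabilizing log(x + 1) transform.

    Natural log; order-preserving, zeros map to 0. Raises ``ValueError``
    on negative input.
    """
    x = np.asarray(counts, dtype=float)
    if x.size and np.min(x) < 0:
        raise ValueError("counts must be nonnegative")
    return np.log1p(x)


def make_common_grid(all_transformed_values, n_bins: int = 100) -> HistogramGrid:
    """Equal-width grid over the pooled transformed range.

    Spans ``[0, max * (1 + delta)]`` with a small headroom ``delta`` so the
    maximum observation falls inside the final bin; representatives are the
    bin midpoints. All subjects of a gene share this grid.

    Raises
    ------
    ValueError
        If ``n_bins < 2`` or no values are supplied.
    DegenerateRangeError
        If every pooled value is 0 (an all-zero gene carries no
        distributional signal; callers should skip the gene).
    """
    v = np.asarray(all_transformed_values, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    if v.size == 0:
        raise ValueError("cannot build a grid from an empty value set")
    hi = float(np.max(v))
    if hi <= 0.0:
        raise DegenerateRangeError("all values are zero: degenerate range")
    upper = hi * (1.0 + _GRID_DELTA)
    breakpoints = np.linspace(0.0, upper, n_bins + 1)
    reps = 0.5 * (breakpoints[:-1] + breakpoints[1:])
    return HistogramGrid(breakpoints, reps)


def build_histogram(transformed_values, grid: HistogramGrid) -> ExpressionHistogram:
    """Bin one subject's transformed values on the shared grid.

    Bins are half-open ``[b_k, b_{k+1})`` with the final bin closed, so a
    value equal to an interior breakpoint goes to the bin on its right and
    the maximum of the range stays in the last bin. An empty value sequence
    yields a flagged empty histogram (``n_cells == 0``, NaN mass).
    """
    v = np.asarray(transformed_values, dtype=float)
    if v.size == 0:
        return ExpressionHistogram(grid, np.full(grid.n_bins, np.nan), n_cells=0)
    bp = grid.breakpoints
    if np.min(v) < bp[0] or np.max(v) > bp[-1]:
        raise ValueError("value outside the grid span")
    idx = np.searchsorted(bp, v, side="right") - 1
    idx[idx == grid.n_bins] = grid.n_bins - 1  # close the final bin
    mass = np.bincount(idx, minlength=grid.n_bins).astype(float) / v.size
    return ExpressionHistogram(grid, mass, n_cells=int(v.size))
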
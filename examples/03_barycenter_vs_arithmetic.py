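"""Why a Wasserstein barycenter, not an arithmetic average of histograms.

Averages two well-separated unimodal histograms both ways and compares the
total transport objective sum_i W2^2(average, input_i). The arithmetic
average is bimodal (it ignores the metric on the expression axis); the
barycenter is a single mode at the metric midpoint and achieves a strictly
smaller objective.
"""

import numpy as np

from bsde import ExpressionHistogram, HistogramGrid, barycenter_exact_1d, w2_exact_1d

bp = np.linspace(0.0, 10.0, 41)
grid = HistogramGrid(bp, 0.5 * (bp[:-1] + bp[1:]))
x = grid.representatives


def gaussian_hist(center, width=0.5):
    mass = np.exp(-0.5 * ((x - center) / width) ** 2)
    return ExpressionHistogram(grid, mass / mass.sum(), n_cells=100)


inputs = [gaussian_hist(2.0), gaussian_hist(8.0)]

bary = barycenter_exact_1d(inputs)
arith = ExpressionHistogram(grid, np.mean([h.mass for h in inputs], axis=0), 100)


def objective(candidate):
    return sum(w2_exact_1d(candidate, h) ** 2 for h in inputs)


print(f"barycenter mode at x = {x[np.argmax(bary.mass)]:.2f} (metric midpoint of 2 and 8)")
print(f"objective, barycenter        : {objective(bary):.4f}")
print(f"objective, arithmetic average: {objective(arith):.4f}")
print()
print("The barycenter concentrates mass between the inputs and minimizes the")
print("summed squared transport cost; the arithmetic average keeps both modes")
print("and pays roughly the full separation in transport cost.")
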
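"""Entropic (Sinkhorn) transport against the exact 1-D quantile solution.

The regularized distance converges to the exact W2 as the regularization
epsilon shrinks; the exact closed form is what the screen uses by default.
"""

import numpy as np

from bsde import ExpressionHistogram, HistogramGrid, OTConfig, w2_entropic, w2_exact_1d

rng = np.random.default_rng(3)
bp = np.linspace(0.0, 5.0, 21)
grid = HistogramGrid(bp, 0.5 * (bp[:-1] + bp[1:]))
p = ExpressionHistogram(grid, rng.dirichlet(np.ones(20)), 100)
q = ExpressionHistogram(grid, rng.dirichlet(np.ones(20)), 100)

exact = w2_exact_1d(p, q)
print(f"exact 1-D W2 (quantile identity): {exact:.6f}")
for eps in (0.1, 0.01, 0.001):
    value, plan = w2_entropic(p, q, OTConfig(epsilon=eps, max_iter=50_000, tol=1e-8))
    print(
        f"entropic, eps={eps:<6}: {value:.6f}  "
        f"(rel. err {abs(value - exact) / exact:.2e}, {plan.n_iter} iterations)"
    )
print()
print("Smaller epsilon tightens the entropic value toward the exact distance")
print("at the cost of more Sinkhorn iterations.")
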
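"""Operating characteristics of a gene screen and the rank-test baseline.

Type-I error is the proportion of true-null genes called at level alpha;
power is the same proportion among truly differential genes. Genes with
undefined (NA) p-values are excluded from the denominators, with their
counts reported. The comparison baseline is a subject-level Mann-Whitney U
test on pseudo-bulk values (per-subject sums of raw counts), which controls
type-I error but is blind to distributional differences beyond location.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

__all__ = ["OperatingCharacteristics", "operating_characteristics", "mw_subject_baseline"]


@dataclass(frozen=True)
class OperatingCharacteristics:
    alpha: float
    type1_error: float
    power: float
    n_null: int
    n_de: int
    n_skipped_null: int
    n_skipped_de: int

    @property
    def mc_se_type1(self) -> float:
        """Binomial Monte-Carlo standard error of the type-I error estimate."""
        if self.n_null == 0:
            return float("nan")
        p = self.type1_error
        return float(np.sqrt(p * (1 - p) / self.n_null))

    @property
    def mc_se_power(self) -> float:
        if self.n_de == 0:
            return float("nan")
        p = self.power
        return float(np.sqrt(p * (1 - p) / self.n_de))


def operating_characteristics(
    p_values, is_de, alpha: float = 0.05
) -> OperatingCharacteristics:
    """Empirical size and power at level ``alpha`` (p <= alpha inclusive).

    ``is_de`` is a boolean per-gene ground-truth vector aligned with
    ``p_values``; NA p-values are excluded with counts reported.
    """
    p = np.asarray(p_values, dtype=float)
    de = np.asarray(is_de, dtype=bool)
    if p.shape != de.shape:
        raise ValueError("p_values and truth must have equal length")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    ok = ~np.isnan(p)
    null_ok = ok & ~de
    de_ok = ok & de
    t1 = float(np.mean(p[null_ok] <= alpha)) if null_ok.sum() else float("nan")
    pw = float(np.mean(p[de_ok] <= alpha)) if de_ok.sum() else float("nan")
    return OperatingCharacteristics(
        alpha=alpha,
        type1_error=t1,
        power=pw,
        n_null=int(null_ok.sum()),
        n_de=int(de_ok.sum()),
        n_skipped_null=int((~ok & ~de).sum()),
        n_skipped_de=int((~ok & de).sum()),
    )


def mw_subject_baseline(counts: pd.DataFrame, cells: pd.DataFrame, gene: str) -> float:
    """Two-sided Mann-Whitney U p-value on subject-level pseudo-bulk sums.

    Each subject's pseudo-bulk value is the sum of the gene's raw counts
    over that subject's cells; the two arms' pseudo-bulk vectors are
    compared with an exact (small-sample, no ties) or normal-approximation
    rank test. When every pseudo-bulk value is tied the test is undefined
    and p = 1 is returned.
    """
    sub = cells.set_index("cell_id")
    gene_counts = counts.loc[gene]
    bulk = gene_counts.groupby(sub.loc[gene_counts.index, "subject_id"]).sum()
    arm = cells.drop_duplicates("subject_id").set_index("subject_id")["diagnosis"]
    arms = sorted(arm.unique())
    if len(arms) != 2:
        raise ValueError("need exactly two diagnosis levels")
    x = bulk[arm[bulk.index] == arms[0]].to_numpy()
    y = bulk[arm[bulk.index] == arms[1]].to_numpy()
    if x.size < 1 or y.size < 1:
        raise ValueError("need at least one subject per arm")
    if np.all(np.concatenate([x, y]) == np.concatenate([x, y])[0]):
        return 1.0
    return float(mannwhitneyu(x, y, alternative="two-sided").pvalue)
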
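"""Barycenter-based differential-expression test (BSDE).

The test aggregates the per-subject expression histograms of each arm into
its Wasserstein barycenter and uses the W2 distance between the two
barycenters,

    lambda_hat = W2(P_hat, Q_hat),
    P_hat = argmin_mu sum_i W2^2(mu, P_i),   Q_hat = argmin_nu sum_j W2^2(nu, Q_j),

as the test statistic. Under the null hypothesis of no case-control
difference the subject labels are exchangeable, so significance is assessed
by relabeling subjects (preserving the group sizes l and n) and recomputing
the statistic; the permutation p-value uses the inclusive-tie formula

    p = (1 + #{lambda_(i) >= lambda_hat}) / (1 + N),

which is valid (super-uniform under the null) for any number of random
permutations N and never falls below 1/(1+N).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .histograms import (
    DegenerateRangeError,
    ExpressionHistogram,
    build_histogram,
    make_common_grid,
    transform_counts,
)
from .transport import (
    OTConfig,
    _merged_edges,
    _support,
    barycenter_entropic,
    quantile_average_atoms,
    w2_atoms,
    w2_entropic,
)

__all__ = [
    "GroupedHistograms",
    "BSDEResult",
    "bsde_statistic",
    "permutation_test",
    "permutation_pvalue",
    "adjust_fdr",
    "run_gene_screen",
]

REQUIRED_METADATA_COLUMNS = ("cell_id", "subject_id", "diagnosis", "cell_type")


@dataclass(frozen=True)
class GroupedHistograms:
    """Case histograms P1..Pl and control histograms Q1..Qn on one grid."""

    case_hists: list[ExpressionHistogram]
    control_hists: list[ExpressionHistogram]

    def __post_init__(self) -> None:
        if not self.case_hists or not self.control_hists:
            raise ValueError("need at least one case and one control histogram")
        grid = self.case_hists[0].grid
        for h in [*self.case_hists, *self.control_hists]:
            if h.grid != grid:
                raise ValueError("all histograms must share one grid")
            if h.is_empty:
                raise ValueError("empty histograms must be excluded before testing")

    @property
    def n_case(self) -> int:
        return len(self.case_hists)

    @property
    def n_control(self) -> int:
        return len(self.control_hists)


@dataclass(frozen=True)
class BSDEResult:
    statistic: float
    perm_statistics: np.ndarray
    p_value: float
    n_permutations: int
    exhaustive: bool = False
    backend: str = "exact"


def permutation_pvalue(statistic: float, perm_statistics) -> float:
    """Inclusive-tie permutation p-value (1 + #{perm >= observed})/(1 + N)."""
    perm = np.asarray(perm_statistics, dtype=float)
    return float((1 + np.sum(perm >= statistic)) / (1 + perm.size))


class _QuantileEngine:
    """Shared quantile matrix for exact barycenter-distance statistics.

    The exact W2 barycenter of a subset of subjects has as quantile function
    the mean of the subjects' quantile functions; on the common refinement
    of all subjects' CDF partitions every quantile function is piecewise
    constant, so the barycenter distance for *any* relabeling is a weighted
    sum of squared row-mean differences of one precomputed matrix. This is
    what makes subject-label permutation cheap.
    """

    def __init__(self, hists: list[ExpressionHistogram]):
        x = hists[0].grid.representatives
        supports = [_support(h.mass, x) for h in hists]
        _, self.widths, mids = _merged_edges([cs for _, cs in supports])
        self.qmat = np.stack(
            [xs[np.searchsorted(cs, mids, side="left")] for xs, cs in supports]
        )

    def statistics(self, case_masks: np.ndarray) -> np.ndarray:
        """lambda for each boolean case-membership row of ``case_masks``."""
        a = case_masks.astype(float)
        l = a.sum(axis=1, keepdims=True)
        n = a.shape[1] - l
        diff = (a @ self.qmat) / l - ((1.0 - a) @ self.qmat) / n
        return np.sqrt((diff**2) @ self.widths)


def bsde_statistic(g: GroupedHistograms, cfg: OTConfig = OTConfig()) -> float:
    """The observed statistic lambda_hat = W2(case barycenter, control barycenter)."""
    if cfg.backend == "entropic":
        p_hat = barycenter_entropic(g.case_hists, cfg)
        q_hat = barycenter_entropic(g.control_hists, cfg)
        value, _ = w2_entropic(p_hat, q_hat, cfg)
        return value
    xp, wp = quantile_average_atoms(g.case_hists)
    xq, wq = quantile_average_atoms(g.control_hists)
    return w2_atoms(xp, wp, xq, wq)


def _assignments(n_subjects: int, l: int, n_perm: int, rng: np.random.Generator):
    """Case-membership masks: observed first, then permuted relabelings."""
    identity = np.zeros(n_subjects, dtype=bool)
    identity[:l] = True
    n_distinct = math.comb(n_subjects, l) - 1
    if n_distinct <= n_perm:
        masks = []
        for combo in combinations(range(n_subjects), l):
            mask = np.zeros(n_subjects, dtype=bool)
            mask[list(combo)] = True
            if not np.array_equal(mask, identity):
                masks.append(mask)
        return identity, np.array(masks), True
    masks = np.zeros((n_perm, n_subjects), dtype=bool)
    for i in range(n_perm):
        masks[i, rng.permutation(n_subjects)[:l]] = True
    return identity, masks, False


def permutation_test(
    g: GroupedHistograms,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    cfg: OTConfig = OTConfig(),
) -> BSDEResult:
    """Subject-label permutation test of the barycenter W2 statistic.

    Relabelings preserve the group sizes (l, n); both barycenters and the
    distance are recomputed for every relabeling. When the number of
    distinct non-identity label assignments is at most ``n_perm`` they are
    all enumerated instead of sampled (``exhaustive=True``), removing
    Monte-Carlo noise for small cohorts.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    l, n = g.n_case, g.n_control
    hists = [*g.case_hists, *g.control_hists]
    identity, masks, exhaustive = _assignments(l + n, l, n_perm, rng)
    if cfg.backend == "exact":
        engine = _QuantileEngine(hists)
        all_stats = engine.statistics(np.vstack([identity[None, :], masks]))
        observed, perm_stats = float(all_stats[0]), all_stats[1:]
    else:

        def stat(mask: np.ndarray) -> float:
            grp = GroupedHistograms(
                [h for h, c in zip(hists, mask) if c],
                [h for h, c in zip(hists, mask) if not c],
            )
            return bsde_statistic(grp, cfg)

        observed = stat(identity)
        perm_stats = np.array([stat(m) for m in masks])
    return BSDEResult(
        statistic=observed,
        perm_statistics=perm_stats,
        p_value=permutation_pvalue(observed, perm_stats),
        n_permutations=int(perm_stats.size),
        exhaustive=exhaustive,
        backend=cfg.backend,
    )


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NA propagates."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] <= 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _validate_metadata(cells: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell metadata missing required columns: {missing}")
    if cells["cell_id"].duplicated().any():
        dup = cells.loc[cells["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValueError(f"duplicated cell id: {dup!r}")


def run_gene_screen(
    counts: pd.DataFrame,
    cells: pd.DataFrame,
    cell_type: str,
    case_label: str,
    n_perm: int = 1000,
    seed: int = 0,
    cfg: OTConfig = OTConfig(),
    n_bins: int = 100,
    median_above: float | None = None,
) -> pd.DataFrame:
    """Per-gene BSDE screen within one annotated cell type.

    Parameters
    ----------
    counts
        Genes x cells raw count matrix (rows indexed by gene name, columns
        by cell id).
    cells
        Metadata with columns cell_id, subject_id, diagnosis, cell_type.
        ``diagnosis`` must take exactly two values, of which ``case_label``
        names the case arm.
    median_above
        Optional display filter: adds a boolean column marking genes whose
        median raw count over the tested cells exceeds this threshold.

    Returns a table with one row per gene: statistic, p_value, q_value
    (Benjamini-Hochberg across testable genes), subject and cell counts,
    and a status ("ok", or the reason a gene was skipped with p = NA).
    Deterministic for a fixed seed.
    """
    _validate_metadata(cells)
    levels = set(cells["diagnosis"].unique())
    if len(levels) != 2:
        raise ValueError(f"diagnosis must take exactly two values, got {sorted(map(str, levels))}")
    if case_label not in levels:
        raise ValueError(f"case label {case_label!r} not found in diagnosis column")
    if cell_type not in set(cells["cell_type"]):
        raise ValueError(f"unknown cell type {cell_type!r}")
    unknown = set(cells["cell_id"]) - set(counts.columns)
    if unknown:
        raise ValueError(f"cells absent from the count matrix: {sorted(unknown)[:5]}")

    sel = cells[cells["cell_type"] == cell_type]
    subjects = []
    for subj, grp in sel.groupby("subject_id", sort=True):
        arm = grp["diagnosis"].iloc[0]
        if grp["diagnosis"].nunique() > 1:
            raise ValueError(f"subject {subj!r} has inconsistent diagnosis labels")
        subjects.append((str(subj), arm == case_label, list(grp["cell_id"])))
    absent = sorted(set(map(str, cells["subject_id"])) - {s for s, _, _ in subjects})
    if absent:
        warnings.warn(
            f"subjects with no {cell_type!r} cells excluded from testing: {absent}",
            UserWarning,
            stacklevel=2,
        )
    n_case_subj = sum(is_case for _, is_case, _ in subjects)
    n_ctrl_subj = len(subjects) - n_case_subj
    if n_case_subj < 1 or n_ctrl_subj < 1:
        raise ValueError("need at least one case and one control subject with cells")

    cell_cols = [c for _, _, ids in subjects for c in ids]
    sub = counts[cell_cols]
    is_case = np.repeat(
        [is_case for _, is_case, _ in subjects],
        [len(ids) for _, _, ids in subjects],
    )
    n_cells_case = int(is_case.sum())
    n_cells_ctrl = int((~is_case).sum())

    children = np.random.SeedSequence(seed).spawn(len(counts.index))
    rows = []
    for gi, gene in enumerate(counts.index):
        gene_counts = sub.loc[gene].to_numpy()
        row = {
            "gene": gene,
            "cell_type": cell_type,
            "statistic": np.nan,
            "p_value": np.nan,
            "n_case": n_case_subj,
            "n_control": n_ctrl_subj,
            "n_cells_case": n_cells_case,
            "n_cells_ctrl": n_cells_ctrl,
            "status": "ok",
        }
        if median_above is not None:
            row["passes_median_filter"] = bool(np.median(gene_counts) > median_above)
        values = transform_counts(gene_counts)
        try:
            grid = make_common_grid(values, n_bins=n_bins)
        except DegenerateRangeError:
            row["status"] = "degenerate-range"
            rows.append(row)
            continue
        case_hists, ctrl_hists = [], []
        start = 0
        for _, subj_is_case, ids in subjects:
            h = build_histogram(values[start : start + len(ids)], grid)
            start += len(ids)
            (case_hists if subj_is_case else ctrl_hists).append(h)
        grouped = GroupedHistograms(case_hists, ctrl_hists)
        res = permutation_test(
            grouped, n_perm=n_perm, seed=np.random.default_rng(children[gi]), cfg=cfg
        )
        row["statistic"] = res.statistic
        row["p_value"] = res.p_value
        rows.append(row)

    table = pd.DataFrame(rows)
    table["q_value"] = adjust_fdr(table["p_value"].to_numpy())
    front = ["gene", "cell_type", "statistic", "p_value", "q_value"]
    table = table[front + [c for c in table.columns if c not in front]]
    return table
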
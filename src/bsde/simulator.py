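"""Zero-inflated negative binomial simulator for case-control scRNA-seq.

The generator emulates per-gene, per-subject expression of a single cell
type. For gene i and subject j a parameter quadruple (mu_ij, phi_ij, z_ij,
sigma_ij) -- negative-binomial mean, dispersion (size), dropout probability
and cell-level variability -- is drawn from a four-variate Gaussian prior on
the transformed scale (log for mu, phi, sigma; logit for z, which keeps the
dropout probability in [0, 1]). Each cell k then receives its own mean
through log mu_ijk ~ N(log mu_ij, sigma_ij^2), and its count is drawn from
ZINB(mu_ijk, phi_ij, z_ij): zero with probability z, otherwise negative
binomial with mean mu and size phi, i.e. variance mu + mu^2/phi.

Four differential-expression constructions perturb the case arm:

* mean DE: mu* = r_mu * mu with dispersion adjusted so the negative-binomial
  variance is unchanged;
* variance DE: the full ZINB variance is multiplied by r_v with the mean
  unchanged;
* proportion DE: the two arms are opposite-weight mixtures of two ZINB
  components sharing phi and z;
* multimodality DE: one arm is an equal two-component ZINB mixture, the
  other a single ZINB matched in mean and variance.

Size factors of 1 (or r_p = 0.5, r_m -> 0) recover the null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "ZINBParams",
    "ParamPrior",
    "DESpec",
    "SimulatedDataset",
    "default_prior",
    "sample_params",
    "rzinb",
    "zinb_mean_var",
    "simulate_gene_subject",
    "mean_de_params",
    "variance_de_params",
    "proportion_de_counts",
    "multimodal_de_counts",
    "multimodal_single_params",
    "generate_dataset",
]

DE_TYPES = ("null", "mean", "variance", "proportion", "multimodal")


@dataclass(frozen=True)
class ZINBParams:
    """Per-gene, per-subject generative parameters.

    mu, phi parameterize the negative binomial with variance mu + mu^2/phi;
    z is the dropout (zero-inflation) probability; sigma the SD of the
    cell-level log-mean perturbation.
    """

    mu: float
    phi: float
    z: float
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.phi <= 0:
            raise ValueError("mu and phi must be positive")
        if not 0.0 <= self.z <= 1.0:
            raise ValueError("z must lie in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


@dataclass(frozen=True)
class ParamPrior:
    """Four-variate Gaussian over (log mu, log phi, logit z, log sigma).

    The default (see :func:`default_prior`) is a synthetic stand-in for a
    reference-data fit: typical lowly expressed gene (mu ~ 2), moderate
    dispersion, ~30% dropout, mild cell-level variability, with a mild
    positive correlation between log-mean and log-dispersion.
    """

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mean, dtype=float)
        c = np.asarray(self.covariance, dtype=float)
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "covariance", c)
        if m.shape != (4,) or c.shape != (4, 4):
            raise ValueError("prior must be four-variate")
        if not np.allclose(c, c.T):
            raise ValueError("covariance must be symmetric")
        if np.min(np.linalg.eigvalsh(c)) < -1e-10:
            raise ValueError("covariance must be positive semidefinite")


def default_prior() -> ParamPrior:
    """Synthetic default prior (no external reference-data fit is shipped)."""
    sd = np.array([0.5, 0.5, 0.5, 0.3])
    corr = np.eye(4)
    corr[0, 1] = corr[1, 0] = 0.3  # mild log mu / log phi coupling
    cov = corr * np.outer(sd, sd)
    return ParamPrior(
        mean=np.array([np.log(2.0), np.log(1.0), logit(0.3), np.log(0.3)]),
        covariance=cov,
    )


@dataclass(frozen=True)
class DESpec:
    """One gene's differential-expression construction.

    size_factor is r_mu / r_v / r_p / r_m depending on de_type;
    mixture_fold sets mu2/mu1 for proportion DE (the protocol leaves the
    component means free).
    """

    de_type: str = "null"
    size_factor: float = 1.0
    mixture_fold: float = 2.0

    def __post_init__(self) -> None:
        if self.de_type not in DE_TYPES:
            raise ValueError(f"unknown DE type {self.de_type!r}")
        if self.de_type in ("mean", "variance") and self.size_factor <= 0:
            raise ValueError("size factor must be positive")
        if self.de_type == "proportion" and not 0.0 < self.size_factor < 1.0:
            raise ValueError("r_p must lie in (0, 1)")
        if self.de_type == "multimodal" and not 0.0 < self.size_factor < 1.0:
            raise ValueError("r_m must lie in (0, 1)")
        if self.mixture_fold <= 0:
            raise ValueError("mixture_fold must be positive")


@dataclass(frozen=True)
class SimulatedDataset:
    """Counts plus labels and per-gene ground truth from one simulation run."""

    counts: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]
    cell_subject: list[str]
    subject_arm: dict[str, str]
    de_truth: list[DESpec]
    n_per_arm: int
    m_cells: int
    seed: int

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_names, columns=self.cell_ids)

    def cells_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "subject_id": self.cell_subject,
                "diagnosis": [self.subject_arm[s] for s in self.cell_subject],
                "cell_type": "simulated",
            }
        )

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.gene_names,
                "de_type": [d.de_type for d in self.de_truth],
                "size_factor": [d.size_factor for d in self.de_truth],
            }
        )


def sample_params(prior: ParamPrior, rng: np.random.Generator) -> ZINBParams:
    """Draw one (mu, phi, z, sigma) quadruple from the transformed Gaussian."""
    v = rng.multivariate_normal(prior.mean, prior.covariance, method="svd")
    return ZINBParams(
        mu=float(np.exp(v[0])),
        phi=float(np.exp(v[1])),
        z=float(expit(v[2])),
        sigma=float(np.exp(v[3])),
    )


def zinb_mean_var(mu: float, phi: float, z: float) -> tuple[float, float]:
    """Closed-form ZINB moments: mean (1-z)mu, variance
    (1-z)(mu + mu^2/phi) + z(1-z)mu^2."""
    mean = (1.0 - z) * mu
    var = (1.0 - z) * (mu + mu**2 / phi) + z * (1.0 - z) * mu**2
    return mean, var


def rzinb(k: int, mu, phi, z, rng: np.random.Generator) -> np.ndarray:
    """k draws from ZINB(mu, phi, z); mu may be scalar or length-k."""
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (k,))
    if np.any(mu <= 0) or phi <= 0 or not 0.0 <= z <= 1.0:
        raise ValueError("require mu, phi > 0 and z in [0, 1]")
    counts = rng.negative_binomial(phi, phi / (phi + mu), size=k)
    dropout = rng.random(k) < z
    counts[dropout] = 0
    return counts


def simulate_gene_subject(params: ZINBParams, m: int, rng: np.random.Generator) -> np.ndarray:
    """Counts for one gene in one subject's m cells.

    Cell-level heterogeneity enters through a log-normal mean:
    log mu_k ~ N(log mu, sigma^2), guaranteeing positive cell means.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    if params.sigma > 0:
        mu_k = np.exp(rng.normal(np.log(params.mu), params.sigma, size=m))
    else:
        mu_k = np.full(m, params.mu)
    return rzinb(m, mu_k, params.phi, params.z, rng)


# ---------------------------------------------------------------------------
# differential-expression parameter maps
# ---------------------------------------------------------------------------


def mean_de_params(p: ZINBParams, r_mu: float) -> ZINBParams:
    """Scale the mean by r_mu, keeping the negative-binomial variance fixed.

    mu* = r_mu mu, z* = z, and phi* = r_mu^2 mu phi / (mu + (1 - r_mu) phi)
    solves mu* + mu*^2/phi* = mu + mu^2/phi. The map is undefined (phi* <= 0)
    when r_mu > 1 + mu/phi; callers should reject such parameter draws.
    """
    if r_mu <= 0:
        raise ValueError("r_mu must be positive")
    denom = p.mu + (1.0 - r_mu) * p.phi
    if denom <= 0:
        raise ValueError("equal-variance dispersion is nonpositive for this draw")
    phi_star = r_mu**2 * p.mu * p.phi / denom
    return ZINBParams(mu=r_mu * p.mu, phi=phi_star, z=p.z, sigma=p.sigma)


def variance_de_params(p: ZINBParams, r_v: float) -> ZINBParams:
    """Multiply the full ZINB variance by r_v, keeping the mean fixed.

    mu* = mu, z* = z, and
    phi* = phi mu / (r_v mu + (r_v - 1) phi + (r_v - 1) z phi mu).
    """
    if r_v <= 0:
        raise ValueError("r_v must be positive")
    denom = r_v * p.mu + (r_v - 1.0) * p.phi + (r_v - 1.0) * p.z * p.phi * p.mu
    if denom <= 0:
        raise ValueError("variance-scaled dispersion is nonpositive for this draw")
    return ZINBParams(mu=p.mu, phi=p.phi * p.mu / denom, z=p.z, sigma=p.sigma)


def proportion_de_counts(
    p1: ZINBParams,
    p2: ZINBParams,
    r_p: float,
    arm: str,
    m: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mixture-proportion DE: the case arm draws each cell from component 1
    with probability r_p, the control arm with probability 1 - r_p.

    The two components must share phi and z; membership is resampled per
    cell. r_p = 0.5 makes the arms identically distributed (null).
    """
    if not 0.0 < r_p <= 1.0:
        raise ValueError("r_p must lie in (0, 1]")
    if arm not in ("case", "control"):
        raise ValueError("arm must be 'case' or 'control'")
    if p1.phi != p2.phi or p1.z != p2.z:
        raise ValueError("mixture components must share phi and z")
    w = r_p if arm == "case" else 1.0 - r_p
    comp1 = rng.random(m) < w
    mu_k = np.where(comp1, p1.mu, p2.mu)
    return rzinb(m, mu_k, p1.phi, p1.z, rng)


def multimodal_single_params(p2: ZINBParams, r_m: float) -> ZINBParams:
    """Single-component match for the equal two-component mixture.

    With mu1 = mu2 (1 + r_m)/(1 - r_m), the mixture
    0.5 ZINB(mu1, phi, z) + 0.5 ZINB(mu2, phi, z) has mean (1-z) mu* with
    mu* = mu2/(1 - r_m); phi* is solved from equality of the full variances
    using the within- plus between-component decomposition of the mixture.
    """
    if not 0.0 < r_m < 1.0:
        raise ValueError("r_m must lie in (0, 1)")
    mu2, phi, z = p2.mu, p2.phi, p2.z
    mu1 = mu2 * (1.0 + r_m) / (1.0 - r_m)
    mu_star = mu2 / (1.0 - r_m)
    _, v1 = zinb_mean_var(mu1, phi, z)
    _, v2 = zinb_mean_var(mu2, phi, z)
    var_mix = 0.5 * (v1 + v2) + 0.25 * ((1.0 - z) * (mu1 - mu2)) ** 2
    denom = var_mix - (1.0 - z) * mu_star - z * (1.0 - z) * mu_star**2
    # denom = (1-z)mu*^2/phi*; positive because the mixture over-disperses
    phi_star = (1.0 - z) * mu_star**2 / denom
    return ZINBParams(mu=mu_star, phi=phi_star, z=z, sigma=p2.sigma)


def multimodal_de_counts(
    p2: ZINBParams, r_m: float, arm: str, m: int, rng: np.random.Generator
) -> np.ndarray:
    """Multimodality DE: case cells from the equal two-component mixture,
    control cells from the moment-matched single ZINB."""
    if arm not in ("case", "control"):
        raise ValueError("arm must be 'case' or 'control'")
    if arm == "case":
        if not 0.0 < r_m < 1.0:
            raise ValueError("r_m must lie in (0, 1)")
        mu1 = p2.mu * (1.0 + r_m) / (1.0 - r_m)
        comp1 = rng.random(m) < 0.5
        mu_k = np.where(comp1, mu1, p2.mu)
        return rzinb(m, mu_k, p2.phi, p2.z, rng)
    star = multimodal_single_params(p2, r_m)
    return rzinb(m, star.mu, star.phi, star.z, rng)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

_MAX_REDRAWS = 1000


def _draw_admissible(
    prior: ParamPrior, spec: DESpec, rng: np.random.Generator
) -> tuple[ZINBParams, ZINBParams, int]:
    """Subject parameters plus their case-arm counterpart, redrawing the
    (rare) prior samples on which the moment-matched dispersion is
    nonpositive. Rejection applies identically in both arms so the base
    parameter distribution stays exchangeable across subjects."""
    for attempt in range(_MAX_REDRAWS):
        base = sample_params(prior, rng)
        try:
            if spec.de_type == "mean":
                return base, mean_de_params(base, spec.size_factor), attempt
            if spec.de_type == "variance":
                return base, variance_de_params(base, spec.size_factor), attempt
            return base, base, attempt
        except ValueError:
            continue
    raise RuntimeError("could not draw admissible parameters; check size factor")


def generate_dataset(
    n_genes: int,
    n_per_arm: int,
    m: int,
    prior: ParamPrior | None = None,
    de_specs: list[DESpec] | None = None,
    de_fraction: float = 0.0,
    de_type: str = "mean",
    size_factor: float = 2.0,
    mixture_fold: float = 2.0,
    seed: int = 0,
) -> SimulatedDataset:
    """Simulate a full case-control dataset for one cell type.

    Each arm has ``n_per_arm`` subjects with ``m`` cells each. Per gene and
    subject a fresh parameter quadruple is drawn from the prior; the gene's
    DESpec perturbs the case arm only (null genes are untouched). Ground
    truth is recorded per gene. Fully deterministic for a fixed seed.

    ``de_specs`` gives explicit per-gene constructions; otherwise the first
    ``round(de_fraction * n_genes)`` genes use (de_type, size_factor) and
    the rest are null.
    """
    if n_genes < 1 or n_per_arm < 1 or m < 1:
        raise ValueError("n_genes, n_per_arm and m must all be at least 1")
    prior = prior or default_prior()
    if de_specs is None:
        n_de = int(round(de_fraction * n_genes))
        de_specs = [
            DESpec(de_type, size_factor, mixture_fold) for _ in range(n_de)
        ] + [DESpec("null") for _ in range(n_genes - n_de)]
    if len(de_specs) != n_genes:
        raise ValueError("need one DESpec per gene")

    rng = np.random.default_rng(seed)
    subjects = [f"case{j+1}" for j in range(n_per_arm)] + [
        f"ctrl{j+1}" for j in range(n_per_arm)
    ]
    subject_arm = {
        s: ("case" if s.startswith("case") else "control") for s in subjects
    }
    cell_ids = [f"{s}_c{k+1}" for s in subjects for k in range(m)]
    cell_subject = [s for s in subjects for _ in range(m)]
    counts = np.zeros((n_genes, len(cell_ids)), dtype=np.int64)
    n_redraws = 0

    for gi in range(n_genes):
        spec = de_specs[gi]
        for sj, subj in enumerate(subjects):
            arm = subject_arm[subj]
            sl = slice(sj * m, (sj + 1) * m)
            if spec.de_type in ("null", "mean", "variance"):
                base, perturbed, redraws = _draw_admissible(prior, spec, rng)
                n_redraws += redraws
                params = perturbed if arm == "case" else base
                counts[gi, sl] = simulate_gene_subject(params, m, rng)
            elif spec.de_type == "proportion":
                base = sample_params(prior, rng)
                p2 = ZINBParams(
                    mu=spec.mixture_fold * base.mu, phi=base.phi, z=base.z
                )
                counts[gi, sl] = proportion_de_counts(
                    base, p2, spec.size_factor, arm, m, rng
                )
            else:  # multimodal
                base = sample_params(prior, rng)
                counts[gi, sl] = multimodal_de_counts(
                    base, spec.size_factor, arm, m, rng
                )
    if n_redraws:
        warnings.warn(f"{n_redraws} parameter draws rejected and redrawn", UserWarning)

    return SimulatedDataset(
        counts=counts,
        gene_names=[f"gene{g+1}" for g in range(n_genes)],
        cell_ids=cell_ids,
        cell_subject=cell_subject,
        subject_arm=subject_arm,
        de_truth=list(de_specs),
        n_per_arm=n_per_arm,
        m_cells=m,
        seed=seed,
    )
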
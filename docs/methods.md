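# Methods

## The test

For a single gene within one cell type, each subject's cells give an
empirical distribution of `log(count + 1)` expression. All subjects of a
gene share one histogram grid: 100 equal-width bins spanning `[0,
max·(1+10⁻³)]` of the pooled (both arms, all subjects) transformed values,
with bin representatives at midpoints. Bins are half-open `[b_k, b_{k+1})`
with the final bin closed. Equal-width binning keeps the transport cost
matrix interpretable in expression units; the grid depends only on pooled
values and is therefore permutation-invariant, so it is built once per gene
and reused across permutations.

The statistic is λ̂ = W₂(P̂, Q̂), the 2-Wasserstein distance between the
case and control barycenters (uniform weights within each arm). Significance
comes from subject-label permutation preserving the group sizes (l, n), with
the inclusive-tie estimator p = (1 + #{λ⁽ⁱ⁾ ≥ λ̂})/(1 + N); p is bounded
below by 1/(1+N) and is super-uniform under the null for any N. When the
number of distinct non-identity label assignments is ≤ N they are enumerated
exhaustively, which removes Monte-Carlo noise exactly where it is worst
(tiny cohorts). Default N = 1000.

### Computing the transport quantities

Two backends satisfy the same contracts:

* **Exact (default).** In one dimension, W₂²(P,Q) = ∫₀¹ (F⁻¹ − G⁻¹)² dt and
  the uniform-weight W₂ barycenter is the distribution whose quantile
  function is the mean of the input quantile functions. For histograms both
  are closed-form on the common refinement of the inputs' CDF partitions.
  The screen computes λ̂ directly in quantile space: on the refinement of
  *all* subjects' partitions every subject's quantile function is a constant
  per segment, so λ̂ for any relabeling is a weighted root-sum-of-squares of
  row-mean differences of one precomputed subjects × segments matrix. This
  makes the permutation loop a single matrix product and is exact — it
  avoids even the discretization incurred by re-binning the barycenter onto
  the grid (the re-binned barycenter is available as a histogram object when
  needed). The exact backend is the ε → 0 limit of the entropic one,
  deterministic, and faster here than matrix scaling.
* **Entropic.** Log-domain stabilized Sinkhorn–Knopp scaling for the pairwise
  distance and iterative Bregman projections for the barycenter, on the
  squared-Euclidean cost between bin representatives. The cost matrix is
  divided by its maximum entry before scaling (keeping `exp(−c/ε)` in
  floating range on any grid) and the transport cost is rescaled back.
  Defaults: ε = 10⁻² (after normalization), `max_iter` = 10⁴, marginal/L1
  tolerance 10⁻⁸. Zero-mass bins are dropped from the scaling (for the
  distance) or handled through −∞ log-mass (for the barycenter), so sparse
  empirical histograms are safe. Non-convergence is reported in the returned
  plan and by a warning, never silently. These solver settings are
  engineering defaults validated against the exact 1-D oracles; the
  regularization level is a numerical device, not a model parameter.

Genes whose pooled counts are all zero have no distributional signal; they
are skipped with status `degenerate-range` and p = NA rather than fabricating
a grid. Subjects with no cells of the target type are excluded with a
warning. Across genes, Benjamini–Hochberg q-values are reported alongside
raw p-values (the field default for DEG screens; the across-gene
multiplicity rule is otherwise open). An optional display filter flags genes
with median raw count above a threshold (median of *raw* counts, an
interpretive choice).

## The simulator

Per gene i and subject j, parameters (μᵢⱼ, φᵢⱼ, zᵢⱼ, σᵢⱼ) — NB mean, NB
size/dispersion (variance μ + μ²/φ), dropout probability, and cell-level
variability — are drawn from a four-variate Gaussian on the transformed
scale: log for μ, φ, σ and **logit for z** (a log-scale dropout rate could
exceed 1; the logit respects [0,1]). Each cell k draws its own mean on the
log scale, log μᵢⱼₖ ~ N(log μᵢⱼ, σᵢⱼ²) — the log scale guarantees positive
cell means — and then a count from ZINB(μᵢⱼₖ, φᵢⱼ, zᵢⱼ): zero with
probability z, otherwise NB. ZINB moments: mean (1−z)μ, variance
(1−z)(μ + μ²/φ) + z(1−z)μ².

The size parameterization (variance μ + μ²/φ) is fixed because it is the
convention under which the variance-DE dispersion map below scales the full
ZINB variance by exactly r_v (verified symbolically).

### Shipped prior (synthetic)

No external reference-data fit is distributed. The default prior is a
synthetic stand-in chosen once to represent a typical moderately expressed,
moderately dispersed single-cell gene: mean (log 2, log 1, logit 0.3,
log 0.3) for (log μ, log φ, logit z, log σ), standard deviations
(0.5, 0.5, 0.5, 0.3), correlation 0.3 between log μ and log φ, zero
elsewhere. It is user-overridable (`ParamPrior`), and any fit to a real
reference dataset can be supplied in its place.

### Differential-expression constructions (case arm only)

* **Mean DE** (r_μ): μ* = r_μ μ, z* = z, φ* = r_μ² μφ / (μ + (1−r_μ)φ),
  which keeps the NB variance μ + μ²/φ exactly unchanged. The map is
  undefined when r_μ > 1 + μ/φ (φ* ≤ 0); such prior draws are rejected and
  redrawn, identically in both arms so subjects stay exchangeable.
* **Variance DE** (r_v): μ* = μ, z* = z,
  φ* = φμ / (r_v μ + (r_v−1)φ + (r_v−1)zφμ), which multiplies the full ZINB
  variance by exactly r_v with the mean unchanged.
* **Proportion DE** (r_p ∈ (0,1)): the case arm draws each cell from
  component 1 of a two-component ZINB mixture with probability r_p, the
  control arm with probability 1−r_p; components share φ and z. The
  protocol leaves the component means free; here μ₁ comes from the prior
  and μ₂ = fold·μ₁ with default fold 2. r_p = 0.5 recovers the null.
* **Multimodality DE** (r_m ∈ (0,1)): the case arm is an equal mixture of
  ZINB(μ₁, φ, z) and ZINB(μ₂, φ, z) with μ₁ = μ₂(1+r_m)/(1−r_m); the
  control arm is a single ZINB(μ*, φ*, z) with μ* = μ₂/(1−r_m) (the mixture
  mean) and φ* solved from equality of the full variances via the
  within-plus-between decomposition of the mixture variance — the
  denominator is provably positive, so no draw is rejected. The prior-drawn
  mean plays the role of μ₂.

Mean and variance DE keep the full cell-level log-normal mean perturbation;
the two mixture constructions draw counts from the stated pure ZINB
mixtures, which contain no cell-level term.

### What the generator does and does not emulate

It reproduces subject-level parameter heterogeneity, dropout, overdispersion
and cell-level expression variability for a single cell type with
independent genes. It does **not** model library-size differences, batch
effects, gene–gene correlation, or unequal cells per subject. Passing tests
therefore demonstrate calibration and power under subject exchangeability
with independent genes — not robustness to depth confounding or correlated
gene sets.

## Evaluation

Type-I error and power are proportions of p ≤ α (inclusive) among true-null
and true-DE genes respectively, at α = 0.05 by default, with binomial
Monte-Carlo standard errors; NA genes are excluded from denominators and
counted. The comparison baseline is a two-sided Mann–Whitney U test on
subject-level pseudo-bulk values, aggregated as the **sum** of raw counts
over each subject's cells (the sum being the standard pseudo-bulk
aggregation; mean vs sum is immaterial to ranks when subjects have equal
cell counts). If every pseudo-bulk value ties, p = 1.

## Problem sizes used in the shipped experiments

The calibration experiment uses 400 null genes, 5 subjects per arm, 20
cells per subject and 200 permutations; the power comparison uses 100 genes
per DE type at the largest conventional size factors (r_μ = 4, r_v = 4,
r_p = 0.9, r_m = 0.4) with 10 subjects per arm and 100 cells per subject.
These sizes give Monte-Carlo standard errors on proportions of about 0.01–
0.05 while keeping each experiment in the seconds-to-minutes range.

## Known limitations

* Under the shipped prior the multimodality construction at r_m ≤ 0.4
  produces case/control distributions that are extremely close in total
  variation (≈ 0.02–0.03 at the prior's typical μ ≈ 2, φ ≈ 1): the two
  arms are moment-matched, and at low expression the mixture components
  overlap almost completely. No test can have power much above α there;
  detecting multimodality requires better-separated components, i.e. genes
  with higher expression and lower dispersion than this prior typically
  produces. With a reference-data prior containing such genes, the
  distributional test's advantage over pseudo-bulk baselines on this DE
  type becomes visible.
* The number of histogram bins (100) and the bin-boundary convention are
  package choices; results are insensitive to refinement (mass on coarse
  bins is preserved exactly) but extremely coarse grids will blur small
  shifts.
* p-values are bounded below by 1/(1+N); genome-wide FDR control at small
  q-values needs N well above the default when many genes are tested.
* Permutation assignments are sampled with replacement in the non-exhaustive
  regime; duplicates are harmless to validity.
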
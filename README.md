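# bsde

**Barycenter single-cell differential expression** — a nonparametric test for
finding differentially expressed genes in *case–control* single-cell RNA-seq
studies, where expression must be compared between groups of subjects, not
groups of cells.

## The problem

In a case–control design each subject contributes hundreds of cells, so each
subject has its own *distribution* of expression for every gene. Treating
cells as independent observations ignores subject-level correlation and
inflates false positives; collapsing each subject to a pseudo-bulk summary
(a sum or mean) discards everything about the distribution except location,
and is blind to changes in variance, mixture proportions, or modality.
Parametric mixed models can cover some of this ground but lose type-I error
control under misspecification — common in sparse, heterogeneous, dropout-
ridden single-cell data.

## The method

For one gene within one annotated cell type, with `l` case subjects and `n`
control subjects:

1. Transform counts by `x ↦ log(x + 1)` and build each subject's histogram
   `P_1..P_l`, `Q_1..Q_n` on a common set of breakpoints.
2. Aggregate each arm into its **Wasserstein barycenter**

   P̂ = argmin_μ Σᵢ W₂²(μ, Pᵢ),  Q̂ = argmin_ν Σⱼ W₂²(ν, Qⱼ),

   where W₂ is the 2-Wasserstein (earth mover's) distance with squared-
   Euclidean ground cost. Unlike the arithmetic average of histograms, the
   barycenter respects the metric on the expression axis
   (see `examples/03_barycenter_vs_arithmetic.py`).
3. Test with the statistic **λ̂ = W₂(P̂, Q̂)** and calibrate it by permuting
   subject labels (preserving group sizes), which is valid because subject
   labels are exchangeable under the null:

   p = (1 + #{λ⁽ⁱ⁾ ≥ λ̂}) / (1 + N).

Small cohorts are handled by exhaustive enumeration of label assignments.
Because the histograms are one-dimensional, the package computes barycenters
and distances exactly through quantile functions by default; an
entropy-regularized Sinkhorn backend (the route usually taken for speed in
general OT problems) is provided and validated against the exact solution.

The package also ships the simulation protocol used to study the test's
operating characteristics: per-subject zero-inflated negative binomial
(ZINB) expression with subject-level parameter heterogeneity drawn from a
four-variate Gaussian prior on the transformed scale, and four
differential-expression constructions (mean, variance, mixture proportion,
multimodality) whose size is controlled by a factor `r`, with
moment-preserving parameter maps so that each construction changes exactly
what it claims to change.

## Worked example

```sh
python examples/02_simulate_and_screen.py
```

simulates 60 genes (30% carrying a mean shift at size factor r_μ = 2) for
5 case and 5 control subjects with 50 cells each, screens them, and prints:

```
 gene cell_type  statistic  p_value  q_value  n_case  n_control  ...  status
gene1 simulated   0.508512 0.031746 0.146520       5          5  ...      ok
gene2 simulated   0.440943 0.015873 0.086580       5          5  ...      ok
...
type-I error (null genes, alpha=0.05): 0.024  (n=42)
power (mean-DE genes, r_mu=2)        : 0.833  (n=18)
```

`statistic` is the barycenter distance λ̂ in log-expression units, `p_value`
its permutation p-value, `q_value` the Benjamini–Hochberg adjustment across
the screen. On null genes the rejection rate stays at the nominal level;
on mean-shifted genes the test detects most signals.

The same pipeline is available from the shell:

```sh
bsde simulate --n-genes 100 --n-per-arm 5 --m 50 --de-type variance \
     --size-factor 4 --de-fraction 0.2 --seed 1 --out-prefix sim/
bsde test --counts sim/counts.mtx --genes sim/genes.tsv --barcodes sim/barcodes.tsv \
     --cells sim/cells.tsv --cell-type simulated --case-label case \
     --n-perm 1000 --seed 1 --out results.tsv
bsde evaluate --results results.tsv --truth sim/truth.tsv --alpha 0.05 --out oc.tsv
```

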
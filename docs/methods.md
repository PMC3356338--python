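# Methods

## Problem setting

Given a genes × samples expression matrix with a two-group labeling
(control n₁, treatment n₂) and a collection of gene sets ("pathways"), a
pathway differential-expression test asks whether the joint expression of a
set differs between the groups.  Self-contained tests (sum of t-square,
Hotelling's T²) compare the same set across phenotypes; competitive tests
(GSEA) compare the set against the remaining genes.  Their operating
characteristics — power, false-positive rate (FPR), number of significant
calls — depend strongly on the correlation structure among genes, which is
what the simulators here control.

## Pathway statistics

*Gene-wise statistic.*  The pooled-variance two-sample t,
`t_i = (ȳ_i − x̄_i) / (s_p,i √(1/n₁ + 1/n₂))`.  Genes with zero pooled
variance get `t = 0` with a warning: this keeps the sum-of-t-square statistic
finite and is conservative (an all-constant gene carries no evidence either
way).  The choice of the pooled rather than Welch form follows the
sum-of-t-square test's convention.

*Sum of t-square.*  `Σ_{i∈S} t_i²`; invariant under gene reordering.

*Hotelling's T².*  `T² = (n₁n₂/(n₁+n₂)) d′ S*⁻¹ d` where `d` is the
difference of group mean vectors on the set and `S*` is the pooled
within-group covariance `((n₁−1)S₁ + (n₂−1)S₂)/(n₁+n₂−2)` with its
correlation off-diagonals shrunk toward zero.  The shrinkage intensity is the
analytic optimum for the "diagonal, unequal variance" target,
`λ* = Σ_{i≠j} v̂ar(r_ij) / Σ_{i≠j} r_ij²` clipped to [0, 1], with
`v̂ar(r_ij)` computed from the group-centered, variance-standardized sample
products.  When all sample correlations are exactly zero the ratio is 0/0 and
λ is defined as 1 (fully diagonal), the limiting value.  Shrinkage makes S*
invertible even when the set has more genes than samples; `force_intensity=0`
bypasses it, in which case T² at p = 1 equals the squared pooled t exactly.

*GSEA enrichment score.*  Genes are ranked by descending t (ties broken by
gene order, deterministically).  Walking down the list, a member at rank i
adds `|t_i|^w / N_R` (`N_R` = sum of member weights) and a non-member
subtracts `1/(N − N_H)`; the ES is the running-sum value of maximal absolute
deviation, sign kept.  The weight exponent defaults to w = 1 (the weighted
form standard for this method); w = 0 gives the unweighted Kolmogorov–Smirnov
form.  If the set is the whole list the miss penalty never fires and ES = 1.

## Permutation nulls

Self-contained statistics are scored against sample-label permutations:
labels are uniformly re-assigned (group sizes preserved), the statistic is
recomputed in full — including the shrinkage intensity — and
`p = (1 + #{permuted ≥ observed}) / (1 + B)`.  The add-one estimator never
returns 0 and the test is exact (conservative) under exchangeability for any
statistic.  A consequence worth stating explicitly: on null data where both
groups are identically distributed, the FPR of the permutation Hotelling test
is controlled at *every* pathway size, including p ≫ n.  Size-dependent FPR
inflation of shrinkage-Hotelling tests reported elsewhere can only arise from
non-permutation reference distributions (χ²/F approximations applied to the
shrunk statistic) or from freezing data-dependent tuning at the observed
labeling; neither is done here, so this package's Hotelling test shows no
such inflation — its large-p behavior is instead a mild conservatism as
heavy shrinkage flattens the statistic.

GSEA significance is two-sided on |ES|.  Two nulls are provided:

- **sample-label permutation** (default): the whole ranking is recomputed per
  relabeling, preserving gene-gene correlation.  This is the default because
  the gene-label null is badly anti-conservative when genes within a set are
  correlated — measured here at FPR ≈ 0.67 (α = 0.05) on within-pathway
  correlated null data with ρ = 0.5 — whereas the sample-label null stays
  calibrated on the same data.
- **gene-label permutation** (`gsea_null="gene"`): B random member sets of
  the same size drawn from the ranked universe, equivalent to permuting gene
  labels for a single set.  Exhaustive enumeration over all subsets is
  available for tiny universes.

For the competitive background, simulation type I supplies an explicit null
background data set (the ranked list spans pathway ∪ background genes); for
all other types the complement of the data matrix serves as background.

## Simulators

All entries start iid N(0, 1).  Differential expression is controlled by the
detection call DC ∈ [0, 1]: in each truly-DE pathway the first
`⌈DC·size⌉` genes in gene order receive a treatment-group mean shift of
`effect_size` (default 1).  Using the *first* genes rather than a random
subset makes the shifted subset reproducible and the realized DC exactly
`⌈DC·size⌉/size`.  The shift is applied after any correlation transform, so
the realized mean difference equals the effect size exactly.  DC = 0
everywhere is the null configuration used for FPR estimation.

*Shared-factor correlation.*  `Y = √(1−ρ)·X + √ρ·z` with one standard normal
`z` per sample column added to every gene: every gene pair then has
population correlation ρ while marginal variances stay 1.  ST I applies one
factor globally across pathway and background genes; ST II applies an
independent factor per pathway, giving exactly zero population correlation
between pathways.  At ρ = 0 both reduce to the uncorrelated simulator.

*Network-constrained covariance (ST III/IV).*  For a multivariate normal
vector, zero entries of the precision matrix K = Σ⁻¹ are conditional
independences: the partial correlation is `ρ_ij|rest = −k_ij/√(k_ii k_jj)`.
A covariance is *consistent* with an undirected network when K vanishes on
every non-edge.  Two constructions:

- **Pairwise iterative proportional scaling** (ST IV).  K starts at the
  identity; each sweep updates every edge's 2×2 precision block so the
  implied marginal covariance matches `[[1, ρ], [ρ, 1]]` (rank-two Woodbury
  update of Σ), plus rank-one vertex updates pinning unit variances.
  Off-edge entries of K are never touched, so consistency is exact by
  construction.  Sweeping edges rather than maximal cliques gives the correct
  fixed point on arbitrary (non-decomposable) graphs without clique
  enumeration, at the cost of more sweeps.  Convergence is declared when the
  *constraint residual* — max over edges of |σ_ij − ρ| and over vertices of
  |σ_ii − 1| — drops below `tol` (default 1e-8, max 5000 sweeps); the
  residual criterion is used instead of the sweep-to-sweep change because it
  implies the advertised postcondition directly.  Σ is re-synchronized with
  K⁻¹ once per sweep to control floating-point drift.  Infeasible targets
  (e.g. strongly negative ρ on odd cycles) push K out of the
  positive-definite cone and fail fast with an infeasibility error rather
  than silently shrinking ρ.  For trees the fixed point has the closed form
  σ_ij = Π(edge targets along the unique path), which the tests verify.
- **Alternating projection** (ST III).  From a seeded random SPD matrix with
  unit diagonal, alternate (i) zeroing non-edge precision entries with
  (ii) projection back into the PD cone by flooring eigenvalues at 1e-6,
  then rescale Σ to unit diagonal (a congruence by a diagonal matrix, which
  preserves the precision's zero pattern).  Only the consistency contract is
  promised (tolerance 1e-6); edge correlation strengths are whatever the
  random start yields — typically small in magnitude.

Samples are drawn via the Cholesky factor of Σ with a seeded generator.  For
ST III/IV the treatment mean vector splits each pathway's shifted genes half
at `+effect_size`, half at `−effect_size` (odd counts: the extra gene
positive); overlapping pathways write their assignments in pathway order.

*Default grid.*  Pathway sizes 20–100 in steps of 20, ten pathways per size
(50 pathways, 3000 genes), 7000 additional background genes for ST I, α =
0.05 — all fields of `SimulationDesign`, overridable per configuration.

## Power assessment

Power = fraction of (truly-DE pathway, run) pairs with p ≤ α, pooled over
repeated simulations; the FPR is the same fraction on DC = 0 data.  Error
bars are bootstrap standard deviations of the per-run estimates (200
resamples).  Because the sum-of-t-square branch shares its permutation draws
across pathways within a run (a large constant-factor speedup), per-run
estimates are dependent across pathways; the bootstrap over runs accounts for
this.  Per-size breakdowns are emitted alongside the pooled estimates.
Grid cells derive their seeds deterministically from (master seed, cell
index), so parallel and serial execution produce identical tables, and
individual cell failures are recorded in the table rather than aborting the
grid.

## Surrogate pipeline

For a real labeled matrix no ground truth is available, so the reference
list computed at full sample size stands in: its significant pathways are
scored as positives.  Bootstrap subsamples (with replacement, stratified
within condition so the two-group design and per-condition m are preserved)
are retested at reduced sizes and scored against the reference as
TP/FP/TN/FN; power = TP/(TP+FN), FPR = FP/(FP+TN).  Because the reference
may itself contain false declarations, these are robustness estimates, not
truth-referenced power.  The distance to convergence at a probed size is
operationalized as 1 − power; OLS of distance on sample size predicts the
optimal size at the zero crossing (−intercept/slope), with the regression F
statistic and p-value reported and a zero slope flagged as undefined.
Per-gene detection calls use pooled-t p-values with Benjamini–Hochberg
correction (a plain t + BH stands in for more elaborate per-gene statistics;
no fudge-factor regularization).  Correlation profiling computes each
pathway's mean pairwise Pearson correlation exactly and the global mean
exactly up to 2000 genes, switching to 10⁵ seeded random pairs above that.

## What the synthetic data does and does not show

The generators reproduce the *correlation structure* axis — none, global,
block, network-constrained — with Gaussian margins, constant effect sizes
and exactly known ground truth.  They do not emulate transcription mechanics,
heterogeneous per-gene effect sizes, heavy-tailed or discrete expression
distributions, batch effects, or the GO-derived pathway overlap structure of
real annotation (fixtures use preferential-attachment networks and BFS
neighborhoods as structural stand-ins).  Passing tests therefore demonstrate
correctness of the procedures and their operating characteristics under the
stated models, not performance on any particular real dataset.

## Numerical choices and problem sizes

Tolerances: IPF consistency 1e-8, projection 1e-6, max 5000 sweeps;
symmetry enforced to 1e-10; shrinkage intensity clipped to [0, 1]; p-values
bounded below by 1/(B+1).  Default B = 1000 permutations; the test-suite and
acceptance-script runs use B = 100–200 with 3–5 simulation runs and
100–200-gene universes, sizes chosen so the full assessment remains
interactive on a single CPU while keeping Monte-Carlo standard errors a few
percent.  Known limitations: the projection construction does not control
edge-correlation strength; GSEA's power on ST III/IV data where *every*
pathway is shifted is near the significance level by construction (no
competitive contrast), so its power curves there are flat and
non-convergent.
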
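# Methods

This note documents the statistical procedures `dcoex` implements, the
conventions it fixes where the literature leaves a choice, what the
synthetic-data generator does and does not emulate, and known limitations.

## Shared two-sample framework

All continuous group comparisons (pathology burden, per-gene expression,
per-target protein abundance) use one machinery
(`dcoex._stats.levene_gated_ttest`):

- Levene's test for homogeneity of variance, **mean-centered** by default
  (the original Levene statistic, matching common commercial-package
  behavior; median centering is available via `levene_center`).
- If Levene rejects at α = 0.05 the Welch t-test with Welch–Satterthwaite
  degrees of freedom is used; otherwise the pooled-variance t-test.
- The sign of t follows mean(case) − mean(control). One-sided p-values are
  directed **case > control** (the directed-upregulation hypothesis);
  two-sided values are always carried alongside, and the protein panel
  defaults to two-sided because its targets move in both directions.
- Cohen's d is derived from t via `d = t·√(1/n₁ + 1/n₂)`. This identity is
  the contract the reported effect sizes obey and is regression-tested
  against a battery of published (t, n₁, n₂, d) quadruples.
- Both groups constant: the t statistic is undefined and the result is
  flagged `degenerate` rather than fabricated.

## Exact Mann–Whitney with ties

`mann_whitney_exact` computes the pair-count U with 0.5 credit per tied
pair (equivalent to the midrank rank-sum) and reports the **smaller** of
U₁, U₂ (min convention). The p-value enumerates all C(n₁+n₂, n₁)
assignments of the pooled values (cap 10⁶ assignments, Monte-Carlo with
reported standard error beyond): one-sided p is the proportion of
assignments whose case-vs-control pair count is at least the observed
one, two-sided the proportion with min(U₁,U₂) at most the observed
minimum, so p₁ ≤ p₂ ≤ 2p₁ holds exactly.

The Hodges–Lehmann estimate is the median of all n₁·n₂ pairwise
differences (case − control). Its confidence interval uses the exact
tie-free null U distribution (computed by the classical DP recursion):
k is the largest integer with P(U ≤ k) ≤ (1−conf)/2 and the interval is
the (k+1)-th to (n₁n₂−k)-th ordered difference, with the achieved
confidence level reported (e.g. 97.14% at n = 4,4 — small samples cannot
attain 95% exactly). The rank-biserial effect size is 1 − 2U/(n₁n₂).

## Contingency statistics

The odds ratio applies the Haldane–Anscombe +0.5 correction to **every**
cell unconditionally, with a Woolf interval on the corrected cells
(`exp(ln OR ± z·√Σ1/(cell+½))`). Applying the correction only on zero
cells would change results for non-degenerate tables; the unconditional
convention is fixed and documented here. The risk ratio is the plain ratio
of row risks with the standard Katz log-scale interval
(`SE = √(1/a − 1/(a+b) + 1/c − 1/(c+d))`); zero-risk rows are flagged
rather than corrected. Fisher's exact test (one-sided hypergeometric tail;
two-sided as the sum of tables no more probable than the observed one)
comes from `scipy.stats.fisher_exact`.

## Differential expression

Relative quantities are ratio-scale, so tests run on log₂ values
(variance-stabilizing; the planted fold change is then an exact mean shift)
and fold change is the ratio of group geometric means — one coherent
convention, with a flag raised if a linear-scale analysis produces a
fold-change/t sign disagreement. Outlier screening uses Tukey 1.5·IQR
fences **within group** (a z-score rule is available); screening precedes
the Levene gate, and values flagged here remain available to the network
stage (see below). Genes left with fewer than two values in either group
are excluded with a recorded reason. BH q-values use the standard step-up
`q(i) = min_{j≥i} m·p(j)/j` and are cross-checked against statsmodels in
the tests. The discovery curve counts q-passing genes along a threshold
grid; its "inflection" is the grid point maximizing the discrete second
difference of the count curve — a documented heuristic, not an inference;
the working threshold remains an analyst decision with default 0.2 and
0.05/0.1 columns reported alongside.

## Module scoring

PCA runs on the **gene correlation matrix** (genes sit on heterogeneous
scales, so covariance PCA would let high-variance genes dominate).
Missing entries are group-mean imputed first; standardization then uses
the pooled mean/SD. With more genes than cases the correlation matrix is
rank-deficient — the expected regime — so regression scores use the
Moore–Penrose pseudo-inverse (`scores = Z' R⁺ L`), are standardized to
unit variance so η² and β are comparable across components, and the model
is flagged `rank_deficient`. Component signs are fixed deterministically
(largest-|loading| gene positive). Scree retention keeps components
through the sharpest bend (largest discrete second difference of the
eigenvalue sequence); fixed-k and minimum-proportion rules are available,
and a degenerate flat scree falls back to fixed-k with a warning.

Two-group MANOVA uses Wilks' Λ = |W|/|T| with the exact two-group F,
`F = ((1−Λ)/Λ)·(n−p−1)/p` on (p, n−p−1) df, verified against the
Hotelling T² closed form. Hierarchical regression standardizes all
variables, fits group alone (Model 1) then group + covariate (Model 2),
and tests ΔR² with `F = ΔR²/((1−R²₂)/(n−3))` on (1, n−3) df. Covariate
entries recorded as "unknown" are treated as absent ("no") by default —
a pragmatic choice for sparsely documented clinical covariates — with a
listwise-deletion switch for sensitivity analysis. A covariate collinear
with group is flagged and ΔR² reported as zero rather than fit.

## Networks

Within-group co-expression uses midrank Spearman ρ. For n ≤ 8 the
two-sided p is exact by enumerating all n! permutations of one ranking;
beyond that the t-approximation on n−2 df is used. At n = 5 only |ρ| = 1
is significant at 0.05 (p = 2/120), which makes the novel-edge rule
(|ρ| ≥ 0.9 **and** p < 0.05 in at least one group) effectively a
perfect-monotonicity criterion at that size — a deliberate property of
exact inference at tiny n.

Values excluded from differential expression as outliers are **retained**
for correlations: rank statistics are robust to extreme values and the
variance they carry is informative for co-expression. The two stages
therefore consume different masks of the same matrix.

Edge change tests use the Fisher r-to-z statistic
`z = (atanh r₂ − atanh r₁)/√(1/(n₁−3) + 1/(n₂−3))` (case minus control, so
positive z = strengthened in cases), with |r| = 1 clamped to 1 − 10⁻⁶. The
plain 1/(n−3) variance is the default; the Spearman-specific 1.06/(n−3)
correction is not applied by default because the edge test is specified
simply as the r-to-z transform. Within-group edge significance is
two-sided. Curated edges are never pruned, whatever their correlations;
the novel rule only adds.

Topology follows the NetworkAnalyzer conventions: closeness is the
reciprocal of the mean shortest-path distance ((n−1)/Σd per component),
betweenness is normalized by (n−1)(n−2)/2, heterogeneity is the
coefficient of variation of the degree distribution, and centralization is
Freeman's index `n/(n−2)·(maxdeg/(n−1) − density)`. Disconnected graphs
get per-component path metrics and a flag. All visual encodings (node
fold-change direction, component membership, loading magnitude; edge
source, per-group ρ/p, z-change, solid/dashed significance class) are
exported as typed GraphML/TSV attributes; no drawing is done.

The curated edge list shipped under `data/curated_edges_synthetic.sif` is a
**synthetic, hand-designed** illustrative stand-in (hub-centered, 55
edges over 23 AD-related genes), not a database export; the file name and
`dcoex.fixtures` docstring say so.

## Protein panel and PMI QC

Protein targets reuse the shared framework on the linear abundance scale
(the values are already normalized upstream), with BH applied **within**
each of the four a-priori categories — controlling the false discovery
proportion inside mechanistically coherent domains rather than across the
whole panel. Loading-control totals get an independent per-target
two-sided comparison over a disjoint column, as a QC for differential
loading. Per-target n is derived from data availability after screening
and reported.

PMI QC runs before any outlier removal (the pipeline driver enforces this
ordering) and reports Pearson and Spearman coefficients side by side, with
the rank-based statistic as the headline since heavy-tailed burden and
abundance measures make the rank correlation the more defensible summary.

## Synthetic cohorts

On the log₂ scale a gene with loading λ on its module's latent factor is
`μ + 1{case}·log₂(fc) + σ·(λF + √(1−λ²)ε)`, so the implied within-module
correlation between genes with loadings λ₁, λ₂ is λ₁λ₂, the marginal log₂
SD is σ, and the planted Cohen's d is log₂(fc)/σ. Defaults emulate the
target study conditions: 5 donors per arm, 84 genes, two modules (12 and
8 genes, loadings 0.85/0.8), 20 planted fold changes spanning 1.5–6.7×,
σ = 0.75 (so planted d spans ≈ 0.6–3.7, the moderate-to-very-large range
the small-cohort regime requires to reach significance), 2% missingness,
2% symmetric ±4σ outliers, dual-pathology probability 1.0 in cases vs
0.25 in controls, a covariate present in 60% of cases vs 40% of controls
with a 20% unknown rate, PMI uniform on 5–48 h and independent of all
signal, and a 16-target protein panel with planted d from −5 to +4.6.
The distributional form (log₂-normal multiplicative noise) is a modeling
choice — it keeps values positive and makes the planted fold change the
exact expectation ratio on the log scale — not an empirical claim about
qPCR error. One global seed spawns independent substreams per modality
(expression, proteins, pathology, covariates, corruption), so adding a
modality never perturbs another, and a fixed seed fixes every byte of the
serialized cohort.

What the generator does **not** emulate: amplification-level artifacts
(Ct values, plate effects, normalization-algorithm quirks), spatial
structure in histology, non-log-normal heavy tails, and correlated
missingness. Passing tests on synthetic cohorts therefore validate the
statistical machinery under the stated model, not robustness to every
real-data pathology.

## Problem sizes and numerical choices

Calibration checks use 2,000 simulated null genes (type-I error), 1,000
genes per planted effect size (power vs the noncentral-t closed form,
ncp = d/√(1/n₁+1/n₂)), 400 replicates for permutation-support and r-to-z
null calibration, and graphs of ≤ 12 nodes for exhaustive BFS oracles —
sizes chosen so the whole suite runs in well under a minute of CPU while
keeping Monte-Carlo standard errors a few times smaller than the
tolerances asserted. Exact enumeration caps: 10⁶ group assignments
(Mann–Whitney) and n ≤ 8 (Spearman permutations). Floating-point output
in pipeline reports is fixed at 4 significant decimals so reruns diff
cleanly.

## Known limitations

- The exact Mann–Whitney CI machinery uses the tie-free null U
  distribution for interval inversion; with heavy ties the achieved
  confidence is approximate (the point estimate and p-value remain exact).
- Welch gating via a pretest (Levene) is itself a debated practice; it is
  implemented because it is the convention this workflow standardizes, and
  both one- and two-sided p-values are always reported so the gate never
  hides information.
- At n = 5 per arm the novel-edge rule can only admit perfectly monotone
  pairs; larger cohorts admit |ρ| ≥ 0.9 pairs below perfection.
- Hierarchical regression treats the covariate as binary; graded injury
  severity or other multi-level covariates are out of scope.
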
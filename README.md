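# dcoex

Small-cohort case-control statistics and differential co-expression network
analysis for postmortem molecular data.

## The problem

Postmortem case-control studies of brain tissue often have five or fewer
donors per arm, several modalities measured on the same cases
(immunohistochemical pathology burden, targeted qPCR expression panels,
protein panels), and directed a-priori hypotheses. At these sample sizes
asymptotic tests are unreliable and the analysis has to lean on exact
small-sample statistics, explicit variance-assumption gating, and
effect-size reporting. `dcoex` implements that full multi-stage workflow as
a tested, reusable library:

1. **Pathology** — an ordinal 0/1/2 tau–amyloid colocalization index
   compared with an exact (tie-aware) Mann–Whitney permutation test
   (min-convention U, midrank ties), Hodges–Lehmann shift estimates with
   exact achieved-confidence intervals, rank-biserial effect sizes
   `r = 1 − 2U/(n₁n₂)`, and 2×2 contingency statistics: unconditionally
   Haldane-corrected odds ratios with Woolf intervals, Katz risk-ratio
   intervals, and Fisher's exact test.
2. **Differential expression** — per-gene Tukey-fence outlier screening,
   Levene-gated pooled/Welch t-tests on log₂ relative quantities (one-tailed,
   case > control, by default), geometric-mean fold changes, Cohen's
   `d = t·√(1/n₁ + 1/n₂)`, Benjamini–Hochberg q-values and a discovery
   curve whose elbow guides the working threshold (default q ≤ 0.2).
3. **Module scoring** — group-mean imputation, correlation-matrix PCA with
   regression-method component scores, scree-based retention, two-group
   MANOVA via Wilks' Λ (exact F), per-component η² = F·df₁/(F·df₁ + df₂),
   and two-model hierarchical regression adding a binary covariate
   (ΔR² F-change test).
4. **Networks** — within-group Spearman matrices with exact permutation
   p-values at small n, a curated-plus-novel edge rule (|ρ| ≥ 0.9 and
   p < 0.05 in either group), Fisher r-to-z tests of between-group
   correlation change per edge, NetworkAnalyzer-convention topology metrics
   (degree, betweenness, closeness, clustering, density, characteristic path
   length, heterogeneity, Freeman centralization), and GraphML/SIF/TSV
   export with all visual encodings as data attributes.
5. **Protein panels** — the same gated-t framework per target with
   category-wise FDR (pathology / gliosis / excitatory / inhibitory),
   loading-control QC, and hierarchical regression for significant targets.
6. **Quality control** — postmortem-interval correlations against pathology
   burden, the first expression principal component, and total protein
   abundance, computed before any outlier removal.
7. **Synthetic cohorts** — a generator that emulates the statistical
   structure of such studies (latent-factor gene modules, planted fold
   changes, missingness, symmetric outliers, per-group pathology rates,
   protein effects, a group-associated covariate, signal-independent PMI)
   with a recorded ground truth, so every stage is testable end to end
   without any external data.

## Worked example

```python
from dcoex import ContingencyTable2x2, contingency_stats, index_group_test

res = index_group_test([2, 1, 1, 1], [2, 2, 2, 2])
print(res.U, round(res.p_one, 4), res.hl_estimate)     # 2.0 0.0714 1.0

con = contingency_stats(ContingencyTable2x2(4, 0, 1, 3))
print(round(con.or_point, 1), round(con.or_ci[0], 3))  # 21.0 0.639
```

Here `U = 2` means only two of the sixteen case-control pairs favor the
control arm; the exact one-sided p of 0.0714 is the proportion of the 70
possible group assignments at least that extreme, and the Hodges–Lehmann
estimate says the typical case outranks the typical control by one index
level. The Haldane-corrected odds ratio of 21 (95% CI 0.639–690) quantifies
the dual-pathology enrichment despite the zero cell.

Each capability has a narrative script under `examples/`; for instance
`python examples/differential_network.py` builds the bundled illustrative
network and prints

```
nodes: 23, edges: 77 (55 curated + 22 novel)
density = 0.304, avg neighbors = 6.696
...
hub: APP (degree 17, betweenness 0.408, closeness 0.815)
```

meaning the data-driven rule added 22 high-confidence co-expression edges
to the 55 curated interactions, and APP is the dominant hub reachable from
everywhere in at most three steps.

A thin CLI wraps the full pipeline:

```sh
dcoex simulate --seed 1 --out cohort/
dcoex run --expression cohort/expression.tsv --metadata cohort/metadata.tsv \
          --pathology cohort/pathology.tsv --proteins cohort/proteins.tsv \
          --out results/
```

## Layout

```
src/dcoex/        library (pathology, diffexpr, modules, network, proteins,
                  synthetic, io, pipeline, cli, fixtures)
examples/         one narrative script per capability
tests/            pytest suite incl. acceptance checks
docs/methods.md   statistical methods and design notes
```
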
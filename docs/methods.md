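# Methods

This note documents the models, parameter choices, and numerical decisions
behind `txcensus`, and what the synthetic cohort does and does not emulate.

## The activation test (NB-act)

Autoencoder-based expression-outlier callers model each gene's count
distribution across the cohort and therefore require the gene to be expressed
in a reasonable fraction of samples (operationally: FPKM > 1 in ≥ 5% of
samples). Genes silent in almost every sample — exactly the ones whose rare
*activation* may be oncogenic — fall outside that domain. NB-act covers them
with a parametric tail test: under the null the gene is expressed at no more
than a baseline of 1 FPKM (the conventional expressed/non-expressed
boundary), so the null mean fragment count for gene *g* in sample *s* is
μ = L_g · N_s / 10⁹ with L_g the annotated transcript length and N_s the
per-sample library size. The p-value is P(X ≥ k) for the observed count *k*,
with X negative-binomial of mean μ and size θ.

**Dispersion convention.** θ is the NB *size* parameter, Var X = μ + μ²/θ, so
*small θ means large variance*. The default θ = 0.02 corresponds to the
lowest (most variable) dispersion estimates observed for expressed genes and
is chosen to be conservative: with θ = 0.02 the null leaves ≈ 4.5 × 10⁻³ of
tail mass beyond 50× the baseline mean, so only decisively activated genes
(hundreds-fold over baseline) reach significance after multiple-testing
control. `nbact_pvalue` evaluates the tail through the negative-binomial
survival function (no explicit pmf summation), which is stable for counts up
to at least 10⁶; the test suite verifies agreement with an explicit
log-gamma pmf summation to 10⁻¹⁰ across μ from 0.1 to 1000.

**Multiple testing.** The adjustment scope is not fixed by the method itself;
the package default is Benjamini–Hochberg jointly across all rare-gene ×
sample tests with calls at adjusted p < 0.05, matching the FDR level used for
the expression-outlier caller. Per-sample adjustment is available via
configuration (`nbact_adjust_scope`).

**Gene partition.** With n samples and bound b = ⌈0.05 n⌉: *common* genes
have FPKM > 1 in ≥ b samples (expression-outlier domain), *rare* genes in
1 … b−1 samples (NB-act domain), *silent* genes in none. The partition
requires n ≥ 20, below which the 5% rule degenerates. Boundaries are read
literally: "at least 5%" is inclusive, "fewer than 5%" exclusive.

**Harmonization.** External caller outputs are unified into one call table:
significant expression outliers split by z-score sign into under/over-
expression, splicing outliers by the sign of the delta Intron Jaccard Index.
A significant call with exactly zero effect carries no direction and is
dropped with a warning — a measure-zero event under any continuous effect
distribution.

## Variant filters

Unmatched tumor call sets mix somatic and germline variants. The cascade
keeps PASS calls, drops population variants (gnomAD MAF > 0.05%), and drops
low-VAF calls (VAF < 0.1, enriched for shearing artifacts). The
recurrence-analysis refinement additionally requires VAF ≥ 0.15, ≥ 20
supporting reads, and coding/UTR consequences (impact HIGH/MODERATE/LOW or a
5'/3'-UTR or coding-sequence consequence term). Structural variants require
PASS, ≥ 3 supporting read pairs, no exact-breakpoint population match
(consumed as a precomputed flag), and must not recur in ≥ 4 myeloid *and*
≥ 4 lymphatic entities (the conjunction: recurrence in one lineage alone is
kept, as it may be lineage-specific biology rather than artifact).

Boundary rulings, where only a discard condition is stated, read each
inequality literally: kept at MAF exactly 0.05% and VAF exactly 0.1 / 0.15;
the promoter window is strict (|pos − TSS| < 2000 bp, strand-agnostic); the
splice-affecting prediction cutoff is inclusive (score ≥ 0.2). A variant
absent from the population database is treated as maximally rare (AF 0).
Copy-number overlap is any intersection (≥ 1 bp, half-open intervals); a gene
touching both a "+" and a "−" segment reports both flags.

## Enrichment and variance components

All enrichments are 2×2 Fisher exact tests. Driver and variant-category
enrichments are two-sided; entity association is one-sided (enrichment
direction), as association claims are directional. The reported odds ratio is
the sample cross-product estimate a·d/(b·c); its 95% CI uses the log-OR
normal approximation with a 0.5 continuity correction applied only when a
cell is zero. Degenerate tables (empty stratum or zero margin) are flagged
untestable and emit no p-value. Significance stars follow the conventional
0.05 / 0.01 / 0.001 / 0.0001 scale.

Recurrence strata default to {1, 2–5, >5} called samples per gene (distinct
samples, per category); the interior edge is configurable since only the
outer stratum is canonical. The top-k-per-sample restriction (default k = 3,
per category) counters samples with pathologically many outliers; ties break
stably by (p ascending, |effect| descending, gene ID ascending).

Variance components fit, per gene, an OLS model of the corrected expression
z-score on four genomic predictors — log copy ratio, then binarized
high-impact, promoter, and structural-variant indicators — and take
*sequential* (type-I) sums of squares in that order, the order chosen to let
copy ratio, the dominant driver of expression aberration, absorb shared
variance first. Fractions are normalized to sum to one over the predictors;
`include_residual=True` adds the residual to the denominator instead. A
constant predictor column contributes 0 rather than failing.

## Driver-gene model

The feature matrix has 85 columns in five blocks: 21 mutational-recurrence
features (score = −log₁₀ p, q-value, and within-cohort rank for each of 7
tools), 9 splice-prediction features (distinct-sample counts at score
cutoffs 0.01–0.95), 22 expression-outlier features ({up, down} × {nominal,
adjusted p < 0.05} × |z| ≥ {0, 2, 3, 4, 5} plus two totals), 11 activation
features (adjusted-significant counts at fragment-count cutoffs 0–2000 plus
a nominal total), and 22 splicing features (as expression with |Δ Jaccard| ≥
{0, 0.05, 0.1, 0.2, 0.3}). These grids are this package's defaults — the
block *sizes* are canonical, their exact composition is configurable
(`FeatureConfig`) — and counts are non-increasing along each nested cutoff
grid by construction, which the tests assert. Absence of events encodes as 0
(worst rank / q = 1 for recurrence).

The classifier is a random forest with `min_samples_split=19`,
`max_depth=10`, and library defaults otherwise, evaluated by average
precision under stratified five-fold cross-validation repeated with 10
deterministic seeds. Only out-of-fold probabilities (averaged over repeats)
are used for ranking; the top-k genes are categorized as reported hematologic
drivers, reported cancer drivers, or candidates, with a Fisher enrichment of
truth among the top-k. Benchmarks against recurrence-only prediction are
expressed as feature-ablation runs of the same pipeline (`ablate_block`).

## Entity association and the validation caller

Association tests, per gene and entity, the 2×2 table {called vs not} ×
{in-entity vs not} over samples (distinct samples; one-sided, greater), BH-
adjusted across all tests of a category, significant at adjusted p < 0.05.
Per-entity activation fractions are distinct activated samples over entity
size, reported as percentages rounded to one decimal.

The validation-cohort caller normalizes counts by median-of-ratios size
factors (reference = per-gene geometric mean over genes with no zero count;
this is the standard DESeq2 estimator, so a doubled sample has exactly twice
the factor of its peers, with the factors' geometric mean at 1), transforms
as log₂(x + 1) (the pseudocount accommodates zeros), and fits a two-component
equal-variance Gaussian mixture by EM with deterministic initialization:
means at the 10th/90th percentiles, equal weights, pooled variance;
convergence when the log-likelihood gain falls below 10⁻⁸ or after 500
iterations. Samples hard-assigned to the higher-mean component are
activated, which makes the call invariant to component relabeling. All-equal
input is reported as degenerate with no activation. The EM log-likelihood
trace is retained and asserted non-decreasing.

## Synthetic cohort

The generator emulates the study conditions: a six-entity miniature of the
cohort design (three myeloid, three mature-B entities, including a rare
HCL-V-like entity of 29 samples; 398 samples total by default), library
sizes log-uniform on [10⁷, 10⁸] (typical total-RNA-seq depth), NB counts
with generator dispersion θ = 10 (ordinary biological overdispersion —
distinct from the test's deliberately heavy-tailed null). Common genes
(half the pool) express around 5 FPKM with 0.5-log-normal gene effects; rare
genes express at 3 FPKM in ~1% of samples, keeping them inside the rare
partition. Planted activations default to 1000 FPKM: under the θ = 0.02 null
a planted event then carries p < 10⁻⁷ and survives BH decisively, which is
what a genuinely activated gene looks like (a 50-FPKM bump has tail mass
4.5 × 10⁻³ and is intentionally below the test's detection floor under FDR
control — the conservatism is the point). The variant fixture enumerates the
full cross of filter branches with truth flags written at construction, so
filter tests are exact, not statistical. Caller-output tables plant driver
signal as Poisson event-rate shifts (rate 0.5 → 0.5 + strength) and
recurrence p-values as u^(1+strength); the validation cohort draws log-scale
values from the stated mixture (means 1 and 6, sd 0.7, n = 42 with 5/14 and
5/28 activated) and maps them to the count scale as 2^y − 1.

What the generator does **not** emulate: read-level data (no junction
counts, coverage tracks, or fragment-length structure), covariation between
genes (no batch effects or co-regulation, hence nothing for an autoencoder
to correct), splice-outlier internals (splicing is emulated at the call
level only), and linkage between the variant fixture and the count matrix.
Passing tests therefore demonstrate the correctness and calibration of the
statistics and plumbing on data matching their stated assumptions — not
robustness to the confounders of real cohorts.

## Problem sizes and numerical choices

Default test/verification scales: null calibration at 500 rare genes × 100
samples × 20 seeds (10⁶ tests); oracle grids at 5 means × 5001 counts;
driver-model experiments at 2000 genes with 50 planted drivers (prevalence
2.5%), 5 folds × 10 repeats. Exact-test checks enumerate 2×2 tables with
margins ≤ 30 using exact rational arithmetic. Internal coordinates are
0-based half-open; TSV inputs are 1-based inclusive and converted on read.
All randomness flows through explicit seeds; repeated runs are byte-stable.

## Known limitations

The activation test assumes the annotated length and library size fully
determine the null mean — no GC or mappability correction, no pooled
dispersion estimation. The NB-act adjustment scope and the exact feature-grid
composition are configurable defaults, not canonical values. Entity
association ignores study-group structure (each entity is tested against the
rest of the cohort). The EM caller fits a single gene at a time and does not
share variance information across genes.
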
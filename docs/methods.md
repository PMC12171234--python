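# Methods

## Scope and data model

txmeta synthesizes treatment effects (ELS versus control log2 fold
changes) on gene expression across several small rodent studies of the
prefrontal cortex, measured on heterogeneous platforms (log2-intensity
microarray-style tables and RNA-seq counts) in two species (mouse, rat).
Per-study results are re-keyed to a harmonized, mouse-anchored gene key
through an ortholog table before synthesis; genes without an ortholog
entry for a study's species are dropped from that study and logged.

## Quality control

**Sample outliers.** The criterion is a nearest-median-comparator Tukey
fence on the sample-sample correlation matrix: for each sample *s*, find
the comparator *c* ≠ *s* whose median correlation is closest to *s*'s, and
flag *s* if its median falls below Q1 − 1.5·IQR of *c*'s correlations. The
published rule this operationalizes ("adjusted median correlation outside
the comparator's interquartile range") is stated only loosely, so both the
fence multiplier and the correlation type (Spearman by default, Pearson
selectable) are configurable. Whether the rule is applied once or repeated
is equally unstated; we iterate to a fixed point — flagged samples are
removed and the rule reapplied on the remaining submatrix, which needs no
recomputation because correlations are pairwise. With fewer than four
samples no flagging is attempted. Count matrices are transformed to
log2-CPM (offset 0.5) first, since correlations of raw counts are
dominated by library size.

**Gene filter.** Rows with zero variance, or with fewer than 70% distinct
values across samples, are removed and logged with their reason. The
filter is idempotent.

**Diagnostics.** PCA follows `prcomp(t(x), scale = TRUE)`: genes centered
and scaled to unit variance, SVD on the sample × gene matrix, top four
components reported with their associations to treatment, sex, batch and
log10 library size (point-biserial for binary covariates, correlation
ratio for multi-level ones). Batch-by-treatment cross-tabulations flag any
batch level wholly contained in one treatment group as a perfect confound.
Neither diagnostic gates the pipeline; like the source analysis, they
inform model choice rather than automate it.

## Per-study differential expression

Designs are `Intercept + Treatment` for simple studies and
`Intercept + Treatment + LibrarySize + Sex` for the one covariate-bearing
design. Treatment is coded reference = 0, ELS = 1; library size enters as
log10 of the per-sample total, since raw totals dominate the design
numerically. Gene-wise (weighted) least squares gives the coefficient
vector, the unscaled SD u_g of the treatment coefficient (the square root
of the corresponding diagonal of (XᵀWX)⁻¹), residual variance s²_g on d_g
degrees of freedom, and average expression A_g.

**Moderation.** The prior (d₀, s₀²) is estimated by moment matching on
log variances: e_g = log s²_g − ψ(d_g/2) + log(d_g/2) has mean
log s₀² − ψ(d₀/2) + log(d₀/2) and excess variance ψ′(d₀/2) beyond its
sampling variance ψ′(d_g/2). The mean is a lowess curve of e against A_g
(span 0.5) for intensity data — the abundance-dependent-prior strategy —
or a scalar otherwise; the excess variance is inverted through ψ′ by
Newton iteration. This closed-form route is deterministic and needs no
optimizer. Non-positive excess variance yields d₀ = +∞ (complete pooling;
moderated statistics then use the normal distribution). Posterior
variances are s̃² = (d₀s₀²(A) + d s²)/(d₀ + d), moderated t is
β̂/(u·s̃), and the standard error carried into meta-analysis is defined as
SE = u·s̃ (equivalently |log2FC|/|t|) — the sampling-variance extraction
is not spelled out in the source analysis, and this is the standard
construction.

**Count data.** Counts are converted to
log2-CPM = log2((count + 0.5)/(library + 1)·10⁶). An initial unweighted
fit gives residual SDs whose square roots are lowess-smoothed against mean
log2 count; each observation's precision weight is the inverse fourth
power of the trend value at its fitted log2 count. The weighted fit is
then moderated with a scalar prior. No sample-quality weights are used.

## Random-effects synthesis

Genes present in at least 4 of 5 studies enter the meta-analysis. Per
gene, τ² is estimated by REML Fisher scoring started at the
DerSimonian-Laird value, floored at zero, tolerance 1e-8, at most 100
iterations. The raw Fisher update oscillates on some problems; steps that
fail to improve the restricted likelihood are halved until they do, which
restores monotone convergence without changing the fixed point (spot
checks against R's `metafor::rma(method = "REML")` agree to ~1e-5 on
estimate, SE and τ²; a τ²-grid oracle at step 1e-5 agrees within 1e-4). If
the iteration still fails, the DerSimonian-Laird estimate is used and the
gene flagged as a fallback; genes whose fit fails under both estimators
are "unstable", reported separately and excluded from the
multiple-testing family.

Inference is on z = μ̂/SE(μ̂) with normal tails and a CI multiplier fixed
at 1.959964, matching the defaults of standard meta-analysis software and
the printed-CI arithmetic of the reference results. BH FDR is a hand-rolled
step-up that accepts a family size m larger than the supplied p-vector, so
printed result subsets can be adjusted inside their original family; it is
cross-checked against statsmodels and an O(m²) oracle in the tests.

**Known limitation — small-k coverage.** With k = 5 studies and moderate
heterogeneity (τ ≈ 0.1 against sampling variances of 0.002–0.05), z-based
random-effects intervals genuinely undercover: Monte Carlo puts true
coverage near 0.90–0.91, not 0.95, and this package reproduces that
property because it reproduces the method. Knapp-Hartung adjustments would
widen the intervals but are deliberately not used, to stay faithful to the
reference analysis.

## Gene-set enrichment

Genes are ranked by meta-analytic z (the pooled estimate is selectable; the
reference analysis does not state its ranking input), ties broken by gene
key for determinism. The enrichment score is the weighted KS running sum
with weight exponent 1: members add |r|/Σ_set|r|, non-members subtract
1/(N − set size); ES is the signed extremum and the leading edge the
members at or before (positive ES) / after (negative ES) the extremum. The
implementation evaluates only the candidate values immediately before and
after each member position (the walk is piecewise monotone between
members) and is tested for exact agreement with an explicit cumulative
walk. The null is simple seeded gene-sampling: same-size random draws from
the ranked background, shared across sets of equal size;
p = (1 + #{same-sign nulls ≥ |ES|})/(1 + #same-sign nulls) and
NES = ES / mean(|null ES| of that sign). This trades resolution at extreme
p-values (floor 1/(n_perm + 1), default n_perm = 10,000) for exact
reproducibility; the adaptive multilevel scheme of the fGSEA tool is not
implemented. GMT collections can be trimmed by provenance label
(case-insensitive substring on the description field), intersected with
the ranked background, and bounded to sizes 10–1000 by default.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
with defaults fixed to the emulated cohort: five studies with per-group
sizes (12,11), (22,24), (3,4), (5,5), (3,3) — the two studies with
injected outliers (2 and 1) reduce to the published final group sizes —
two species, one covariate-bearing design, and one count-based study (the
one analyzed with precision weights; the other RNA-seq studies are
generated as log2-scale tables, mirroring their trend-based analysis).
Gene baselines are N(7, 2²) log2 units. A fraction (default 0.1) of genes
carry a true effect δ_g ~ N(0.5, 0.2²) log2 units, realized per study as
δ_gi = δ_g + N(0, τ²) with τ = 0.1 — the reference analysis reports no
heterogeneity estimates, so the default τ is a generator choice, not a
published value. Intensity noise has SD decreasing logistically with
baseline (residual SD 0.3–0.6, reproducing the mean-variance trend the
moderation stage must absorb); counts are negative-binomial with mean
2^(baseline+effect)·library/10⁶ and dispersion following a 1/mean trend
plus a floor of 0.05. Outliers are made by adding independent Gaussian
noise sized to attenuate a sample's median correlation by a target amount
(constant shifts barely move correlations). Ten percent of genes are
removed per study at random to exercise the presence filter; a
configuration under which no gene could reach k − 1 studies fails
explicitly.

What the generator does not emulate: probe-level microarray artifacts,
read-level count generation, GC/length biases, correlated gene modules,
batch structure beyond a simple two-level offset, and outliers that are
shifted rather than decorrelated. Passing tests therefore demonstrate the
statistical machinery under the model's own assumptions, not robustness to
every failure mode of real GEO data.

## Problem sizes and determinism

Tests and the acceptance script run cohorts of 500–2,000 genes, 100–200
simulation replicates per property, and permutation counts of 200–1,000 —
sizes at which every Monte Carlo bound tested has comfortable sampling
slack while the whole suite stays fast. All randomness flows from
numpy `Generator`s; the pipeline expands one global seed into per-stage
seeds through `SeedSequence` spawn keys, so full runs and stage re-runs
from saved intermediates are byte-identical. TSV round trips parse floats
in round-trip mode for the same reason.
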
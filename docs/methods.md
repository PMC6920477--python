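# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of `sdtx`.

## Study design and data model

The package analyses repeated-measures expression cohorts with three
clock-time-matched morning samples per subject: T1 (before therapeutic
sleep deprivation), T2 (after the ~36 h vigil) and T3 (after recovery
sleep), from three groups — treatment responders, non-responders and
healthy controls. Expression values are log-scale intensities for a fixed
gene universe; dropout is represented by absent rows (available-case
analysis throughout, no imputation), and T3 samples from subjects flagged
as recovery-sleep protocol violators are excluded from trajectory
analysis. Sample metadata carry subject id, timepoint, group, age, sex and
the violation flag; group and sex must be constant within subject.

## Quantile normalization

Each sample's empirical distribution is replaced by the across-sample mean
of order statistics; ties within a sample receive the mean of the tied
reference quantiles. This makes the value multiset identical across
samples (exactly, for tie-free data) while preserving within-sample rank
order, and it is idempotent. Normalization is applied jointly across all
timepoints by default (configurable), since the downstream models compare
values across timepoints. Probe-level background correction is out of
scope: the pipeline ingests gene-level matrices.

A caveat the worked example makes visible: with small gene universes and
strongly asymmetric differential expression, forcing identical per-sample
distributions redistributes part of the shift onto unaffected genes
(spillover calls of opposite sign). At transcriptome scale (~25k genes)
the effect is negligible; recovery tests therefore run on unnormalized
matrices or balanced designs.

## Per-gene longitudinal contrasts (M1–M3)

For each gene, two nested linear mixed models are fitted by **maximum
likelihood** (not REML — the LRT compares fixed-effect structures) on the
T1/T2 samples:

* h0: expression ~ intercept + age + sex(F) [+ group, + time for M2/M3]
  + subject random intercept;
* h1: h0 + the tested term — the T2 indicator (M1) or the group × T2
  interaction (M2: responder vs non-responder, patients only; M3: patient
  vs control).

The tested term always adds exactly one fixed-effect parameter, so
Λ = 2(ℓ₁ − ℓ₀) is referred to χ²(1), two-sided by construction. Reference
levels are non_responder (M2) and control (M3); timepoint is coded T1=0,
T2=1, so a positive estimate means higher expression at T2 (M1) or a larger
T2−T1 change in responders/patients (M2/M3). Benjamini–Hochberg q-values
are computed per contrast across converged genes. Baseline group
differences use T1-only ordinary least squares (expression ~ group + age +
sex) with a Wald test on the group coefficient.

**Fitting engine.** Both models are fitted with a profiled-likelihood
engine (`sdtx.mixedlm`): for a fixed variance ratio γ = σ_u²/σ_e², the GLS
coefficients and the profiled σ_e² are closed-form via the Woodbury
identity (all dense algebra is q × q, q = number of random effects),
leaving a bounded 1-D optimisation over log γ (Brent, xatol 1e-10). γ = 0
is representable, so a singular fit degenerates *exactly* to OLS with the
OLS log-likelihood — the boundary case needs no separate refit path, only
a flag. The engine reproduces statsmodels MixedLM (ML) log-likelihoods to
~1e-8 on single-grouping data (asserted in tests); a custom engine is used
because the set-level model below requires crossed random effects, which a
single-grouping-factor fitter cannot express, and because sharing one
engine keeps per-gene and set-level inference consistent (it is also ~10×
faster per gene, as the design cross-products are computed once per
contrast and reused across genes).

On balanced two-timepoint data the time LRT collapses to the closed form
Λ = n·log(1 + t²/(n−1)) with t the paired t statistic on subject
differences (the between-subject covariates cancel in the difference
component, and for an interior optimum σ̂_u² > 0 the within/between parts
of the likelihood are variation independent). The test suite verifies the
engine against this closed form to |Δp| < 1e-6 and against the plain
paired-t p at the loose tolerance appropriate for two tests that share a
statistic but use different reference distributions (χ²(1) vs t_{n−1}).

Degenerate genes (zero variance) yield `converged=False` with p = 1 and
are excluded from FDR; they never raise.

## Circadian panel and Monte-Carlo over-representation

The packaged panel holds 23 unique symbols: ten canonical clock genes
(PER1, NR1D2, PER3, NR1D1, PER2, ARNTL, NPAS2, CLOCK, CRY2, CRY1, in
decreasing signal-to-noise for predicting circadian rhythmicity) and
thirteen further blood-rhythmicity predictors (DDIT4, CLEC4E, FKBP5,
DAAM2, TPST1, IL13RA1, SMAP2, HNRNPDL, FOSL2, FLT3, CDC42EP2, TMEM88,
RBM3); PER1 and NR1D2 appear on both source lists and are de-duplicated.
A user panel file can override it.

The Monte-Carlo test draws B (default 10,000) same-size gene sets without
replacement from the analyzed universe and counts draws with at least the
panel's number of genes at p < 0.05 uncorrected (the in-test threshold is
deliberately uncorrected and independent of the pipeline FDR level);
p_emp = (exceed + 1)/(B + 1). Because the null is draw-without-replacement,
it *is* hypergeometric, and the exact tail P(X ≥ obs | N, K, m) is always
reported alongside as a cross-check (agreement within 3 Monte-Carlo SEs is
asserted over randomized instances). Panel genes absent from the universe
are dropped with m reduced and reported.

## Preranked gene-set enrichment

Scores are direction · (−log10 p) (p floored at the smallest positive
float), sorted descending with ties broken by symbol. For a set of m genes
in a list of N, the running sum increments by |score|^w / Σ|score|^w at
hits and decrements by 1/(N−m) at misses; ES is the extreme deviation
(magnitude ties between the positive and negative extreme resolve to the
positive one, tolerance 1e-12). The weight default is w = 1; w = 0 gives
the unweighted KS form, under which ES is invariant to positive rescaling
of scores and antisymmetric under list reversal (both asserted).

The null is gene-label permutation of set membership (the only scheme
available to preranked input): B random same-size subsets of the list
(vectorised; default B = 1000). The permutation p is one-sided within the
sign of the observed ES with add-one smoothing; NES = ES divided by the
mean |null ES| of matching sign. Two FDRs are reported: the classical
positive/negative-pooled NES-based GSEA FDR, and within-direction BH on
permutation p-values (`q_bh`). Sets with no member in the list, or
covering it entirely (miss decrement undefined), are skipped.

## Time-course gene-set analysis

For each gene set, genes are standardized per gene over the analyzed
cohort (z-score), stacked, and fitted with two nested mixed models by ML:

* h0: value ~ gene-specific fixed intercepts + subject random intercept;
* h1: h0 + shared categorical timepoint effects (T2, T3 vs T1) +
  gene-specific random time deviations — one iid variance for the
  per-(gene, T2/T3) departures from the shared trend.

Subject intercepts and gene-time deviations are crossed random effects;
the 2-D profiled optimisation uses Nelder-Mead on (log γ_subject,
log γ_gene-time) from three starts. Timepoints are categorical (only three
exist; no spline basis). h1 adds two fixed-effect parameters plus one
variance component that sits on the boundary of its space under the null,
so the default reference is the Self–Liang 50:50 mixture
χ²(2) : χ²(3) — chosen on asymptotic grounds; a plain χ²(2) (slightly
anticonservative) and a within-subject timepoint-permutation null (exact
by construction; only h1 needs refitting per permutation, since h0 has no
time term) are available via `reference=`. At the calibration scale used
in the tests (10-gene sets, 20 subjects, 500 simulations) the mixture
reference rejects at 0.048 at the 0.05 level; permutation and parametric
p-values agree in rank order (Spearman ρ > 0.8) across graded effect
sizes.

Sets with fewer than two usable genes or three subjects, or whose
optimisation fails, are reported `converged=False` with a reason string
and excluded from the per-cohort BH correction; a collection run warns and
continues. The analysis is run separately per cohort (patients, controls,
responders, non-responders), q-values within cohort.

**Trends.** Per gene: median standardized expression over the cohort's
subjects at each timepoint, minus the T1 value (first column exactly
zero). Genes are grouped by agglomerative hierarchical clustering of their
trend vectors (Euclidean, complete linkage; default cut at ≤ 5 clusters
per set — the display convention, not an inferential choice) and each
cluster is displayed as its median trend. Heatmaps use a red-up/blue-down
diverging palette centred at zero, rows ordered by hierarchical
clustering; specific sets can be excluded from display (e.g. visually
non-homogeneous ones); rendering is byte-deterministic, and an empty-state
placeholder is written when nothing is significant.

## Synthetic cohort generator

The generator is the package's test bed and defines its study conditions:

* **Design**: 60 responders, 16 non-responders, 15 controls, participating
  60/56/53, 16/16/13, 15/15/15 at T1/T2/T3 → 91 + 87 + 81 = 259 samples,
  169 from responders. Dropout is missing-at-random within group (which
  subjects participate at a timepoint is a uniform seeded draw — only the
  counts are specified by the design, not the mechanism). Two patients
  with T3 samples are flagged as protocol violators.
* **Model**: value = per-gene baseline (N(7, 1) log-intensity) + subject
  intercept N(0, 0.5²) + optional per-gene age/sex covariate effects + sum
  of applicable injected effects + residual N(0, 0.3²). All effects are
  additive on the log scale. σ_u = 0.5 and σ_e = 0.3 were chosen as
  typical of between-subject vs within-subject variability on log-intensity
  arrays (intraclass correlation ≈ 0.74).
* **Ages** are drawn N(43.5, 14.8²) for patients and N(40.5, 15.9²) for
  controls, truncated to [18, 80]; sex is Bernoulli with the per-group
  male fractions of the design table.
* **Effects** (`EffectSpec`): time_main, group_by_time, baseline_shift and
  set_coherent_trajectory, each with a per-timepoint profile zeroed at T1,
  a magnitude in log units and an optional group restriction. A truth
  table maps every gene × contrast to its injected status; by convention
  each effect kind flags exactly one contrast (its designed target), so
  recovery tests inject one kind at a time.
* The first 23 gene names are the circadian panel symbols (switchable), so
  panel analyses run against simulated data.

What the generator deliberately does **not** emulate: probe-level noise
and array artifacts (e.g. globin interference), count-based distributions
(values are Gaussian on the log scale by design), gene–gene correlation
beyond shared injected effects, and medication or clinical covariates.
Passing tests therefore demonstrate correctness and calibration of the
statistics under the design's sampling structure — not robustness to
array-specific artifacts or real biological covariance.

## Problem sizes and runtime

Tests and the acceptance script use scaled-down universes chosen to keep a
full run within minutes on one CPU while leaving every statistical check
well-powered: 2000 genes for type-I error (binomial SE ≈ 0.5 %), 500 genes
with 50 true effects for interaction recovery over three seeds, a 200-gene
list with 2000 random sets for enrichment calibration, 500 simulated null
sets for trajectory calibration, and 20 seeds for trajectory power. The
original study's 24,733-gene universe changes only the constant factor of
the per-gene loop (~15 ms/gene), not any statistical property.

## Known limitations

* ML-based LRTs are mildly anticonservative at very small cohort sizes;
  the engine provides no small-sample (Kenward–Roger-style) correction.
* No moderated/empirical-Bayes variance shrinkage and no random slopes —
  the per-gene model is exactly the random-intercept LRT described above.
* The classical pooled GSEA FDR can be noisy with few sets per sign; the
  BH-on-permutation-p variant is reported alongside for that reason.
* The set-level model fixes the random-effect structure (iid gene-time
  deviations); richer covariances (per-gene trends correlated across
  timepoints) are not expressible.
* Trend cluster count is a display convention (≤ 5 per set), not estimated
  from the data.
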
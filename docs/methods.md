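# Methods

## Overview

`frogclock` implements the statistical core of a cross-species DNA
methylation aging study: penalized-regression age estimators ("epigenetic
clocks") for the two clawed frog species *Xenopus laevis* and *X.
tropicalis*, alone and jointly with humans; per-species epigenome-wide
association studies (EWAS) of age with meta-analysis; and set-enrichment
analysis of the age-related CpGs.  Because the package is exercised on
synthetic cohorts, this note describes both the analysis model and what the
simulator does and does not emulate.

## Age scales

Chronological age enters the models on one of three scales.

**Identity** — age in years, used for the single-species clocks.

**Log-linear** — a continuous two-piece transform anchored at the species'
age of sexual maturity `m` with offset `k > 0`:

    F(a) = log((a + k) / (m + k))   for a <= m
    F(a) = (a - m) / (m + k)        for a >  m

`F(m) = 0` and both one-sided derivatives at the knot equal `1/(m+k)`, so
`F` is C1 and strictly increasing; its inverse is closed-form.  The log
region stretches embryonic and larval ages — the frog cohorts contain
whole-embryo samples as young as two days — so that a squared-error
regression does not collapse them against decade-old adults, while adult
ages advance linearly.  In effect the clock "ticks faster" before sexual
maturity, and the speed is calibrated per species through `m`.  The offset
defaults to `k = m/5`; it bounds the log singularity away from age zero and
is configurable.  Inverting a score below `F(0)` would place an age before
fertilisation; such predictions are returned raw with a warning rather than
clipped.

**Relative** — age divided by the species' maximum recorded lifespan `L`
(laevis 30.3 y, tropicalis 16 y, human 122.5 y), a dimensionless fraction
normally in [0, 1] that aligns species of very different lifespan on one
axis.  Predictions on this scale are reported raw, not clipped to [0, 1].

Registry defaults: maturity 1 y (laevis), 0.375 y (tropicalis), and 13.5 y
for humans.  The human maturity constant is a package default (the clocks
are insensitive to its exact value because the human age range dwarfs it);
all constants are configurable through the species registry.

## Clocks

A clock is an elastic-net linear model on beta values with mixing parameter
alpha = 0.5, fixed midway between ridge and lasso by convention rather than
tuned.  The penalty strength is selected by an internal 10-fold
cross-validation minimising mean squared error on the *transformed* age
scale (the selection scale is a package choice; the transformed scale is
the one the loss is defined on).  Seven clock specifications are built in:

| clock          | samples              | response    | outer CV        |
|----------------|----------------------|-------------|-----------------|
| pan            | both frog species    | log-linear  | leave-one-out   |
| relative_pan   | both frog species    | relative    | leave-one-out   |
| young          | frogs, age < 2 y     | log-linear  | leave-one-out   |
| laevis         | X. laevis only       | identity    | leave-one-out   |
| tropicalis     | X. tropicalis only   | identity    | leave-one-out   |
| dual_chrono    | frogs + humans       | log-linear  | 10-fold         |
| dual_relative  | frogs + humans       | relative    | 10-fold         |

Before fitting, CpGs are restricted to the "detectable" set: mean beta over
the training samples within [0.05, 0.95] (bounds configurable).  CpGs
saturated at the rails carry no usable dynamic range.  Missing betas are
resolved by dropping the CpG (default) or imputing its mean — a package
policy, since array data normally arrive complete.

Predictors are standardised internally during fitting, as glmnet does, but
the reported coefficients and intercept are folded back to the raw beta
scale: a saved clock is one sparse linear formula on betas plus its
transform parameters, and a prediction is the inverse transform of the
linear score under the sample's own species parameters.  Training samples
are put in a canonical (lexicographic) order before fitting so the model is
exactly invariant to the order samples arrive in.

Accuracy is estimated by outer cross-validation with every step — the
detectability filter, standardisation and inner penalty search — refit
inside each training fold, so held-out predictions are untouched by their
own sample.  Frog-only clocks use leave-one-out CV (matching the small n);
the dual clocks use 10-fold CV with folds assigned by a seeded shuffle
stratified by cohort, so every fold contains both human and frog samples.
Reported metrics are the Pearson correlation R between predicted and
observed age and the **median** absolute error (years, or relative-age
units for the relative clocks).

Numerical settings: the penalty path has 50 values spanning three decades
below the critical penalty (sklearn defaults), coordinate-descent tolerance
1e-3.  At that tolerance the inner-CV error curve is flat below roughly
0.4% of the maximal penalty, which places a floor of about 0.5% relative
shrinkage on noise-free predictions; this is far below the noise level of
any realistic cohort and is documented here because the test suite
exercises exact-recovery cases against it.

## EWAS of age

Within each species, every CpG is screened by the Pearson correlation `r`
of its beta values with chronological age (in years, untransformed).
Significance uses the exact t statistic `r*sqrt(n-2)/sqrt(1-r^2)` with
`n-2` degrees of freedom; the two-sided p-value is converted to a signed
standard-normal equivalent `z = sign(r) * Phi^{-1}(1 - p/2)`.  Tissue is
ignored within species — the deliberate choice for cohorts of 30–35
samples, where per-tissue strata would be tiny; a stratified variant
(per-tissue screens Stouffer-combined across tissues) is available but off
by default.  Correlations of magnitude 1 have their p floored at 1e-300 so
z stays finite in rankings.  Zero-variance CpGs are emitted flagged
(r undefined) and excluded from ranking and meta-analysis.

Species-level screens are combined over the shared CpGs by Stouffer's
equal-weight method, `z_meta = (z_1 + ... + z_k)/sqrt(k)`, standard normal
under the joint null.  Hit counts are reported at the genome-wide
(p < 1e-7) and suggestive (p < 1e-5) thresholds, fixed cutoffs used as-is
with no further multiplicity adjustment.  A helper correlates two z
vectors over their shared CpGs (with its two-sided p) for cross-study
comparisons, e.g. against an externally supplied mammalian EWAS of age.

## Enrichment

From an EWAS table the top k = 500 CpGs with positive and with negative age
correlation are selected (ranked by z; ties broken lexicographically by CpG
id so selection is deterministic).  Each list is intersected with every
named annotation set over the restricted background — the CpG universe
actually analysed, not the whole array, so enrichment is not confounded by
platform design.  With background size N, set size K, selection size n and
overlap k, the enrichment p-value is the one-sided upper tail
`P(X >= k)` for `X ~ Hypergeometric(N, K, n)`; effect size is the sample
odds ratio of the 2x2 table with the Haldane–Anscombe 0.5 correction when
any cell is empty (the conditional-MLE estimator would also be defensible;
the sample OR is simpler and reproducible).  Depletion is read off OR < 1,
with the complementary lower-tail p emitted alongside.  The report's
display column is `-log10(p)` signed by the direction of the odds ratio.

## QC clustering

Samples are compared by `1 - Pearson correlation` of their beta profiles
(pairwise-complete over missing values) and clustered by average linkage
(UPGMA, via scipy; its tie-breaking between equidistant merges is
deterministic though not specified beyond that).  Cutting the dendrogram at
a height threshold yields branch labels, numbered by first appearance in
leaf order; a cut uses merges *strictly* below the threshold, so a cut at 0
returns singletons.  The package labels branches and leaves outlier
exclusion to the analyst — no automatic exclusion rule is applied.

## Synthetic cohorts

The generator emulates the study's sampling design so the whole pipeline is
testable without external data:

* **Design** — 35 *X. laevis* (ages 0.005–19 y) and 30 *X. tropicalis*
  (0.005–8 y) across blood, brain, liver, muscle, skin, toe and whole-animal
  samples with the study's per-tissue counts, plus a human cohort
  (default 200 samples, ages 0–101 y, five tissues) for the dual clocks.
  The human cohort is deliberately scaled down by ~7x from the reference
  human dataset to keep desk-scale runtimes; this mostly affects the
  tightness, not the attainability, of the dual-clock accuracies.
* **Ages** are drawn log-uniformly over each species' range (floored at
  0.005 y ≈ 2 days) so embryos and juveniles are well represented, matching
  the study's developmental emphasis.
* **Betas** follow `clip01(baseline + species_offset + tissue_offset +
  direction*effect*g(age) + noise)`, where `g` is the species' log-linear
  transform rescaled to [0, 1] over its age range — the planted signal is
  therefore nonlinear in chronological age exactly the way the clocks
  assume.  Defaults: 4000 CpGs; 300 positively and 200 negatively drifting
  CpGs with drift magnitudes uniform on [0.3, 1] x 0.35 beta units; noise
  sd 0.03; per-tissue offsets sd 0.02; per-species offsets sd 0.05.
* **Baselines** come from a low/intermediate/high Beta mixture mimicking
  array bimodality; drifting CpGs draw their baseline from the components
  that leave headroom for the drift ('+' low/mid, '-' mid/high).  Under
  defaults ~2% of values hit the [0, 1] rails and are clipped.
* **Annotations** — 80% of the positive CpGs are flagged as PRC2 targets
  versus a 10% background rate, planting the hypermethylation-of-
  Polycomb-targets signature the enrichment stage must recover; a PRC1 set
  filled at background rate serves as a negative control.
* **Sex** is unknown below maturity (as in the study, where juveniles
  cannot be sexed) and random otherwise.
* A single seeded generator drives all draws in fixed order, so equal
  configs give bit-identical cohorts.

What the simulator does **not** emulate: probe hybridisation artifacts,
batch and storage effects, genomic coordinates and neighbourhood
correlation between CpGs, realistic effect-size distributions (planted
effects are strong by design), biological covariance between tissues, or
individual-level longitudinal structure.  Passing tests therefore
demonstrate that the pipeline's statistics are implemented correctly and
recover known structure under the study's design, not that the clocks
would achieve comparable accuracy on real arrays.

## Problem sizes and determinism

The default validation sweep — seven clocks, LOO over up to 65 frogs and
10-fold over 265 combined samples, on 4000 CpGs — runs in a few minutes on
one CPU; unit tests use a reduced cohort (36 frogs, 400 CpGs).  Every
stochastic step (cohort generation, inner-CV folds, outer fold shuffles) is
driven by an explicit integer seed, and pipeline outputs are byte-identical
across reruns with equal config and seed.

## Known limitations

* The log-linear transform's exact published functional form is not
  specified to parameter level in the source material; the two-piece C1
  form here is a documented stand-in with the stated qualitative
  properties (log before maturity, linear after, speed set by maturity).
* LOO cross-validation refits the penalty per left-out sample, so the
  "clock" whose accuracy is reported is an ensemble of closely related
  models; the shipped clock is the single fit on all training samples.
* The hypergeometric test treats CpGs as exchangeable; with correlated
  probes (CpG islands) real backgrounds are effectively smaller, so real
  enrichment p-values are anti-conservative in a way the simulator does
  not model.
* Relative-age and below-birth predictions are reported raw; consumers
  who need bounded estimates must clip downstream.
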
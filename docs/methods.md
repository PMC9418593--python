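# Methods

## Problem and model

`tapage` estimates *behavioral age* from smartphone touchscreen dynamics.
The raw datum is a per-subject stream of interaction timestamps
(milliseconds).  Consecutive inter-touch intervals (ITIs) are paired —
(ITI at k, ITI at k+1) — and smoothed into a **joint interval distribution
(JID)**: a 50×50 probability mass over the log10-ms plane.  A gradient-
boosted tree ensemble regresses chronological age on 2504 features (2500
JID cells, gender code, JID Shannon entropy, log10 median daily
interaction count, screen size), trained on healthy subjects under
10-fold cross-validation so each subject gets an out-of-fold prediction.
The signed error (predicted − chronological, years) is the behavioral age
gap; a disease cohort's typical gap is contrasted with a bootstrap null of
age-matched healthy subjects.

## Feature extraction

- **Pairing.** ITIs are differences of successive timestamps; pairs are
  formed from successive ITIs.  Pairs never bridge a midnight boundary:
  overnight gaps would otherwise dominate the slow tail with artifactual
  mass.  The grid ceiling (10^5 ms ≈ 28 h) makes genuinely long gaps
  marginal anyway.  Duplicate timestamps (zero ITIs) are dropped before
  pairing because the features live in log space.  An unbroken same-day
  run of m events yields m−2 pairs.
- **KDE.** An isotropic Gaussian kernel with bandwidth 0.1 (log10-ms
  units, no cross-term) is evaluated at 50 equally spaced cell centers per
  axis spanning log10-ms [0.5, 5]; cell values are renormalized to sum to
  one.  Centers-vs-edges and the kernel normalization constant are
  conventions; renormalization makes them equivalent up to edge effects.
  Pairs outside the grid range still contribute kernel mass to in-grid
  cells; mass falling off the grid is discarded by renormalization.
  The separable implementation (two n×50 kernel matrices multiplied) is
  algebraically identical to the double loop over pairs × cells and is
  tested against that brute-force oracle at 1e-10.
- **Entropy** is Shannon entropy in bits (base 2; the base only rescales
  one feature, which tree models are insensitive to), with 0·log 0 := 0.
- **Inclusion filter**: subjects need ≥ 7 distinct days with data
  (inclusive threshold).  **Accumulation window**: analyses run at 90 or
  180 days; features carry their window so a bundle refuses features built
  at another window (the deliberate exception is the duration-sensitivity
  analysis, which truncates test streams on purpose).
- No covariate imputation: a missing screen size is a hard error.

## Normative model

Fixed boosting configuration: maximum depth 9, 567 trees, learning rate
1e-2, minimum child weight 8, L1 alpha 1e-3, row and column subsampling
1.0, squared-error objective.  These are frozen defaults; re-tuning is out
of scope.  Numerical choices that were ours:

- **Split enumeration** uses the greedy exact method. On cohorts of a few
  hundred rows it is both deterministic and faster than histogram binning
  with 2504 features, and it matches the classical default behavior of
  gradient-boosting libraries on small dense data.
- **Determinism**: single-threaded training with a fixed seed yields
  bit-identical ensembles; the test suite pins both.
- **Folds** are age-stratified: subjects sorted by age are dealt in blocks
  of k with a seeded permutation per block, so fold sizes differ by at
  most one and fold age profiles match.
- **R²** is the squared Pearson correlation between predicted and real age
  (the convention of the normative-age literature).  The coefficient of
  determination is exposed alongside (`R2_cod`); the two differ in sign
  conventions for anti-correlated predictions, a documented caveat.
- Constant predictions make R² undefined; it is reported as NaN with a
  warning rather than silently zero.

## Attribution

Per-feature attributions are exact Shapley values of the tree ensemble's
cover-weighted conditional-expectation game, computed by the polynomial
tree-path algorithm re-implemented in `tapage._treeshap` in double
precision (numba-compiled).  Float64 matters: at 567 trees the float32
attribution path accumulates ~1e-4 of additivity error, while this
implementation satisfies base + Σ contributions = prediction to ~1e-12
against a float64 re-evaluation of the ensemble.  Tree routing replicates
float32 threshold comparisons exactly, so leaf assignment matches the
library's predictions bit-for-bit.  The implementation is verified two
independent ways: against an exhaustive-coalition Shapley oracle (all
feature subsets, cover-weighted expectations) on small-feature models at
1e-10, and against the float32 C++ implementation inside XGBoost at 1e-3.

Healthy subjects are attributed by their out-of-fold model; patient
cohorts by averaging contributions over the ten fold models.  Population
maps split each subject's JID-cell attribution into positive and negative
parts *before* averaging, so the maps decompose: positive + negative =
plain mean attribution.

## Deviation analysis

Ten predictions per patient (one per fold model) give ten per-model median
signed errors.  The null distribution samples, per iteration, one healthy
subject within ±2 years of each patient (uniform, without replacement
within the iteration; scarcest age pools pick first so sampling cannot
strand) and records the median of their out-of-fold errors; healthy
in-fold predictions are never used, keeping the null unbiased.  The two
median sets are compared with Welch's two-sample t-test (the
pooled-variance form is an option).  Per-patient predicted age is the
median over the ten models (mean exposed as an option) and is related to
real age by a Huber M-estimator robust regression (tuning constant 1.345,
slope t-test on n−2 degrees of freedom); perfectly collinear input
degenerates the robust scale estimate and falls back to the ordinary
least-squares line.

A known caveat: the t-test treats the ten fold-model medians as the only
source of uncertainty on the patient side.  Because the ten models share
one patient sample, cohort-level sampling variability is not in the test's
standard error, making the test anticonservative for small cohorts.  The
report therefore also carries a two-sided *empirical* p — the position of
the mean patient median within the bootstrap null distribution — which
does carry that variability (a median of n age-matched healthy errors has
the same sampling law as a median of n same-process patient errors) and is
the better calibrated reference.

## Synthetic cohorts

No public tap-stream corpus ships with the package, so a generator
emulates the statistical structure the analysis needs.  ITIs follow a
four-component mixture of log-normal regimes — fast (10^2.0 ms ≈ 100 ms),
medium (10^3.0 ≈ 1 s), slow (10^3.6 ≈ 4 s) and gap (10^4.5 ≈ 32 s), each
with 0.25–0.30 log10 spread — with Markov persistence 0.5 (the next
interval stays in the current regime with probability 0.5), so the joint
(k, k+1) distribution is not an outer product and the JID has something to
capture.  Regime weights are a softmax of logits linear in age around a
reference of 50 years; the fast slope is negative (−0.030 per year) and
the slow/gap slopes positive (+0.018 / +0.016), matching the observed
direction of smartphone aging (fast consecutive intervals decline with
age, multi-second intervals increase).  A per-subject Gaussian random
effect (sd 0.30 per logit) creates individual variability around the age
norm, which is what bounds achievable model accuracy.  Ages are uniform on
16–86, recording lengths uniform on 7–180 days, daily interaction counts
Poisson with mean 250, day starts at a random morning offset, and events
never spill past midnight.  Disease is modeled as an *effective age*
offset: a patient of chronological age a with acceleration Δ draws mixture
weights at age a+Δ; by construction a +Δ patient is stream-identical to a
healthy subject of age a+Δ generated from the same random substream, which
the tests exploit for paired comparisons.

All magnitudes are invented plumbing — only the age-effect direction is
anchored in observed behavior.  Defaults were fixed once, after a single
pilot run, so that the full pipeline on n = 300 healthy subjects lands at
realistic normative performance (MAE ≈ 6 years, R² ≈ 0.8, the scale
reported for human cohorts), and were not revisited.  What the generator
deliberately omits: circadian and weekday structure beyond day
segmentation, app identity, notification-driven bursts, device changes,
and any non-monotone age effects.  Passing tests therefore demonstrate
that the pipeline recovers the statistical structure it assumes, not that
it would perform identically on human data.

Seeding: one global seed spawns independent per-subject substreams
(`numpy` SeedSequence), so subject i is reproducible regardless of cohort
size; every stochastic stage (fold assignment, training, bootstrap,
duration bands) takes an explicit seed.

## Problem sizes used by the shipped analyses

The acceptance script and acceptance-level tests run the full pipeline at
n = 300 healthy subjects (ages 16–86, 7–180 recording days, 180-day
window), a 41-patient disease cohort at +8 years acceleration, 10,000
bootstrap iterations for the headline null, 1,000–2,000 iterations inside
replicated calibration loops, and a 120 + 20 subject end-to-end demo at a
90-day window.  These sizes were chosen as the package's working scale:
large enough for stable estimates of every reported quantity, small enough
to run on a single CPU in minutes.

## Known limitations

- The generator's invented magnitudes mean absolute numbers (MAE, gaps)
  characterize the synthetic world, not any human population.
- The squared-correlation R² convention is insensitive to calibration
  (slope/intercept) of the predictions.
- Tree-model age predictions regress toward the training mean, so an
  injected +Δ acceleration is recovered attenuated by roughly the
  calibration slope of the normative model (~0.85 at the working scale);
  recovery tests use a ±3 year band around the injected +8.
- Predictions saturate at the edges of the trained age span: a patient
  whose effective age exceeds the oldest training subject cannot be
  predicted older, so acceleration appears muted in the oldest patients —
  the familiar pattern of advanced aging being most visible in younger
  patients.  Acceptance analyses therefore simulate disease cohorts over
  ages 20–70 (the adult disease range at the long monitoring window),
  keeping +8-year effective ages inside the trained 16–86 span.
- The two-sample t-test inherits the anticonservatism noted above; the
  bootstrap null distribution itself (reported alongside) is the better
  calibrated reference.
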
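# Methods

This note documents the modelling and simulation choices in
`plantarpress`: what is computed, under which assumptions, which knobs
matter, and what the synthetic cohort does and does not establish.

## Problem setting

One subject = one binary outcome (lower-extremity overuse injury within
six months) plus a baseline pressure-plate assessment: five walking
strides per foot and five running strides per foot, barefoot and shod,
sampled at 250 Hz.  Each footfall yields the whole-foot vertical force
and, for ten anatomical zones, peak pressure, mean pressure and mean
force (mean pressure × zone area).  Only running data enters the model;
walking data supplies the normalisation constant.  The analysed cohort
contains only subjects who stayed healthy or developed an overuse
injury; acute injuries, unknown status and invalid records are excluded
up front (`filtering`).

## Preprocessing

**Reference selection.** Per footwear condition, the longest running
trial over all subjects is the alignment reference, shared across
subjects and measurement types.  Ties go to the lowest
(subject, foot, trial index).

**Alignment.** A shorter trial is brought to reference length by
distributing `L_ref − L` zeros over its two ends; all `L_ref − L + 1`
distributions are enumerated and scored by mutual information between
the padded trial and the reference's matching (zone, measurement)
signal.  MI uses a 256 × 256 joint histogram spanning each signal's own
[min, max], natural logarithm, empty cells contributing zero.  The
implementation evaluates all paddings in one vectorised pass by
exploiting that the padded value multiset — hence both marginal
entropies — is padding-invariant, so only the joint entropy varies;
tests pin this against a literal per-padding enumeration with an
independent MI route (`numpy.histogram2d` + scikit-learn's contingency
MI).  MI values within 1e−9 nats are treated as tied and the smallest
left pad wins: for unstructured signals many paddings are
*mathematically* tied (all-singleton joint histograms), and exact
float comparison would make the winner an accident of summation order.

Alignment is computed per (measurement, zone) signal independently, a
switchable choice; maximising once per trial across measurement types
would couple zones whose activity windows differ.

**Averaging and scaling.** Aligned running trials are averaged
pointwise per (zone, measurement, footwear), with both feet pooled by
default (`pool_feet=False` keeps them separate).  Peak-pressure,
mean-pressure and mean-force averages are then divided by the subject's
maximum barefoot-walking vertical force; vertical-force signals are
featurized but not rescaled, mirroring the scale step's definition.
Walking trials are never aligned or featurized.

## Feature bank

Every signal is summarised by the same bank (default ≈ 170 features per
signal, depending on signal length):

| family | ids | notes |
|---|---|---|
| moments / extremes | maximum, minimum, mean, standard_deviation, skewness, kurtosis | population sd |
| energy | abs_energy | Σ x² |
| trend | linear_trend_slope / _intercept | OLS on sample index |
| autocorrelation | autocorr_lag_1..10 | (Σ(x_t−μ)(x_{t+l}−μ)) / ((n−l)σ²) |
| spectral | fft_angle_k, fft_magnitude_k, k = 0..min(99, n−1) | A_k = Σ_m x_m e^(−2πimk/n); the phase of a numerically zero coefficient (|A_k| < 1e−12) is defined as 0 |
| autoregressive | ar_coeff_0..10_maxlag_10 | conditional least squares with intercept φ_0, so "coefficient 7, maximum lag 10" is the lag-7 weight |
| shape | count_local_maxima | strict interior maxima |

Undefined values (constant series for skewness/AR, lags ≥ n) are NaN in
the table and imputed with the *training-fold* median inside each CV
fold, never globally.  This bank deliberately approximates, rather than
reproduces, the very wide generic feature sets of automated extractors;
with 62 signals it yields ~10,000–11,000 candidate features per subject
plus five person characteristics (sex coded male = 1).

Feature names follow the bijective grammar
`zone|measurement|footwear|feature_id`, which the importance analysis
parses back into groups.

## Model and evaluation

All selection happens inside each leave-one-subject-out fold:
ANOVA-F ranking (constant features forced to score 0; perfectly
separating features capped at the largest finite float), then the grid
k ∈ {5, 10, 15, 20, 25} scored by *training* AUC of the candidate model
(ties → smallest k; the grid clamps to the available feature count),
then an L1-penalised logistic regression on features z-scored with
training-fold statistics (liblinear, C = 1, tol = 1e−4, ≤ 100
iterations, fixed solver seed).  liblinear penalises the intercept as
well, so under a strong penalty predictions shrink toward 0.5 rather
than the class base rate — the toolchain-faithful behaviour, asserted
as such in the tests.

With single-subject test folds, per-fold metrics are undefined; AUC and
Brier are computed once on the pooled out-of-fold probabilities.  The
tests verify AUC against brute-force pair counting (ties = ½) on all
label patterns up to size 8, and include a deliberately leaky harness
(selection before the split) demonstrating the inflation the fold-local
design avoids.

**Group importance.** Groups per kind: 10 foot areas (whole-foot
vertical force and person characteristics belong to none), 5
measurement types (the four signal types + person characteristics), 2
footwear conditions.  Baseline and per-group-excluded LOOCV runs use a
fixed per-fold budget of ⌊0.1 N⌋ features (10% rule; 15 at N = 155)
instead of the k grid, which keeps 18 evaluations tractable.  Reported
are ΔAUC = AUC_excluded − AUC_baseline and ΔBrier = Brier_baseline −
Brier_excluded, so positive always means "better without the group";
rank 1 = most negative ΔAUC, ties broken by ΔBrier, exact ties sharing
an average rank.  Runs are deterministic, so a group never selected in
either run yields deltas of exactly 0.

**Occurrence report.** A feature "occurs" in a fold when it survives
both stages — ranked into the top-k *and* kept a nonzero L1 weight;
features at or above 10% of folds are reported.

## Synthetic cohort

The generator emulates the study's data structure, not running
biomechanics:

* **Anthropometrics** are class-conditional normals (healthy
  175.69 ± 8.23 cm, 68.65 ± 9.00 kg, 69% male; injured 177.70 ± 8.04 cm,
  69.75 ± 8.63 kg, 74% male), outcome ~ Bernoulli(35/155 by default).
* **Signals.** Each zone's mean pressure is a squared-sine bump on a
  zone-specific stance window (heels 0–40%, midfoot 20–60%, metatarsals
  30–90%, toes 55–100%), scaled so the nominal whole-foot peak vertical
  force is 2.5 × body weight running and 1.1 × walking.  Mean force =
  mean pressure × area and vertical force = Σ zone forces hold exactly,
  by construction.  Peak pressure is mean pressure times a noisy peak
  factor, floored at 1.
* **Stance durations**: run 0.22 ± 0.02 s, walk 0.70 ± 0.05 s (≈ 55 and
  175 samples at 250 Hz) — plausible values; trial lengths therefore
  vary, which is what makes alignment necessary.
* **Noise structure** (free parameters, no empirical source): lognormal
  subject-level per-zone amplitude (sd 0.15) and peak-factor (sd 0.08)
  signatures shared across a subject's trials, trial-level global
  (sd 0.08) and per-zone (sd 0.05) amplitude jitter, timing jitter
  (subject sd 0.02, trial sd 0.01 of stance), per-sample peak-factor
  noise (sd 0.05).  Shod trials reuse the subject's signature with a
  0.9 amplitude attenuation, making footwear conditions partially
  redundant.
* **Injury effect.** δ (default 0.3) multiplies the forefoot peak
  factor of injured subjects by 1 + δ, concentrating the effect in
  forefoot peak pressures while leaving mean pressure/force and
  vertical force untouched — this is what lets the group-exclusion
  analysis attribute the signal to the peak-pressure group.
  `effect_target="mean_pressure"` instead scales the bump amplitude,
  propagating the effect into every derived measurement; an optional
  `timing_shift` moves the injured forefoot windows earlier.

One master seed drives profile sampling and per-subject trial streams;
identical seeds give byte-identical cohorts and, through the pipeline,
bit-identical artifacts.

**What passing tests show — and don't.** The synthetic cohort validates
the *machinery*: conservation laws, alignment recovery, leakage safety,
effect detection and attribution under a known ground truth.  It does
not validate the clinical claim: real plantar-pressure signals have
richer intra-subject correlation, sensor noise, footwear heterogeneity
and far subtler class differences, so an AUC of ~0.93 on δ = 0.3
cohorts says nothing about achievable performance on real runners.

## Study conditions used in checks

End-to-end checks run at desk scale: null cohorts δ = 0 with 60
subjects, effect cohorts δ = 0.3 with 80 subjects, five seeds in the
test suite and three in the acceptance script.  Null-cohort LOOCV AUC
has large intrinsic spread at this size (≈ ±0.14 across seeds;
permuted-label runs bracket 0.16–0.72 around a mean of ~0.50), so the
no-signal check asserts the band on the mean over seeds rather than a
single draw.  The alignment-recovery fixtures slice zero-flanked
references and add Gaussian noise with sd = 0.5% of the bump amplitude
("mild"); at ~1% noise, occasional ±1-sample misses appear.

## Known limitations

* The feature bank is a curated approximation of wide automated
  extractors; absolute feature counts are not comparable to theirs.
* The exhaustive padding search is O(paddings × length) per signal;
  fine at stance lengths (~50–80 samples), not designed for signals of
  thousands of samples.
* AUC confidence intervals are out of scope; single-cohort AUCs at
  N ≲ 100 should be read with the spread documented above in mind.
* The generator's left and right feet are independent; real gait is
  bilaterally correlated.
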
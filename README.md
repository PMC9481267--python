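# plantarpress

Predicting lower-extremity overuse injuries from plantar-pressure
time series.

Overuse injuries of the leg and foot — medial tibial stress syndrome,
tendinopathies, patellofemoral pain — develop gradually under repetitive
load and account for a large share of running-related injuries.  A
pressure plate captures, in a few strides, the vertical force and the
per-zone pressure distribution of each footfall.  `plantarpress`
implements a complete, leakage-safe machine-learning pipeline that turns
such recordings into a six-month injury-risk probability per subject and
identifies *which* loading features carry the signal.  It is aimed at
sports-biomechanics and sports-medicine researchers who have zone-
resolved pressure-plate trials (or want to prototype against realistic
synthetic ones) and need a reproducible risk model with honest
cross-validated error estimates.

## The method

For each subject the plate yields, per footfall, four time series
sampled at 250 Hz: whole-foot vertical force *F*(t), and peak pressure,
mean pressure and mean force for each of ten anatomical zones (hallux,
toes 2–5, metatarsal heads 1–5, midfoot, medial/lateral heel), with
mean force = mean pressure × zone area.  The pipeline:

1. **Alignment.** Trials differ in stance duration.  Every running
   trial is zero-padded to the length of the longest trial of its
   footwear condition; among all (left, right) paddings the one
   maximising the 2D-histogram mutual information (256 × 256 bins,
   natural log) with the reference trial is kept.  Padding preserves
   the time axis — nothing is stretched or resampled.
2. **Averaging and scaling.** Aligned trials are averaged pointwise per
   (zone, measurement, footwear); pressure and force averages are
   divided by the subject's maximum barefoot-*walking* vertical force,
   removing body-weight and speed scale while preserving relative zone
   loading.
3. **Features.** Each of the 62 signals per subject is summarised by a
   configurable bank: maximum, absolute energy Σx², linear trend,
   autocorrelations, skewness/kurtosis, the magnitude and phase of DFT
   coefficients A_k = Σ_m x_m e^(−2πimk/n), and the coefficients
   φ_0…φ_10 of an AR(10) model x_t = φ_0 + Σ_i φ_i x_{t−i} + ε_t fitted
   by conditional least squares.  Sex, height, weight, BMI and shoe
   size join as person characteristics.
4. **Model.** Within every leave-one-subject-out fold — and only there —
   features are ranked by the ANOVA F statistic, the set size
   k ∈ {5, 10, 15, 20, 25} with the best training AUC is chosen, and an
   L1-penalised logistic regression (liblinear, C = 1, ≤ 100
   iterations) is fitted on z-scored features; its zero coefficients
   act as a second selection stage.
5. **Evaluation.** Pooled out-of-fold probabilities give one AUC
   (ranking ability) and one Brier score BS = (1/N) Σ (p_i − y_i)²
   (calibration).  A group-exclusion analysis re-runs the evaluation
   with all features of one foot area, measurement type or footwear
   condition removed (15 features per fold via the 10% rule, i.e.
   ⌊0.1 N⌋), ranking the groups by how much their removal hurts.

Because raw study data of this kind is rarely public, the package ships
a first-class synthetic cohort generator that reproduces the structural
invariants above (heel→toe roll-off, exact force/pressure/area
relations, variable trial lengths, class-conditional anthropometrics)
with a tunable injured-subject effect δ concentrated on forefoot peak
pressures.

## Worked example

```python
from plantarpress import CohortConfig, OveruseInjuryModel

model = OveruseInjuryModel.from_cohort(CohortConfig(n_subjects=40, seed=7))
res = model.fit()
print(res.summary())
```

```
Lower-extremity overuse injury risk model (LOOCV)
==========================================================
Subjects:              40  (healthy 29, injured 11)
Candidate features:    10731
k grid:                [5, 10, 15, 20, 25]
L1 penalty C:          1.0
Pooled AUC:            0.859
Pooled Brier score:    0.138
Mean selected k/fold:  23.2
Mean nonzero weights:  5.2
10%-rule budget:       4
----------------------------------------------------------
Features in >= 10% of folds (selection AND nonzero weight):
  metatarsal_1  peak_pressure  barefoot  abs_energy               100.0%
  metatarsal_1  peak_pressure  shod      linear_trend_slope        97.5%
  metatarsal_1  peak_pressure  barefoot  fft_magnitude_5           70.0%
  metatarsal_1  peak_pressure  barefoot  fft_magnitude_68          57.5%
  metatarsal_1  peak_pressure  barefoot  linear_trend_intercept    17.5%
  metatarsal_2  peak_pressure  shod      fft_magnitude_3           12.5%
  metatarsal_4  peak_pressure  barefoot  linear_trend_slope        95.0%
```

Read this as: on a 40-subject synthetic cohort with a 30% forefoot
peak-pressure elevation in the 11 subjects who go on to be injured, the
leave-one-out model separates injured from healthy with AUC 0.859 and
well-calibrated probabilities (Brier 0.138); the features that survive
both selection stages in most folds are, as injected, forefoot
peak-pressure features.  `res.group_importance()` returns the
group-exclusion table (ΔAUC/ΔBrier per foot area, measurement and
footwear, positive = model improved without the group),
`res.feature_occurrence()` the per-fold occurrence report, and
`res.plot_roc()` the pooled ROC curve.

The same pipeline is scriptable from the shell:

```bash
plantarpress all --seed 7 --out run_dir          # simulate → ... → importance
plantarpress filter --roster roster.csv --out out
plantarpress evaluate --features features.csv --out out
```

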
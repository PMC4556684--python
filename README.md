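# afmse

Multiscale-entropy and heart-rate-variability analysis of **ventricular
response intervals (VRIs)** in permanent atrial fibrillation, with a
biostatistics layer for ischemic-stroke risk stratification.

## The problem

During atrial fibrillation the ventricles respond irregularly to chaotic
atrial activity, so the classical sinus-rhythm HRV toolbox loses much of its
meaning. The irregularity itself, however, carries structure across *time
scales*: AF ventricular response is white-noise-like at short scales but
shows 1/f-type long-range correlations at periods beyond roughly 200 s.
Quantifying irregularity in the very-low-frequency scale range turns out to
carry prognostic information for ischemic stroke that conventional HRV
measures and the CHA₂DS₂-VASc score miss.

This package implements that analysis end to end for 24-hour Holter beat
annotations, plus a synthetic-data generator so every stage is testable
without any clinical data.

## The method

**Sample entropy.** For a series *x* with pattern length *m* and tolerance
*r* (Chebyshev distance, strict `<`, self-matches excluded),

```
SampEn(m, r) = −ln(A / B)
```

where *B* counts template pairs matching at length *m* and *A* the same
pairs still matching at length *m* + 1. Defaults: *m* = 2, *r* = 0.15 of the
reference SD. For i.i.d. Gaussian noise the scale-1 value has the closed
form −ln(erf(r/2)) ≈ 2.47, which the test suite uses as an analytic oracle.

**Time-scale-based MSE.** The cleaned VRI tachogram is linearly interpolated
and resampled at 2 Hz, then coarse-grained into non-overlapping block means
of τ samples; SampEn is computed per scale with the tolerance fixed from the
scale-1 SD. Because of the fixed resampling rate, scales are in *seconds*,
so entropy bands align with the conventional spectral bands:
HF 2.5–6.5 s, LF 6.5–25 s, VLF 25–300 s, VLF1 25–90 s, VLF2 90–300 s.
Each band is summarised by **MeanEn** (mean entropy) and **SlopeEn** (OLS
slope of entropy vs log₁₀ scale). `MeanEn_VLF2` — the mean over 90–300 s —
is the headline stroke predictor.

**Risk statistics.** Per-patient features feed Student's t / χ² / Fisher
group comparisons, Spearman correlation matrices, OLS covariate regression,
C-statistics with DeLong CIs, Cox proportional-hazards models reported as
hazard ratio per 1-SD increment, Nelson–Aalen cumulative-hazard curves with
log-rank tests, and stratified 4-fold cross-validated sensitivity and
specificity (Youden threshold chosen on training folds only).

**Synthetic generator.** AF-like interval series are built by spectral
synthesis — white power above a 200-s crossover period, 1/f^β excess below
it — rescaled to study-like moments (mean 811 ms, SD 230 ms) and clipped to
[200, 3000] ms. Cohorts couple each patient's `MeanEn_VLF2` to
exponential stroke times through a proportional-hazards model with a
configurable per-1-SD log hazard ratio, plus CHA₂DS₂-VASc covariates and
censoring.

## Worked example

```python
from afmse.synthetic import SynthConfig, generate_vri_series, generate_cohort
from afmse.features import extract_features
from afmse.riskstats import cox_fit, c_statistic

# one synthetic 24-h AF recording -> all Holter features
rec = extract_features(generate_vri_series(SynthConfig(seed=1)))
print(rec["mean_vri_ms"], rec["sdvri_ms"], rec["mean_en_vlf2"])
# 811.265  229.212  0.543

# a 500-patient cohort generated at true HR 1.80 per 1-SD of MeanEn_VLF2
cohort = generate_cohort(SynthConfig(seed=1, n_patients=500)).table
res = cox_fit(cohort, "mean_en_vlf2",
              adjusters=["age", "cha2ds2_vasc", "antithrombotic"])
print(res.hr_per_sd, res.ci_low, res.ci_high)
# 1.75 (95% CI 1.44–2.11), 117 events among 500 patients
print(c_statistic(cohort, "mean_en_vlf2").auc)
# 0.63
```

The feature record shows the expected AF signature: high short-scale entropy
(MeanEn_HF ≈ 1.84, near the white-noise ceiling) falling towards the
long-scale plateau (MeanEn_VLF2 ≈ 0.54 for this seed). The adjusted Cox fit
recovers a hazard ratio close to the generating value of 1.80, and the
C-statistic shows the modest discrimination typical of a single Holter
marker.

There is also a CLI:

```bash
afmse simulate --out sim/ --seed 3           # beat CSVs + cohort table
afmse features --in sim/patient_000.csv --out features.json
afmse diurnal  --in sim/patient_000.csv --out diurnal.csv
afmse cohort-stats --cohort cohort.csv --out stats.json
afmse run --out runs/demo --seed 3           # full pipeline
```

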
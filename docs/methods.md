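# Methods

This note documents the models, conventions and design choices behind
`afmse`, in the spirit of a statistical package's model documentation. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Signal model and preprocessing

The raw input is an annotated beat stream: onset times in seconds from
recording start and one label per beat — `N` (conducted), `V` (ventricular
ectopic), `A` (artifact) — with an optional wall-clock anchor. The analysis
substrate is the ventricular response interval (VRI) series: differences of
successive onsets, in ms, each anchored at its *terminating* beat's onset
(the common tachogram convention; the choice matters only at interpolation
boundaries).

**Ectopy/artifact policy.** By default every interval that starts or ends at
a non-`N` beat is dropped (`ve_policy="drop"`); the alternative `"keep"` is
exposed because the handling of ectopy-adjacent intervals in AF tachograms
is not standardized. Ectopy is accounted per beat (n_V / total beats);
artifact per *time* (summed duration of `A`-adjacent intervals over total
recording time). Runs of dropped intervals longer than 10 s are bridged by
the interpolation but counted (`n_long_gaps`).

**Eligibility.** A recording passes the screen when it spans ≥ 22 h, has
≤ 5% ventricular ectopy by beats, and ≤ 5% artifact by time. Eligibility is
*reported, never enforced*: short synthetic fixtures run through the same
code paths with the flag set accordingly.

**Resampling.** The tachogram is linearly interpolated against interval
onsets and sampled at 2 Hz on a grid from the first to the last interval
onset (`floor(span·2) + 1` samples). Boundary convention: the grid starts at
the *second* beat (the first interval's onset), so a nominal 24-h recording
yields 172 799 samples rather than 172 801; tests pin this convention.

## Multiscale entropy

Coarse-graining replaces the 2 Hz series with non-overlapping block means of
τ samples (trailing partial block discarded). Sample entropy uses pattern
length m = 2, tolerance r = 0.15, Chebyshev distance with strict `<`
matching (some implementations use `≤`; at continuous data the difference is
measure-zero, at quantized data it is not — the kernel and its naive oracle
agree exactly either way), self-matches excluded, and both template counts
taken over the N − m templates that admit an (m+1)-length extension
(Richman–Moorman convention).

**Tolerance convention.** r normalizes to the SD of the scale-1 resampled
series and is *held fixed across scales* (the original MSE formulation).
Under this convention white noise gives a strictly decreasing profile
(coarse-grained SD shrinks as τ^(−1/2) against a fixed tolerance) while
1/f-type noise is scale-stable. Per-scale re-normalization
(`r_reference="per_scale"`) is exposed as an option and flattens the
white-noise profile, as a test demonstrates.

**Scale grid.** 20 log-spaced scales per decade over [2.5, 300] s, each
snapped to an integer τ at 2 Hz, duplicates removed, both band edges forced
onto the grid. Scales whose coarse-grained series is shorter than
`min_points` (default 200) or whose entropy is undefined (zero match counts)
are flagged, never imputed and never returned as infinities.

**Band summaries.** MeanEn is the unweighted mean of defined entropies over
grid scales inside the closed band [lo, hi]; SlopeEn is the OLS slope
against log₁₀(scale in seconds). Sign convention: against log₁₀(frequency)
the slope would be negated; seconds are used because the band bounds are
stated in seconds. The LF/HF boundary is 6.5 s (an alternative 6.7 s
appears in some tabulations; band edges are configurable via explicit
(lo, hi) tuples).

**Efficiency.** The match-counting kernel sorts templates by first
coordinate and scans only candidates within tolerance on that coordinate,
giving exact counts at a fraction of the naive O(N²) cost; a full 24-h
profile (42 scales, up to ~34 500 coarse-grained points at the smallest
scale) takes a few seconds on one CPU, and the N = 100 000 scale-1
computation runs in under a minute including JIT compilation.

## Conventional HRV measures

SDVRI is the SD of all intervals; SDAVRI the SD of non-overlapping 5-min
window means (windows anchored at the first onset, windows covering < 30 s
of interval time dropped). Spectral band powers (ULF < 0.0033 Hz,
VLF 0.0033–0.04, LF 0.04–0.15, HF 0.15–0.4) are integrated from a Welch
estimate (1024-s Hann segments, 50% overlap, linear detrend); ULF instead
uses a single full-length linearly detrended periodogram, since Welch
segments cannot resolve it. Powers are reported as ln(ms²). ULF is flagged
on recordings shorter than 22 h, other bands when shorter than two cycles
of the band's longest period. The ULF upper bound is used exactly as
0.0033 Hz (≈ 303 s period).

**Scattering index.** The dispersion of the Lorenz (lag-1 return) plot is
not given a unique formula in the AF literature; the implemented default is
the RMS principal-axis SD — sqrt of the mean eigenvalue of the 2×2
covariance of (VRI_n, VRI_{n+1}) — which equals the interval SD for i.i.d.
data and is invariant under time reversal. Absolute values are therefore
definition-sensitive: study-reported indices (~390 ms) exceed the interval
SD (~230 ms), so that published magnitude is *not* reproduced by this
definition; the function accepts alternatives.

## Diurnal analysis

MeanEn_VLF2 is recomputed in 4-h windows sliding by 2 h, with centres
snapped to odd clock hours so recordings starting at different times align
on a common time-of-day axis; a 24-h recording from 09:00 yields 12 windows
centred 11:00 … 09:00(+1d), the last truncated. A 4-h window leaves only
~48 coarse-grained points at the 300-s scale — below the full-series
minimum — so the windowed minimum is relaxed to 40; the resulting wider
sampling variance is accepted as the price of temporal resolution, and
windows with less than half the nominal coverage are flagged undefined.
The group test emits both a one-way ANOVA across windows (per group — the
"one-way" reading of the published analysis is ambiguous, so the per-group
time ANOVA is always reported) and per-window two-sample t-tests with
Bonferroni correction over the number of windows. Power simulations at
study-like sizes (22 vs ~150, offset 0.08, SDs ~0.14) put the per-window
Bonferroni-corrected power near 0.3, so only a minority of windows is
expected to fire in any one replicate; the test suite asserts the computed
power (far more significant windows than under the null), not a majority.

## Synthetic data generator

The generator emulates the two-regime AF spectrum: squared Fourier
amplitude `w + (1−w)·esf²·max((f/f_c)^(−β) − 1, 0)` with random Gaussian
phases, inverse-transformed over the beat index (effective spacing = mean
interval), rescaled to the target SD and mean, and clipped to
[200, 3000] ms. Defaults: duration 24 h, mean 811 ms, SD 230 ms, β = 1,
crossover period 200 s. `w = white_fraction` (default 0.68, calibrated once
so that the default series' MeanEn_VLF2 averages ≈ 0.60, the study-like
level); `esf = entropy_scale_factor` scales only the sub-crossover excess,
so per-patient long-scale irregularity varies while short-scale behaviour
stays AF-like. Setting `w = 1` gives exact i.i.d. Gaussian intervals (the
analytic-entropy fixture); `w = 0` with a sub-second crossover gives pure
1/f^β noise.

Known limitations of the generator, hence of what passing tests show about
real data:

* Gaussian marginals with the study-like moments put ~0.4% of intervals
  below the 200 ms floor; clipping is logged. Real VRI distributions are
  right-skewed and would not clip symmetrically.
* A single spectral knob cannot match both the study-level MeanEn_VLF2
  (~0.60) and its near-zero SlopeEn_VLF2; the default reproduces the mean,
  with the generator's VLF2 slope around −0.3.
* No ectopic-beat morphology is simulated — only label injection at a
  configurable fraction — and no true AV-nodal conduction dynamics.
* Stationarity: the generator has no diurnal modulation, so diurnal tests
  construct their nonstationarity explicitly.

**Cohorts.** A single global seed expands into per-patient substreams via
`SeedSequence(entropy=seed, spawn_key=(patient, stream))`, so cohorts are
bit-reproducible regardless of generation order. Features are either drawn
parametrically — MeanEn_VLF2 ~ Normal(0.60, 0.14), a modelling choice for
the unreported patient-level dispersion — or computed through the full
pipeline from generated recordings (log-normal entropy_scale_factor,
σ = 0.35). Stroke times are exponential with monthly rate
`(annual_rate/12)·exp(logHR·z)` where z is the within-cohort standardized
MeanEn_VLF2 (defaults: annual rate 5.8%, logHR = ln 1.80); censoring is the
minimum of an independent exponential (mean 60 months) and a 96-month
administrative horizon (about twice the study's median follow-up). The
exponential form is the simplest model consistent with a constant
annualized rate, and a correct Cox fit recovers the generating hazard ratio
(verified at n = 2000 over 50 replicates).

## Statistics layer

* Continuous group comparisons use the classical equal-variance Student
  t-test; categorical use χ², switching to Fisher's exact test for 2×2
  tables with any expected cell < 5. All tests two-sided, α = 0.05.
* C-statistic CIs and paired comparisons use DeLong's method (fast midrank
  formulation); the outcome is event-ever-during-follow-up, ignoring
  censoring times (a time-dependent AUC is out of scope).
* Cox fits standardize the feature within the analyzed subset, so the
  reported HR is per 1-SD and invariant to positive rescaling; subset
  analyses (no-antithrombotic with age + score adjustment; antithrombotic
  with full adjustment) are expressed by passing subsets and adjuster lists.
* Nelson–Aalen curves are grouped by dichotomizing at the cohort mean of
  MeanEn_VLF2 by default; group comparison via the log-rank test.
* Cross-validation is stratified by outcome with a fixed seed; thresholds
  are chosen by the Youden index on training folds only (the published
  procedure names neither rule nor stratification — these are documented
  choices), and predictions are pooled across held-out folds.
* The two-normal threshold model (events N(0.68, 0.15²), n = 22;
  non-events N(0.60, 0.14²), n = 151) dichotomized at the pooled cohort
  mean (0.610) has closed-form sensitivity 67.9% and specificity 52.9%;
  simulation reproduces these. A published operating point of
  66.7%/64.3% at threshold 0.67 is not exactly consistent with those group
  moments (under which the pooled mean is 0.610), so the closed form is the
  oracle here and the discrepancy is documented rather than fitted.

## Numerical and degenerate-input conventions

Constant series: SD-relative entropy is undefined (raised or flagged, never
infinite); the scattering index is 0. Undefined band summaries require ≥ 2
defined scales. Rank-deficient regression designs raise with the collinear
column names. Pipeline feature extraction quarantines failing patients and
continues; stages are content-hashed so unchanged re-runs are no-ops.

## Problem sizes used in the checks

Oracle-equivalence checks run 200 series of length ≤ 500; analytic-limit
checks one series of N = 100 000; profile-shape checks aggregate 20
independent 24-h recordings per noise type (per-seed monotonicity of a
noisy entropy estimate is not a meaningful assertion, so the seed-averaged
profile is tested); Cox recovery uses 50 replicates of n = 2000 with
parametric features; the end-to-end smoke test runs 20 patients at 2 h with
a relaxed `min_points=20` so long-scale summaries remain defined on short
recordings.
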
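# Methods

This note documents the models, conventions, and numerical choices
behind `restwise`, and what the synthetic-data validation does and does
not establish about real recordings.

## Signal chain

### Units, time, montage

Potentials are microvolts throughout; readers convert from
file-declared units. Time is sample-indexed internally (0-based);
seconds appear only at API boundaries, which avoids rate-dependent
rounding ambiguity. Electrode positions, where needed (spherical
interpolation, synthetic topographies), are unit-sphere coordinates;
the 64-channel default montage is the idealized BioSemi-64 layout.

The EDF writer packs 1-second data records of 16-bit integers, so it
requires whole-second recordings and an integer sampling rate; its
quantization step is (physical range)/2^15 per channel. BrainVision
files are written as IEEE float32 (multiplexed), exact to float32
precision.

### Preprocessing

Fixed order: common average reference → band-pass → notches →
(optional artifact hook) → bad-channel interpolation → re-reference.
Choices:

* **Filters**: 4th-order Butterworth applied forward–backward
  (zero-phase), pass band 0.5–80 Hz. Cutoffs are the scientific
  content; the kernel family is a package choice, recorded in the
  config for provenance. Probe-tone behavior: a 10 Hz tone passes
  within 5% amplitude, DC is removed to below 1e-3, 50 Hz is attenuated
  more than tenfold.
* **Line noise**: ±1 Hz Butterworth band-stops at 50 Hz and harmonics
  up to 150 Hz (only those below Nyquist;
  `PreprocessConfig.for_srate` drops unreachable harmonics
  explicitly). A deterministic band-stop is used instead of
  regression-based line-noise removal: same target, testable transfer
  function.
* **Bad channels**: Perrin-style spherical splines — kernel
  g(cos γ) = (1/4π) Σₙ (2n+1)/(n(n+1))⁴ Pₙ(cos γ), truncated at 7
  Legendre terms, ridge regularization 1e-5 on the kernel diagonal,
  constant term constrained to sum-zero weights. Degree-1 (dipolar)
  fields are reconstructed essentially exactly; the suite also checks
  the spline beats a nearest-neighbor copy on smooth fields.
* **Artifact rejection/ICA are deliberately out of scope.** The
  pipeline exposes a pass-through hook for externally cleaned data;
  synthetic inputs are artifact-free by construction. Results on real,
  artifact-laden data therefore depend on upstream cleaning that this
  package does not provide.

### Spectral measures

Welch PSD on 2-s Hamming-tapered epochs with 80% overlap → 0.5 Hz grid
over 0.5–80 Hz, in linear µV²/Hz (computed directly in linear units;
a dB round trip is numerically equivalent). Absolute band power is the
trapezoidal integral over grid points with low ≤ f ≤ high, computed
per channel and then averaged across channels (in that order). Band
edges are inclusive on both sides, so adjacent bands share their edge
grid point; the double-counted trapezoid contribution is below one grid
step of mass. Relative power divides by the integral over the full
0.5–80 Hz grid ("total power"), not the band union; both conventions
exist in the literature and the denominator is configurable. For
statistics, absolute powers enter on the log10 scale; relative powers
as fractions.

### Microstates

* **Spatial similarity** is the Pearson correlation across channels of
  average-referenced maps; polarity is ignored by taking absolute (for
  labeling) or squared (for clustering) correlation.
* **Modified k-means**: clustering runs on all GFP-peak topographies
  (strict local maxima of the GFP trace; plateaus count once, at their
  first sample). Templates are updated as the dominant eigenvector of
  the assigned maps' channel × channel cross-product matrix — the
  polarity-invariant least-squares optimum; plain averaging would
  cancel under sign flips. Assignment maximizes squared correlation;
  empty classes are re-seeded with the currently worst-explained map.
  Convergence: relative GEV change < 1e-7 or 300 iterations; best of
  20 restarts by GEV; restart r draws from seed + r so one master seed
  fixes the ensemble. Ties in labeling go to the lowest class index.
* **Hierarchy**: individual template sets are pooled and re-clustered
  to give session-mean sets; the session means are pooled again for one
  grand-mean set per study (both sessions together). Member sets are
  aligned to an aggregate by Hungarian assignment on |spatial
  correlation| with sign flips to positive correlation. k = 4 for
  grand means; 4–7 supported.
* **Backfitting** labels every sample (no GFP-peak subsampling, no
  temporal smoothing, no minimum-duration rejection — the simplest
  defensible default, exposed in config). Zero-GFP frames inherit the
  previous label (class 0 at the start) and are counted in a QC field.
* **Statistics**: contiguous runs define segments. Runs touching a
  recording boundary count for occurrence and coverage but are excluded
  from mean duration (their length is censored). Classes are reported
  by index with their maps; assigning canonical letter names would
  require reference topographies that are not part of this package.
* Class-never-occurs → occurrence/coverage 0, duration missing.

### Reliability

ICC(2,1) from the two-way ANOVA decomposition; F = MS_B/MS_E with
(n−1, (n−1)(k−1)) df; CI by the McGraw–Wong case-2 construction with a
Satterthwaite df. Negative estimates are reported as computed (the
gate treats them as unreliable anyway); all-identical data yields a
missing value with a reason. Subjects with a missing session are
dropped listwise per measure and counted. The implementation is
checked against an explicit-summation ANOVA oracle (≤ 1e-12 over 1000
random matrices) and against `pingouin`'s ICC(A,1) row.

Split halves are contiguous (extra sample to the first half for odd
lengths) and processed independently through the spectral and
microstate stages, except that microstate halves are backfitted against
the shared grand-mean templates — this isolates statistic stability
from template-estimation noise (configurable by passing different
templates). A measure is *reliable* iff ICC ≥ 0.75 and both sessions'
Spearman–Brown coefficients ≥ 0.75.

### Association screen

Change score Δ = vocab%(T2) − vocab%(T1). Outlier exclusion is
per-analysis and per-pair: subjects beyond `sd_mult` (default 2) sample
SDs from the mean on either variable are removed for that pair only,
in a single pass (no re-iteration). Pearson r with Fisher-z 95% CI;
Bonferroni by the number of correlations computed, or an explicit
study-wide family (e.g. 21). Pairs with fewer than 4 usable subjects
are skipped with a reason. OLS with an age covariate (statsmodels)
provides age-adjusted coefficients; predictor condition number > 1e8
raises, naming the columns.

## Synthetic cohorts

The generator's job is to realize, with known ground truth, exactly the
statistical structure the analysis assumes: trait-like band powers with
controlled between-/within-subject variance, a quasi-stable microstate
dwell process, and a behavioral change score tied to the alpha trait.

**Decomposition.** Each recording is a sum of

1. a microstate component: 4 orthonormal, zero-mean templates (built
   from smooth low-order functions of electrode position), switched by
   an exponential-dwell process (mean 80 ms, no self-transitions,
   10 ms floor) and modulated by a rhythmic envelope
   √(0.2 + 0.8 sin²(2π·10t)) that never vanishes;
2. per-band additive noise: independent band-limited Gaussian noise per
   channel whose variance realizes the subject-session log10 power
   x_ij = g_i + e_ij, with g_i ~ N(µ_b, σ_b²) the stable trait and
   e_ij ~ N(0, σ_e²) session noise, so the true test-retest
   reliability is σ_b²/(σ_b² + σ_e²) in closed form;
3. 1/f background (exponent 1.0), scaled so its alpha-band power is
   one fifth of the mean planted alpha power (alpha SNR ≈ 5), and
   white sensor noise of 1 µV.

An earlier design that modulated a single shared band-limited amplitude
by the template switching was rejected: switching at ~80 ms dwells has
a Lorentzian spectrum with corner ≈ 4 Hz, and the convolution smears
each band's power across its neighbors, corrupting the independently
planted per-band traits. Additive mixing instead adds only *constant*
power to each band; writing the measured power as
m_ij = log₁₀(P_const + 10^x_ij) and linearizing, both variance
components are scaled by the same factor, so the planted ICC ratio is
preserved to first order (the curvature term is second-order in
σ ≈ 0.3). The measured log-alpha power correlates with the planted
session values at r ≥ 0.97 in the suite's cohorts.

Default plants: σ_b = 0.30 for all bands; σ_e set per band so the true
ICCs are delta 0.66, theta 0.77, alpha 0.86, beta 0.80, gamma 0.64 —
the alpha band deliberately most trait-like, mirroring typical adult
findings. Mean log10 powers (channel-averaged µV²) are delta 1.35,
theta 1.0, alpha 1.3, beta 0.9, gamma 0.5, a plausible resting
spectrum.

**Behavior.** Session-1 scores are truncated normals on [0, 100] at
the configured location/scale (children 14.51/11.04; adults 0/0.5 —
note a distribution bounded at zero cannot have mean exactly 0 with
positive SD, so the adult session-1 mean realizes slightly positive).
The change score Δ is built from the standardized alpha trait with the
configured correlation (default 0.38) plus independent noise, then
affinely recalibrated so the *sample* mean/SD equal the configured
values exactly (children 27.65/17.49, adults 65.13/21.75) — affine maps
preserve the planted correlation. Draws that would push T2 outside
[0, 100] are redrawn from the admissible range so the calibration
stays exact; a final clip is a fallback only.

**What the generator does not emulate**: artifacts (blinks, muscle,
electrode pops), age-dependent spectral maturation, biophysical forward
modeling, non-stationarity beyond the dwell process, and spatially
correlated background noise. Passing tests therefore demonstrate the
correctness and calibration of the estimators under the assumed
statistical structure — not robustness to real-world artifact regimes,
which depends on upstream cleaning.

**Determinism.** One master seed fixes the full cohort; each
(subject, session) stream is an independent `SeedSequence` child, so
any single recording can be regenerated in isolation. Repeated runs
are bit-identical.

**A note on planted correlations and outlier screening.** A 2 SD
outlier screen truncates both margins of an (approximately) bivariate
normal pair, which attenuates the correlation among retained subjects
(ρ = 0.46 pre-screen ↔ ≈ 0.38 post-screen, by numerical integration of
the box-truncated bivariate normal). A correlation coefficient
estimated on screened data — as reliability-gated screens produce —
therefore pins down the *truncated* coefficient. Validation of
detection rates plants the pre-screen value obtained by inverting this
attenuation, so that the post-screen coefficient matches the intended
value; the generator's `target_corr` itself remains the plain
(pre-screen) trait-behavior correlation.

## Problem sizes

The statistical checks run at full size (ICC recovery at n = 100 × 200
replicates; CI coverage at n = 90 × 1000 replicates; family-wise error
over 500 cohorts of 21 measures at n = 90; detection over 200
replicates). EEG-level simulations use scaled recordings chosen so
estimator error stays far below the planted effects: the microstate
recovery signal is 180 s at 250 Hz with 64 channels (SNR 10); pipeline
cohorts use 6–10 s recordings at 250 Hz with 12–16 channels and 5–40
subjects. At these sizes the Welch estimate contributes ≈ 0.04 log10
units of measurement noise against planted session noise of ≈ 0.11, so
planted reliabilities pass through the chain essentially undistorted.
Generator defaults remain the full study conditions (64 channels,
1000 Hz, 180 s, n = 36 or 90).

## Known limitations

* The relative-power denominator convention (full grid vs band union)
  changes relative powers by a few percent; both are supported, and
  comparisons across studies must match conventions.
* Microstate statistics depend on backfitting conventions (smoothing,
  minimum duration, peak-only labeling) that vary across toolboxes;
  this package implements the unsmoothed per-sample convention and
  documents it, so absolute duration/occurrence values are comparable
  only to pipelines with the same convention.
* ICC confidence intervals assume balanced complete data after
  listwise dropping; no covariates are supported in the reliability
  stage (by design).
* The EDF codec requires whole-second, integer-rate recordings.
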
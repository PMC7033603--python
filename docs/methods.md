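# Methods

`gaitenv` re-implements, as a tested and reusable pipeline, the
accelerometer-based discrimination of running environments (treadmill vs.
outdoor sidewalk) from a single lower-back sensor: preprocessing of raw
tri-axial center-of-mass accelerations, step segmentation, a 25-feature
gait description, iterated wrapper feature selection, and participant-wise
SVM classification with independent-cohort evaluation. Because no public
recording of the original cohorts exists, a synthetic-data generator with
planted ground truth stands in for the human data; every empirical number
in this document is computed by the test suite or `scripts/acceptance.py`,
not quoted from elsewhere.

## Signal model of the synthetic generator

A run is a train of alternating left/right step pulses. Step *i* has
duration `T_i = T0 (1 + eta_i)`, `eta_i ~ N(0, sigma_t^2)` (stride-to-stride
timing jitter). Within a step, with phase `tau in [0, 1)`:

- **VT** (vertical): `amp_vt * m_i * (sin(pi tau) - 2/pi)` — an impact
  half-sine, mean-removed per step. The DC removal is deliberate: over a
  periodic gait cycle the center of mass returns to its height, so the only
  DC component of the vertical axis is the gravitational reaction. This
  also makes gravity alignment well-posed (the mean acceleration direction
  is the true vertical) and gravity subtraction exact.
- **AP** (anterior-posterior): `amp_ap * m_i * (sin(2 pi tau) - 0.3 cos(4
  pi tau))` — a biphasic braking/propulsion pulse. The quadrature second
  harmonic gives the waveform a positive third moment along the direction
  of travel, mimicking the asymmetric push-off of real AP traces; a pure
  full-sine would have exactly zero skewness and the forward/backward
  orientation of the heading alignment would be undecidable.
- **ML** (medial-lateral): `s_i * amp_ml * m_i * sin(pi tau)` with `s_i`
  alternating sign by stance foot, so ML anti-correlates at the step lag
  and correlates at the stride lag.

`m_i = (1 + eps_i)(1 ± gamma)` carries per-step amplitude jitter
(`eps_i ~ N(0, sigma_a^2)`) and left/right asymmetry `gamma` (+ for right
steps). Gravity (+9.81 m/s²) is added along true vertical, the signal is
rotated into a mis-mounted sensor frame (roll/pitch tilt plus a heading yaw
about vertical; sensor axes x right, y up, z posterior), and white noise is
added last. Sidewalk-analog runs consist of two independently generated
segments (the out-and-back legs) and a slow (0.05 Hz) sinusoidal amplitude
modulation standing in for incline/curve non-stationarity. The generator
plants ground truth per run: contact events (VT pulse peak times — the
standard initial-contact proxy for CoM accelerometry, and the events the
peak-picking detector localizes), foot labels, the pre-rotation anatomical
signal, and the mounting rotation.

### Archetypes and effect scale

Two presets encode the environment contrast. The *consistent* archetype
(treadmill analog: constant belt speed, flat uniform surface) has lower
timing and amplitude jitter and a larger vertical energy share; the
*variable* archetype (sidewalk analog) has higher jitters, a larger AP
share, the slow amplitude modulation, and a higher mean speed. All
contrasts scale linearly with `effect_scale`; at 0 the presets are
identical, so the two conditions are exchangeable — this includes the
condition speed means (2.78 vs. 3.24 m/s at `effect_scale` 1), because
speed is the 25th feature and an unconditional speed gap would silently
break the null. Defaults at `effect_scale = 1` (per step, before
participant effects):

| parameter | consistent | variable |
|---|---|---|
| step period T0 (s) | 0.35 | 0.35 |
| timing jitter sigma_t | 0.021 | 0.045 |
| amplitude jitter sigma_a | 0.035 | 0.07 |
| amp VT / ML / AP (m/s²) | 8.4 / 1.5 / 2.375 | 7.6 / 1.5 / 2.75 |
| slow modulation depth | 0 | 0.05 |
| speed (m/s) | 2.78 | 3.24 |
| asymmetry gamma | 0.05 | 0.05 |
| tilt (roll, pitch) / heading (deg) | (5, 3) / 8 | (5, 3) / 8 |
| noise SD (m/s²) | 0.4 | 0.4 |

### Cohorts and participant effects

`CohortDesign` mirrors the three-protocol study design: 28 treadmill-only
and 25 sidewalk-only participants (training split) and 16 who run in both
environments (independent testing split) — 85 runs, 53 training and 32
testing rows. Each participant receives log-normal random effects drawn
once and shared across their runs: multipliers on step period (SD 0.05),
per-axis amplitudes (SD 0.12), speed (SD 0.09), and on the timing and
amplitude jitter magnitudes (SD 0.3). The jitter effects matter: without
between-participant variability in the regularity/variability features, a
single feature separates the archetypes perfectly and the selection stage
degenerates to one feature — unlike the multi-feature structure the method
is designed to exercise. With them, the strongest single features sit at a
standardized group difference (Cohen's d) around 1.3–1.7 and the pipeline
produces graded, partly overlapping evidence, typically retaining ~5–10
features. Per-run RNG streams derive from (cohort seed, participant index,
condition), so enlarging a cohort never perturbs existing runs.
Demographics (height, mass, age) are drawn from one common distribution
for all protocols, matching a null across protocol groups.

Runs are 40 s (one 40 s treadmill segment; two 20 s sidewalk legs) at
201.03 Hz rather than the 5-minute originals — roughly 110 steps per run,
enough for stable stride-lag autocorrelations while keeping a full 85-run
cohort extraction around ten seconds.

## Preprocessing

Order: 4th-order Butterworth low-pass at 10 Hz → trim 5% from each end of
each segment → gravity alignment → heading alignment.

- The filter is applied forward-backward (zero phase) so step-event timing
  is unbiased; the effective attenuation is the squared magnitude response.
  Filtering and trimming act per segment; a sidewalk turnaround never
  leaks across legs. `floor(fraction * len)` samples are dropped per end.
- Gravity alignment uses the quasi-static assumption: the per-segment mean
  acceleration direction estimates true vertical. The minimal rotation
  taking that direction onto vertical is applied, axes are re-ordered to
  (VT, ML, AP), and 9.81 m/s² is subtracted from VT. A mean magnitude
  below 5 m/s² is rejected (the sensor is not seeing gravity). Inputs in
  g-units are converted at load with an explicit flag.
- Heading alignment takes the principal axis of the horizontal (ML, AP)
  covariance as the direction of travel and rotates it onto AP; the
  orientation along that axis is fixed by requiring non-negative mean AP
  skewness (forward running brakes hard and pushes off slowly). An
  isotropic horizontal covariance (below 1e-12 anisotropy) leaves the
  rotation at identity with a warning status. Rotations are proper and
  preserve per-sample resultant magnitude to 1e-9.
- Recovery accuracy on noiseless runs: tilt to within ~0.05° (the residual
  is second-order coupling between roll and pitch in the minimal-rotation
  convention, below ~0.5° for tilts up to ~15°), heading to within 1°, and
  the full chain reproduces the generator's pre-rotation signal to well
  under 2% RMS.

## Step segmentation

The dominant step period is the lag of the first "dominant" peak (≥ 70% of
the in-band maximum, so that a stride-lag peak elevated by asymmetry does
not shadow the step-lag peak) of the unbiased VT autocorrelation within
0.25–1.0 s. A best in-band peak below 0.2 is rejected as not gait-like
(white-noise autocorrelation fluctuations are an order of magnitude
smaller). Contacts are VT maxima above the 60th percentile separated by at
least half the period; runs with fewer than 30 contacts are rejected.
Inter-contact intervals outside [0.5, 1.5] × the dominant period are
excluded as detection dropouts (a single missed pulse produces a ~2×
interval, which this band removes); a stride is two consecutive retained
steps, so stride durations are exactly the sums of their component steps.
Each retained step is linearly resampled to 50 points per axis (linear
interpolation preserves endpoints and linear trends exactly). Segments are
segmented independently; no step spans a boundary.

## Features (25)

Axis-independent: mean speed, step-time CV, stride-time CV (sample SD over
mean), resultant RMS. Per axis (AP, ML, VT): step regularity, stride
regularity, symmetry, peak, RMS, RMS CV, ratio.

- *Regularity* is the unbiased autocorrelation coefficient
  `[sum x_t x_(t+lag) / (n - lag)] / [sum x_t^2 / n]` of the mean-removed
  axis signal at the mean step or stride lag (rounded to samples). It is
  computed on the continuous per-segment mean-removed signal — the stride
  lag needs the unnormalized time base — and averaged across segments
  weighted by length, avoiding cross-boundary artifacts on two-leg runs.
  *Symmetry* is the step/stride regularity ratio (1 for perfectly
  left/right-symmetric gait); a zero stride regularity makes it undefined
  (reported missing).
- *RMS* per axis is taken over the whole retained mean-removed signal;
  *resultant RMS* is the RMS of the per-sample Euclidean norm of the three
  mean-removed axes, so the squared axis ratios sum to exactly 1 — an
  identity the tests enforce to 1e-9. *Peak* and *RMS CV* (SD/mean of
  per-step RMS across steps) use the 50-point step matrix.
- Gravity is subtracted before any feature computation (declared here
  because RMS-based features depend on this choice); per-axis mean removal
  precedes all RMS/autocorrelation computations.

## Feature selection

Subject-wise forward-sequential selection with an LDA wrapper: each of 100
iterations draws a fresh participant-wise 10-fold partition (all of one
participant's rows in one fold; folds stratified by condition where counts
allow) and greedily adds the feature minimizing the cross-validated
misclassification of a two-class pooled-covariance equal-prior linear
discriminant, standardized with training-fold statistics. The search stops
when no candidate strictly reduces the error; ties break to the lowest
index in the canonical feature order. The discriminant is evaluated in
closed form from per-fold class means and a pooled covariance computed
once and sliced per candidate subset (a singular slice gets a 1e-8 ridge
with a warning); the tests verify fold-by-fold agreement with
`sklearn.discriminant_analysis.LinearDiscriminantAnalysis` and, on
two-Gaussian data at n = 2000, with the closed-form boundary error
`Phi(-delta / 2 sigma)`. Features selected in at least 10% of iterations
are retained — the boundary is inclusive (exactly 10 of 100 qualifies) —
and each retained feature reports its mean 1-based selection rank.
Iterations differ only in fold partition (no data resampling). Speed
participates as a candidate like any other feature.

## Classification

An RBF-kernel SVM (sklearn `SVC`) on the retained features, standardized
by training statistics. Both hyper-parameters — box constraint C and
kernel scale gamma — are chosen by an inner stratified 5-fold grid search
over `10^{-3..3}` (7 × 7 grid), best mean accuracy, ties to the smaller C
(then smaller gamma); the inner split count is capped by the smaller class
so stratification stays valid on small cohorts. Evaluation is
participant-wise 10-fold CV of the training split plus independent
evaluation on the both-environments split (one prediction per participant
per condition; accuracy is row-level), repeated over iterations that differ
in their fold partitions and inner-CV seeds, with per-participant correct-
prediction counts tallied. The treadmill/sidewalk label encoding is fixed
by sorted class order for reproducible decision values. Selection is run
once and its retained set reused across classification iterations.

## Statistics

Training-split condition contrasts use Welch independent t-tests (the
safer default absent an equal-variance assumption); testing-split
contrasts use paired t-tests on within-participant pairs. With r retained
features, m = 2r comparisons are judged at the Bonferroni threshold
alpha/m (for the 9-feature analog: 18 comparisons, 0.05/18 ≈ 0.003).
Degenerate inputs follow fixed conventions: a paired test on identical
vectors returns t = 0, p = 1, as does a one-way ANOVA on groups with no
variance anywhere. Cohort descriptives compare height/mass/age and
per-condition speeds across protocol groups by one-way ANOVA and the
both-environments speeds by a paired t-test; Shapiro–Wilk normality
p-values are reported without triggering any automatic nonparametric
fallback. Only the feature-contrast family is Bonferroni-adjusted.

## Calibration of the whole pipeline

- **Null** (`effect_scale = 0`): conditions are exchangeable. A single
  finite cohort still shows participant-sampling noise that participant-
  wise CV partially shares across folds (single-cohort CV means were
  observed anywhere between ~49% and ~63% while independent-test accuracy
  stayed at chance), so the chance-level check averages CV accuracy over
  iterations that *resample the cohort* — the expectation the
  exchangeability claim is actually about — and requires it within
  50 ± 10%.
- **Planted effect** (`effect_scale = 1`, default cohort): mean CV and
  independent-test accuracy over 20 iterations both reach at least 85%,
  and every planted contrast direction appears in the feature means
  (ratio VT and regularities higher in the consistent arm; ratio AP and
  RMS CVs higher in the variable arm).

## What the synthetic data does and does not show

The generator carries the statistical structure the analysis assumes —
quasi-periodicity, stride-to-stride timing/amplitude variability, L/R
asymmetry, axis energy shares, mounting misalignment, gravity, noise,
between-participant heterogeneity — but its pulses are stylized half/full
sines, not biomechanically fitted waveforms; there is no surface
interaction, no GPS or altitude structure, no frequency content above the
pulse harmonics, and test participants are drawn from the same random-
effect distribution as training participants (so train/test accuracy gaps
from cohort shift are not reproduced by default). Passing tests therefore
validate the pipeline's correctness and calibration, not any claim about
human running data.

## Known limitations

- The contact detector is a percentile-thresholded peak picker; it is
  isolated behind `detect_initial_contacts` so a different gait-event
  method can be swapped in.
- Symmetry is a ratio of signed autocorrelations and can be negative or
  exceed 1 on the ML axis, where step-lag regularity is negative by
  construction.
- The forward search's stopping rule (strict error decrease) can stop at
  one feature when a cohort is linearly separable on a single feature;
  retention frequencies then concentrate accordingly.
- Feature extraction rejects runs shorter than ~30 steps and signals
  without an in-band autocorrelation peak; there is no partial recovery.
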
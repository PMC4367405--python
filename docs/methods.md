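# Methods

This note documents the models, conventions and numerical choices behind
`kneerehab`, the assumptions of its synthetic test-bed, and what the test
suite does and does not demonstrate.

## Sensor model and coordinate conventions

Three IMUs are worn on the chest, thigh (near the knee) and shank (near the
ankle) of the working leg, y axis along the segment's long axis (pointing
proximal/up), x normal to the anterior surface, z mediolateral.
Acceleration is expressed in g as accelerometer output (specific force): an
axis pointing straight up reads +1 g at rest.  Streams are uniformly
sampled (40 Hz default) and assumed synchronized across sites; time is
implicit (index / rate).  Angular velocity is deg/s at the API surface and
rad/s internally; all angles cross module boundaries in degrees because the
clinical tolerances are specified in degrees.

## Gravity extraction

Median filter (3 samples, boundary samples replicated so length is
preserved) removes isolated spikes; a 2nd-order Butterworth low-pass at
0.5 Hz, applied forward-backward, extracts the gravity component with
exactly unit DC gain and zero phase shift.  Zero phase matters: repetition
boundaries are read off this trace, and a causal filter would shift them by
hundreds of milliseconds.  The motion component is exposed as the
raw-minus-gravity residual.  Gyroscope channels are median-filtered only;
their informative content is not confined to the sub-0.5 Hz band.

A knowing bias: at a repetition period T the movement's fundamental
(1/T Hz) is partially inside the filter transition band, so measured
excursions shrink by a factor ≈ 1/(1+(1/(T·0.5))⁴) — about 2.5 % at T = 5 s.
This is visible in the worked example (45° simulated raises measure
≈ 43°) and is well inside the ±10° clinical tolerance.

## Angle measures

Per-sample tilt angles follow the arctangent forms above, evaluated with
`atan2` so signs are preserved.  Two deliberate choices where naive
per-axis tilts break down:

* **Excursions use the long-axis (y) elevation.**  For planar movement the
  y-elevation range equals the transverse x-tilt range, but the x-tilt
  folds (|ρ| = 90° − |elevation|) when a segment crosses horizontal and is
  corrupted by axial roll; the signed elevation is monotone and
  roll-invariant.
* **Hip axial rotation** is measured as atan2(−A_z, Aₓ) of the gravity
  components — the angle by which gravity has migrated from the anterior to
  the mediolateral axis.  A long-axis tilt cannot see rotation about that
  very axis, and the transverse tilts conflate rotation with elevation;
  this form recovers the roll angle exactly, independent of elevation.  The
  roll is geometrically indeterminate when the segment is near vertical
  (both transverse components vanish), so samples with less than 20 % of
  gravity in the transverse plane are excluded; a window with no valid
  samples reports zero rotation.

Excursions are summarized by the robust range: median of the m largest
minus median of the m smallest samples, m = max(1, ⌈X/100·N⌉), X = 10 by
default.  It cancels constant mounting offsets (so small sensor-placement
errors do not bias excursions) and resists residual spikes; for X·N ≤ 100
it degrades gracefully to max − min.  Initial knee flexion is the median of
the first 10 % of the window.  The terminal ("full extension") angle is the
bottom-decile median of the instantaneous flexion trace rather than the
last 10 % of the window: windows run rest-to-rest, so the movement's
terminal posture is the low-flexion extreme inside the window, not the
window's final samples.

The knee flexion convention is thigh_raise − shank_raise: a bent knee makes
the shank excursion lag the thigh's by the flexion angle.

### Gyroscope-fused inclination

The accelerometer output O mixes translational acceleration and gravity
(O_i = a_i − g_i per axis).  For a segment pivoting about its proximal
joint, the sensor's translational acceleration is r̈ = ẇ×r + w×(w×r) with w
from the gyroscope (angular acceleration by central differences, one-sided
at the boundaries) and r the joint-to-sensor lever arm (default 0.25 m,
user-configurable — it depends on anthropometry and mounting).  Gravity is
recovered as g = r̈ − O and converted to an inclination against the
vertical, arccos(−g_y/‖g‖), clamped to the arccos domain (a warning is
logged if the clamp exceeds 0.02).  The inclination is computed on the
recovered gravity rather than on the raw accelerometer output: that choice
reproduces the static identity exactly and keeps the estimate clean during
motion, which is the entire point of the correction.  With w = 0 the
formula reduces to the accelerometer-only inclination.

## Repetition segmentation

All three exercises move the shank away from a resting posture and back, so
repetition boundaries are rest returns.  The segmentation trace is the
great-circle angle between the instantaneous shank gravity direction and
the resting direction (median over the first 0.5 s; recordings are assumed
to start at rest).  This trace is non-negative, zero exactly at rest for
every exercise and movement direction, and well-conditioned even when the
shank is vertical, where individual tilt angles degenerate.  Valleys with
prominence ≥ 5° and spacing ≥ 1 s become boundaries; the recording ends are
implicit boundaries so the first and last repetitions are kept.  Windows
shorter than 1 s or with excursion below the prominence floor (no movement)
are dropped — hence a static recording yields zero repetitions, and
repetitions whose jittered amplitude collapses toward the floor can be
genuinely lost (a handful per 1400 at default noise).  The defaults (5°,
1 s, 1 s) sit an order of magnitude below the exercises' ≥ 15° excursions
and multi-second cadence; all are configurable.  Because boundaries are
event-defined, repetition counts are invariant to the user's pace.

## Features (26 per repetition)

* Means of the raw acceleration per site and axis (9).  Raw, not
  gravity-filtered: the static posture (standing vs. supine) must be
  encoded, and it is exactly the gravity component that carries it.
* First five FFT power-spectrum magnitudes of the gravity-removed long-axis
  acceleration per site (15), after linear resampling of the
  variable-length window to 128 samples (~3 s at 40 Hz, power of two).
  Resampling makes spectral bins commensurate across repetition durations.
  Magnitudes are normalized by length so Parseval reads
  Σ|X_k/N|² = mean(x²); component naming is 1-based (T2 = first non-DC
  thigh bin).  The channel is selectable (`gravity_removed_y` default,
  `raw_y` alternative).
* Peak angles AngT (thigh excursion) and AngS (shank excursion) from the
  robust range (2).

Feature blocks are ordered thigh, shank, chest — by relevance to knee
motion — and that order doubles as the deterministic tie-break in tree
training (below).

## Exercise classification

CART: greedy binary splits minimizing Gini impurity with an exhaustive
threshold search (midpoints between consecutive distinct values), then
weakest-link cost-complexity pruning.  The pruning strength is chosen by
internal stratified 10-fold CV over the geometric midpoints of the master
tree's critical α sequence; the α with minimal mean CV error wins, ties
going to the larger α (smaller tree).  The terminal-node count is therefore
data-driven, not fixed.  Determinism is part of the contract: samples with
feature ≤ threshold go left, and among splits with exactly equal impurity
decrease the earlier feature wins.  Such exact ties actually occur here —
with the protocol's class sizes, a split isolating QSM on a thigh mean and
one isolating SAE on AngT can tie — and the feature order resolves them
reproducibly.  Trees serialize to a human-readable nested text format with
a version header.

Baselines: Gaussian naive Bayes and kNN (Euclidean, K = 5, majority vote,
vote ties broken by the nearest neighbor), both on z-scored features
(training-set statistics; zero variances floored at 1e-9 with a warning).
The tree intentionally uses raw features — axis-aligned splits are
scale-invariant.

## Posture rules

Nominal target angles come from the exercise definitions (45° SLR raise,
45° QSM squat, 0° full extension, 0° upright trunk, 25° SAE initial
flexion); the tolerances are the clinical bands listed in the README.
Codified rules: SLR — |raise − 45| > 10, knee flexion > 20, |rotation| >
20; QSM — trunk bend > 15, |squat − 45| > 15; SAE — initial flexion >
25 + 7 (the additive reading of the initial-flexion rule; a configuration
flag switches to the bare 25° cut), |terminal flexion| > 7.  All
comparisons are strict, so a measure exactly at tolerance is acceptable.
Every applicable rule runs on every repetition — multiple simultaneous
errors are reported — and the hierarchical order (trunk before squat, knee
before rotation before raise) affects only the reporting order, never
suppression.

## Evaluation

Two per-repetition metrics: type-classification accuracy, and
improper-identification accuracy, scored as an exact match of the
(type, error-set) pair — a repetition with a misclassified type counts
wrong regardless of its flags, and a single missing or spurious error label
fails the repetition.  This is the strictest reasonable scoring and is why
improper accuracy trails type accuracy.  Schemes: stratified 10-fold CV;
within-subject CV (stratified 5-fold inside each subject, every
subject-fold a fold); leave-one-subject-out.  Folds are seeded, disjoint
and exhaustive; the classifier is retrained per fold while the rule
thresholds stay fixed (they are clinical constants, not fitted
parameters).  Accuracies are reported in percent with fold-level standard
deviations, per exercise and overall.

## Synthetic test-bed

Each segment is a rigid body with a raised-cosine joint-angle profile per
repetition — C¹, starting and ending at rest, so abutting repetitions chain
smoothly.  The accelerometer output is the exact gravity projection plus
the translational acceleration of the sensor point (pivot about the
proximal joint, numerical differentiation of the exact orientation
trajectory) plus white noise (σ = 0.02 g); the gyroscope is the exact
body-frame angular velocity plus white noise (σ = 0.5 deg/s).  Per-subject
draws: cadence (5 s ± 20 %), per-site mounting misalignment (σ = 3°
elevation and roll offsets); per repetition: amplitude jitter (σ = 3°) and
± 5 % duration jitter.  Rest postures are drawn per session so the signal
stays continuous across repetitions.

Postures: SLR and SAE supine (chest flat); SAE thigh propped at 25° over a
bolster with the knee extending from 25° flexion to 0°; QSM standing with
the thigh pitch equal to the squat angle, a 15° shank lean and a 2°
incidental trunk sway.  Improper variants sit at nominal ± (tolerance +
5°): e.g. SLR raises of 60°/30° (the 20-repetition variant splits 10
above / 10 below 45°), 25° knee flexion, 25° hip rotation, 20° trunk bend,
37° SAE initial flexion, 12° terminal flexion, 25° (shallow) squat.  The
5° margin keeps errors detectable while amplitude jitter creates genuine
near-boundary cases, so improper identification stays below 100 % at
default noise by construction.

What the simulator does **not** model: soft-tissue artifact, gyroscope
bias/drift, asynchronous or dropped samples, multi-joint coupling beyond
single-pivot segments, out-of-sagittal motion except the SLR rotation
variant, and real device noise spectra.  Passing tests therefore
demonstrate the pipeline's correctness against exact kinematic ground truth
and its robustness to white noise, jitter and mounting offsets — not
performance on human recordings.

## Problem sizes and numerical choices

The bundled benchmark uses the full study protocol at its natural size — 10
subjects × 140 repetitions (≈ 1400 windows) — and runs in well under a
minute; oracle checks use 100–1000 random cases each.  Numerical details:
arccos arguments clamped to [−1, 1] (warn beyond 1.02); tilt angles of a
(near-)zero gravity vector are an error ("no gravity reference"); filtfilt
padding is three time constants of the 0.5 Hz filter; robust-range
tail size m = max(1, ⌈X %·N⌉); repetition windows shorter than 10 samples
are rejected as degenerate; all RNG flows through explicit integer seeds
(subject seeds spawned from the master seed via `numpy.random.SeedSequence`).

## Known limitations

* Excursion estimates carry the ~2.5 % low-pass shrinkage noted above;
  compensating it would couple the filter to the cadence estimate and was
  not worth the coupling.
* The hip-rotation measure reports the roll magnitude only while the thigh
  is ≥ ~12° away from vertical; standing exercises therefore get no
  rotation signal at rest (none is geometrically available).
* The gyro-fusion path models a single fixed pivot; it degrades when the
  proximal joint itself translates.
* Improper-identification accuracy is sensitive to the exact-match scoring;
  per-label scoring would read several points higher.
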
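# Methods

This note documents the models, conventions, parameter choices and
limitations behind `imu_qc`, in the order data flows through the package.

## Orientation representation and quality labelling

Quaternions are scalar-first `[w, x, y, z]` with the Hamilton product
(`imu_qc.orientation`). The convention is stated here and in the CSV
headers because nothing downstream can detect a convention mismatch.
Antipodal quaternions represent the same rotation, so every series is made
hemisphere-continuous (sign flipped whenever the dot product of consecutive
samples is negative) before interpolation or angle extraction; without
this, resampling across a sign flip produces near-zero-norm interpolants
and the motion angle jumps by ~360°.

Joint orientation is `conj(q_prox) ⊗ q_dist`, re-referenced to the first
sample of each segment, and reduced to the scalar global motion angle
`θ = 2·acos(clamp(|w|, 0, 1))` (the clamp absorbs floating-point overshoot
of |w| above 1). The global-motion reading deliberately avoids
plane-of-motion decomposition: it measures *technological* accuracy without
entangling it with biomechanical model or alignment errors. Accuracy of a
segment is the RMSD between estimated and reference angle, and the label is
a pure function of RMSD: good ≤ 5°, tolerable ≤ 10°, bad > 10°. Both
boundaries are assigned to the milder category (5° is good, 10° is
tolerable), matching the inclusive "RMSD ≤ 5°" convention of the quality
bands; the bands partition [0, ∞) with no gaps.

## Signal preparation

AHRS-side streams (raw 9-axis at 60 Hz and the estimated orientations) are
linearly resampled to the 100 Hz reference grid. Linear interpolation is
the simplest scheme consistent with the features used downstream — segment
means and variances — whose worst-case sinusoid error `(ω·dt)²/8` (~0.03
for a 5 Hz component at 60 Hz) is negligible against the feature noise
floor. Quaternions are resampled by component-wise lerp plus
renormalization, adequate for a 60→100 Hz step where successive rotations
are close.

Clock offset between the AHRS and the reference is recovered by integer-lag
normalized cross-correlation of the global-motion angle of the most mobile
joint (largest variance of the angle increments), ties broken toward the
smallest |lag|. Sub-sample refinement is pointless here for the same
reason linear interpolation suffices: features are segment averages.
Segmentation consumes an annotation table (`trial_id, phase, joint, start,
end`, 0-based half-open on the reference grid); annotations must be ordered
and non-overlapping per joint. Automatic task segmentation is out of
scope.

## Features and normalization

"Magnetic field" is summarized per module by the Euclidean norm of the
magnetometer triplet. The norm is orientation-invariant, so it
characterizes the *environment* (what the features are meant to capture)
rather than the pose; the calibration reference field is a config scalar
(`mag_reference`, default 1.0 in normalized field units, i.e. the
undisturbed field has norm 1). Acceleration is the raw accelerometer norm
including gravity (1 g at rest) — the classifier is supposed to see the
sensor's actual operating conditions, not a gravity-compensated signal.
Axis proportions use means of |ω_axis| so that sign-symmetric oscillation
still registers a direction; a motionless segment falls back to
(1/3, 1/3, 1/3). Variances are population variances (÷N). For the first
phase of a trial, where no previous segment exists, f16 falls back to f15.

Normalization is `sign(x)·sqrt(|x|)` (four features are signed
differences, so a plain square root would be undefined), then a z-score
with mean/SD estimated **on the training partition only**, clipped to ±3
SD in a single pass. The statistics persist inside the model file and are
applied unchanged to validation data.

## The classifier

A 16-6-1 network with tanh activations throughout; six hidden units are
enough to express the interaction between environment and velocity
features while remaining hard to overfit with ~2000 training segments.
Training minimizes

    L = Σ_i g(c_i) · (s_i − y_i)² + λ‖W‖²

with y = +1 for good and −1 otherwise, λ on weights only. "Bayesian"
regularized training is realized as an L2 penalty with λ chosen from a
small grid (1e-4, 1e-3, 1e-2) on an inner participant-level fold of the
training half; full evidence-framework re-estimation of λ is deliberately
out of scope.

Per-category error gains balance the two sides of the binary decision:
good segments carry `α·N/N_good` and the rejected categories share the
remaining mass uniformly, `(1−α)·N/(N_tol + N_bad)`. Giving each of the
three RMSD categories equal total mass instead (a natural alternative)
puts 2/3 of the loss on the reject side and measurably biases the
threshold-0 decision toward rejection (held-out specificity ~0.94 but
sensitivity stuck near 0.77 on default cohorts); side-balancing restores
the intended symmetry between the two error types while still
up-weighting rare categories per segment. The operating point α is
selected, jointly with λ, on an inner participant-level fold of the
training half by maximizing min(sensitivity, specificity) — the balance
criterion the training loop is judged by — over the small grid α ∈
{0.5, 0.6, 0.7}, λ ∈ {1e-4, 1e-3, 1e-2}. All three gains remain
individually configurable, which bypasses the α search.

Optimization is full-batch gradient backpropagation with a bold-driver
step size: a step that would increase the loss is rejected and the step
halved, otherwise it is accepted and the step grown by 10 %. This makes
the loss curve monotone non-increasing by construction and training
bit-reproducible for a fixed seed (uniform ±0.5 init from a seeded
generator; default 8000 epochs, a few seconds at this problem size). A
segment is accepted iff the output score is strictly positive; an exact 0
is conservatively rejected.

## Synthetic cohorts

The generator (`imu_qc.synthetic`) emulates the study design the method is
meant for: `n_participants` = 20, 9 timed-up-and-go trials each (speeds
natural/slow/fast scale angular-velocity amplitudes by 1.0/0.7/1.4 and
durations inversely), phases sit (3.0 s at natural speed), sit-to-stand
(1.5 s), two walking bouts (2.5 s), turn (2.0 s), turn-to-sit (2.0 s),
with modules on trunk, pelvis, thigh, shank and foot tracking the trunk,
hip, knee and ankle joints.

Ground truth is analytic: minimum-jerk posture transfers (hip 70°, knee
80°, ankle 20°, trunk 15° across sit-to-stand, reversed at turn-to-sit),
windowed sinusoidal flexion-extension during gait (hip 20°, knee 32°,
ankle 14°, trunk 4° at 0.9 Hz · speed), a minimum-jerk 180° heading change
during the turn, and small seated sway. Per-participant lognormal-ish
amplitude (SD 12 %) and cadence (SD 8 %) factors emulate anthropometric
heterogeneity. Module orientations are chained (pelvis → trunk/thigh →
shank → foot), so distal modules naturally accumulate the angular velocity
of every joint above them. Raw signals are derived from the true
kinematics: gyroscope from finite orientation differences (so noise-free
integration reproduces the truth to numerical precision), accelerometer as
gravity rotated into the module frame plus a walking bounce, magnetometer
as a homogeneous unit field rotated into the module frame; Gaussian noise
(gyro 1 °/s, accel 0.02 g, mag 0.005) on top.

Magnetic disturbance emulates a floor-borne field: per trial an amplitude
is drawn uniformly in [0, 0.8] and each module's field magnitude is scaled
by `1 + a·exp(−h/0.4 m)` at its height h (foot 0.10 m … trunk 1.30 m),
with a 20 % slow temporal wobble. The fusion filter itself is *not*
re-implemented — the QC method treats the AHRS as a black box, consuming
only its outputs —
so AHRS estimates are truth composed with a heading-axis drift whose rate
is `30 °/s per unit field deviation + 0.05 °/s per °/s of smoothed gyro
norm above ω₀ = 150 °/s`, with per-module random sign and lognormal gain
jitter (σ = 0.25), plus 0.3° white orientation noise (0.2° on the
reference, emulating gold-standard noise). Drift is applied about the
vertical axis, the axis magnetometers constrain. These gains were
calibrated once, by construction, so that segment RMSD spans the
good/tolerable/bad bands with the characteristic joint ordering (trunk
best, ankle worst, roughly 60/10/30 % good/tolerable/bad overall); they
are not fit to any external number.

What the generator does **not** emulate: physiologically exact gait
kinematics, soft-tissue artefacts, sensor bias/scale errors, fusion-filter
transients, or vector-valued field disturbances. Passing tests on
synthetic cohorts therefore demonstrate that the pipeline recovers a
feature-predictable accept/reject structure of the kind the method
exploits — not field performance on any particular hardware.

## Evaluation

Sensitivity = accepted-good / good; specificity = rejected-bad / bad.
Tolerable segments enter neither metric (they are reported in the label
distribution instead), so both metrics are invariant to relabelling
within the tolerable band. The train/validation split is always at the
participant level (seeded shuffle, 50/50); a guard raises if training rows
contain a validation participant. The pre/post-QC table reports, per task
and joint, N_total, N_good, mean (SD) RMSD of all segments, N_accepted and
mean (SD) RMSD of accepted segments, with the two walking bouts pooled
into a single "walk" row.

## Numerical and edge-case choices

- acos arguments clamped to [0, 1]; quaternion norms validated (≥ 1e-12).
- Cross-correlation on a zero-variance signal raises rather than returning
  an arbitrary lag.
- Clamp-padding at stream edges after lag alignment; the generator leaves
  0.6 s lead-in / 0.3 s tail margins so segments never touch the padding.
- Zero-variance features raise a named error at normalizer fit time.
- A training set without both accept and reject examples raises.
- Sensitivity/specificity with an empty reference class raise rather than
  returning NaN silently.

## Problem sizes

Default cohorts are 20 participants × 9 trials ≈ 14 s each at 60/100 Hz —
about 4300 joint-segments, generated in ~5 s; a full pipeline run
(preparation, features, λ grid, training, evaluation) takes ~15–20 s on
one CPU. The acceptance script repeats the end-to-end experiment on three
independent cohorts and reports medians, ~1 min total.

## Known limitations

- The error model is phenomenological; its gains control difficulty, and
  absolute sensitivity/specificity values on synthetic cohorts move with
  them. Only the qualitative structure (joint ordering, driver→error
  monotonicity) is calibration-anchored.
- Heading drift about the vertical axis interacts with the global-motion
  angle nonlinearly: during large flexion the error axis is nearly
  orthogonal to the joint axis and its effect on θ is quadratically
  suppressed. The feature set can express this (velocity features proxy
  flexion magnitude), but it makes walking-phase labels intrinsically
  noisier than seated ones.
- Integer-lag synchronization assumes identical clock *rates*; only
  offsets are modelled and recovered.
- `pre_post_table` reports the stated column definitions literally;
  N_accepted in a cell may exceed N_good there whenever tolerable/bad
  segments are accepted.
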
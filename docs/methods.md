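# Methods

## Problem

Optical motion capture with force plates is the laboratory gold standard
for gait analysis, but inertial measurement units (IMUs) are what can be
worn in daily life. `gaitsim` implements a complete pipeline for bridging
the two: simulate what a body-worn IMU *would have read* from optically
measured segment poses, calibrate the unknown sensor-to-segment placement,
synchronize the unsynchronized clocks of the two systems, and train a
feed-forward network that maps one gait cycle of five-sensor IMU data to
the 3D joint angles and joint moments of the lower limbs.

## Quaternion kinematics (`quatkin`, `imusim`)

Orientations are Hamilton-convention unit quaternions, scalar-first, with
`ijk = -1`. The global frame is right-handed, X forward, Y left, Z up;
gravity acts along -Z on masses.

A sensor rigidly mounted on a segment sits at a constant 6-DoF offset
`z = (x1, x2, x3, phi1, phi2, phi3)`: translation `x` in the segment frame
(metres) and three angles (radians) composed intrinsically X-Y-Z into the
offset rotation `q_phi`. Per frame,

    q_sensor = q_seg ⊗ q_phi,     x_hat = x0 + q_seg ⊗ x ⊗ q_seg*.

**Gyroscope.** The body-frame increment between consecutive frames is
`dq = q_k* ⊗ q_{k+1}`, giving

    omega = (2 / dt) · (dq_v / ||dq_v||) · atan2(||dq_v||, dq_0),

the angular rate a physical gyroscope reads (sensor frame). Numerical
choices: quaternion sign continuity is enforced before differencing
(`q` and `-q` encode the same rotation; the formula is ill-behaved across
the double cover); a vanishing increment returns exactly zero; the last
frame reuses the final pair (forward difference), since no successor
exists. The pair estimate is centred on the half-sample; tests that
compare against the differential oracle `2 q* ⊗ q̇` average consecutive
pairs to recover O(dt²) agreement.

**Accelerometer.** Position is differentiated twice with central
differences (exact on quadratics); the first and last frames use the
one-sided second-difference forms. The symmetric backward form
`(x_n - 2 x_{n-1} + x_{n-2}) / dt²` is used at the last frame — a
one-signed variant sometimes seen in print is not a consistent second
difference and is treated as a typo. The reading is the specific force

    a_g = a + g,      a_l = q_sensor* ⊗ a_g ⊗ q_sensor,

with `a` the kinematic acceleration and `g = (0, 0, +9.81)` m/s² the
reaction to the gravity field: at rest the up axis reads +9.81, in free
fall all axes read zero, and a sensor flipped upside down reads -9.81.
Formulations that put a minus sign on the motion term define `a` as the
inertial reaction (the negative of the kinematic acceleration); composing
that sign with a kinematic second derivative would read +2g in free fall,
so the specific-force form is used throughout. No gyroscope drift, bias,
noise floor, or magnetometer model is included.

Angle-axis quaternions store the conventional half-angle:
`q = (cos(θ/2), u sin(θ/2))` rotates by θ about unit axis u. Notations
that print `(cos θ, u sin θ)` leave the half-angle implicit.

## Sensor-pose fitting (`posefit`)

The placement of a worn sensor is never exactly known. It is recovered by
minimizing the summed squared mismatch between measured and simulated
channels,

    Θ(z) = Σ_t ||ω_m - ω_s(z)||² + Σ_t ||a_m - a_s(z)||²,

subject to |x_i| ≤ 50 mm and 0 ≤ phi_i ≤ π/2 — wide enough to absorb
realistic placement error, narrow enough to keep the segment assignment
unambiguous. The angular-rate and acceleration terms carry different units
((rad/s)² vs (m/s²)²) and are summed unweighted by default; an
`accel_weight` parameter exposes the choice. The three bounded `phi`
components are interpreted as rotation angles (an angular range is the
natural reading of a [0, π/2] bound), composed intrinsically X-Y-Z.

Minimization uses L-BFGS-B (bounded local, numerical gradients) with five
seeded starts inside the box; the best optimum wins, and the result is
never worse than the supplied initial guess. On noise-free synthetic
trials the true pose is recovered to micrometres and ~1e-8 rad (the
tolerance targets are 2 mm and 0.02 rad). Motionless input leaves the pose
unidentifiable beyond the gravity direction; the fitter warns and reports
non-convergence. Since one sensor stays put for a subject's whole session,
`best_pose_per_subject` re-simulates every per-trial candidate on all
trials and keeps the one with the lowest mean RMSE.

## Synchronization (`sync`)

The IMU and optical clocks share no trigger. The constant offset δ is
estimated from one shared channel (pelvis medio-lateral acceleration) by
minimizing `Υ(δ) = Σ_t (a_m(t) - a_s(t - δ))²` over the overlap, with
fractional shifts by linear interpolation, using Nelder-Mead. The start
value is the time between the first prominent local maximum of each series
(prominence ≥ 0.2 of the range). First-peak seeding is fragile on
near-periodic signals — the "first" qualifying peak can belong to
different cycles, and a peak clipped at the series edge loses its
prominence — so a coarse pre-scan (0.02 s spacing over the ±2 s search
window) guards the Nelder-Mead start: the better of {peak-based init, best
grid point} is refined. By construction the solution is then at least as
good as any coarse grid point. The objective is the raw sum by default; a
`normalized` flag divides by overlap length to avoid shrink-the-overlap
minima when series lengths differ strongly. Only a constant offset is
modelled; clock drift is out of scope.

Noise-free injected offsets in ±2 s are recovered to well under half a
sample at 100 Hz; at 20 dB SNR the worst case over 50 draws stays within
one sample.

## Preprocessing (`preprocess`)

Fixed order: filter → segment → time-normalize.

- **Filtering**: zero-lag second-order low-pass Butterworth, 6 Hz default
  cutoff, applied forward-backward (`filtfilt`, odd reflective padding of
  3× the filter length). The net gain is the squared magnitude response;
  constants pass unchanged and peaks do not shift.
- **Gait cycles**: initial contacts from a threshold detector — local
  minima of the low-pass-filtered foot/ankle vertical position, separated
  by ≥ 0.4 s, prominence ≥ 0.2 of the range. This is a documented proxy
  with a pluggable interface, not a re-implementation of any published
  contact algorithm; the synthetic generator's own contact truth is the
  test oracle (agreement within ±3 frames).
- **Stance phases**: maximal runs with vertical GRF above 20 N (common
  force-plate practice; the threshold is configurable).
- **Time normalization**: each segment is linearly interpolated onto 101
  points spanning 0–100 % of the cycle, endpoints preserved exactly;
  idempotent.
- **Moment normalization**: joint moments are divided by body mass ×
  height, giving N·m kg⁻¹ m⁻¹. "Weight" is read as mass in kg; reading it
  as force (mass·g) would scale all normalized values by 9.81 but leaves
  nRMSE untouched, since that metric is scale-invariant.

Indexing is 0-based with half-open `[start, end)` segments everywhere.

## Network pipeline (`nnpipe`)

One sample is one time-normalized cycle: inputs 5 sensors × 6 channels ×
101 frames (3,030 features after channel-major unrolling), targets 18
joint curves × 101 frames (1,818 outputs). Channel order is segment-major
(pelvis, right thigh, left thigh, right shank, left shank; gyro xyz then
accel xyz), frozen and round-trip exact.

Full-scale defaults: hidden layers 4,000/6,000 with 20 % dropout and
12,500 steps per phase for the kinematic task; 6,000/4,000 with 40 %
dropout and 15,000 steps for the kinetic task; ReLU hidden units, linear
output, MSE loss, Adam at initial learning rate 1e-4, four training phases
with batch sizes 16-32-32-64. Activation, optimizer, loss,
standardization, and He-normal initialization are this package's choices
where the protocol leaves them open. Inputs *and* targets are z-scored
per feature with statistics from the training pool only (leakage-safe);
predictions return on the original scale. A `scale` multiplier shrinks
hidden widths and step counts proportionally for desk-scale runs without
touching the full-scale defaults. The implementation is a compact numpy
MLP (manual forward/backward pass, inverted dropout, seeded), deterministic
given its seed.

Validation is split by whole subject, always: a 5-fold plan with one fixed
test set for hyperparameter work, and leave-one-subject-out (no validation
set — hyperparameters fixed beforehand) for per-subject evaluation. A
leakage assertion re-scans every fold. Two training-pool scenarios mirror
the study design: measured data only, or measured plus simulated
(augmentation) data.

## Metrics (`metrics`)

Per channel over the 101-frame cycle: Pearson r, RMSE in native units,
nRMSE as a percentage of the *ground-truth* curve's range (the reference
curve is the documented choice of denominator). Peak analysis averages a
subject's steps first, then takes per-channel maxima of the mean step.
Scalar comparisons use a paired two-sided t-test and Cohen's d for paired
samples (`mean(diff)/sd(diff)`, ddof = 1). Degenerate inputs (flat curves,
zero-variance differences) yield NaN rather than exceptions so channel
aggregation never aborts. Curve-level r on the mean step is the default
aggregation; concatenated-step r is available by stacking.

## Synthetic gait generator (`gait_synth`)

The measured cohort this kind of pipeline is normally validated on cannot
be redistributed, so the generator produces a stand-in cohort: subjects
sampled around 1.77 ± 0.07 m and 72.3 ± 12.7 kg walk at the five study
speeds (0.8, 1.1, 1.4, 1.7, 2.0 m/s) at 100 or 125 Hz.

- **Curves**: each of the 18 angle and 18 moment channels is a sum of 2–4
  harmonics over the stride with gait-like shapes, speed-dependent
  amplitude gain (0.7 + 0.3·v/1.4), and a small seeded per-subject
  amplitude jitter (6 %). Template coefficients are pinned under a version
  number so tests can rely on exact values. Left lags right by half a
  stride.
- **Kinematic chain**: pelvis → hip → thigh → knee → shank with segment
  lengths fixed at standard anthropometric height fractions (thigh 0.245 H,
  shank 0.246 H, pelvis width 0.13 H). Stride length follows
  `0.83 · v^0.42` m, so stride time is length/speed by construction.
- **GRF**: the right-foot plate channel is a double-bump profile over the
  first 60 % of the stride (stance), zero in swing; with zero joint motion
  (quiet standing) it is exactly body weight, mass × 9.81 N.
- **Soft-tissue artifact**: skin-mounted sensors move relative to bone
  with speed-correlated noise. White noise band-passed to 8–15 Hz,
  re-centred and RMS-normalized exactly, scales to 3 mm and 0.01 rad RMS
  per unit amplitude × speed (m/s) on origin and orientation. The
  constants are this package's choices — chosen once for a clean
  linear-in-speed scaling law, not fitted to any measured artifact
  spectrum. Zero amplitude is the identity.
- **Contact truth**: the per-stride minimum of the right ankle height is
  recorded as the initial-contact frame, giving the segmentation oracle.

What the generator does *not* emulate: marker-level measurement, real
inter-subject kinematic variability (harmonic jitter is far tamer than
human variation), pathological gait, impact transients, or any validated
biomechanical coupling between the angle, moment, and GRF channels. A
network that scores r > 0.9 here demonstrates that the pipeline is wired
correctly and the mapping is learnable end to end — not that comparable
accuracy would be reached on measured human data.

## Pipeline and problem sizes (`pipeline`, CLI)

`run_pipeline` chains cohort generation, virtual-IMU simulation through
fixed per-subject "worn" poses (soft-tissue-noisy poses play the measured
role; clean poses through freshly sampled offsets play the simulated/
augmentation role), segmentation, normalization, subject-wise training,
and scoring. The demo configuration — 3 subjects, two or three speeds,
3–4 strides per trial, `scale = 0.02` — is the package's own desk-scale
default: it exercises every stage in about a minute on one CPU and
reaches mean per-channel r ≈ 0.99 (kinematic) and ≈ 0.98 (kinetic) under
leave-one-subject-out validation on the synthetic cohort. Trial files are
diff-able UTF-8 CSV with a `# key = value` metadata header; floats are
written at %.17g and re-parsed in round-trip mode, so file I/O is lossless.

## Known limitations

- The synthetic cohort is optimistic: templates share one harmonic family,
  so held-out subjects are easier to predict than real people.
- First-peak synchronization seeding requires a distinctive first maximum;
  the grid pre-scan mitigates but cannot fix pathological periodic inputs.
- The pose fitter is a local method; multi-start reduces, but does not
  eliminate, the risk of local minima on noisy real data.
- Full-scale network training (thousands of hidden units, 50k–60k steps)
  is supported by the configuration but is not what the tests run.
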
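# Methods

`cutcoord` implements, end to end on synthetic data, a pipeline for
quantifying and predicting the coordination variability of lower-limb
couplings during cutting movements (rapid changes of direction at 90, 135
and 180 degrees after a run-up). This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## Synthetic trials

Real recordings of this protocol (optical motion capture + force plate +
three inertial sensors) are not publicly available, so the package ships a
seeded generator whose output has the statistical structure the analysis
stages assume. Each trial is one movement cycle on a 200 Hz time base
(configurable), padded with rest samples:

- **Angle channels.** Fifteen joint/segment angles (hip/knee/ankle and
  thigh/leg in three planes) are truncated four-term Fourier templates with
  direction-dependent amplitude and offset. The template coefficients are
  synthetic fixture constants with plausible cutting-gait magnitudes; they
  carry no biological claim.
- **Inter-cycle variability.** Three seeded sources: a per-cycle phase
  shift (SD `phase_jitter_sd`, default 0.008 cycle fractions), a per-cycle
  lognormal amplitude factor (sigma `amp_jitter_sd`, default 0.03), and a
  smooth additive Gaussian-bump process whose pointwise SD is
  `noise_sd_angles` (default 2 degrees) times a variability envelope. The
  envelope is a direction-independent "U" (high during the braking phase,
  0-25% of the cycle; floor 0.35 elsewhere) plus a flat-topped bump over
  the swing window (default 65-100% of the cycle) multiplied by
  `swing_variability_scale[direction]` (defaults 1.0 / 1.6 / 1.6 for
  90 / 135 / 180 degrees). The perturbation is also scaled by the
  direction's template amplitude factor so that *relative* variability is
  comparable across directions before the swing scaling; without this the
  largest-amplitude condition (180 degrees) is systematically the least
  variable, which contradicts the structure the generator must emulate
  (135 and 180 more variable than 90 in late swing). An additive smooth
  process was preferred over a swing-localized time warp because it gives
  exact control over where inter-cycle variance lands and an exact
  zero-noise limit (all cycles identical when every stochastic scale is 0,
  hence coefficient of correspondence exactly 1 everywhere).
- **vGRF.** A two-peak contact profile in body weights (first peak ~1.7 BW
  at 15% of the cycle, second ~1.3 BW at 45%, valley ~0.5 BW), tapered to
  zero at the cycle edges and zero outside it, times body weight (default
  700 N). This guarantees exactly one contiguous above-threshold interval
  per trial. Because the analyzed task is a planted-foot turn, the whole
  analyzed cycle is treated as the contact phase; the conventional gait
  phase names (initial contact 0-10%, foot flat 11-25%, swing 26-75%, end
  of swing 76-100% of normalized time) are used as labels on the
  normalized axis.
- **IMU.** Three sensors (pelvis, thigh, calf); per sensor three
  accelerometer and three gyroscope channels (18 channels total,
  magnetometers excluded). Gyroscope channels are the first derivatives of
  the corresponding segment angles (deg/s); accelerometer channels are a
  0.3 m lever arm times angular acceleration plus a gravity projection
  (9.81 sin(angle)), plus white sensor noise (`noise_sd_imu`, default
  0.05 m/s^2 on accelerometers, 10x that in deg/s on gyroscopes).

Default sizing is 25 subjects x 9 cycles per direction = 225 trials per
direction (675 total). Subject identity enters as seeded per-subject
amplitude/offset modulation (`subject_heterogeneity`). All randomness
derives from one seed through named substreams; identical configs are
byte-identical.

## Preprocessing

Zero-phase filtering uses an order-4 Butterworth design applied
forward-backward (`scipy.signal.filtfilt`, reflective padding of 3x the
filter order), so the realized magnitude response is the squared
single-pass response: 6 Hz for angle channels, 30 Hz for the vGRF, 15 Hz
for IMU channels. The stance/contact window is the longest contiguous run
of filtered vGRF above 20 N (a common contact-detection convention).
Every channel is linearly interpolated over that window onto 101 points
(1% of normalized time each). Min-max scaling to [0, 1] is fitted on
training data only; out-of-range values in validation/test are logged,
never clipped.

## Vector coding: coefficient of correspondence

For a coupling (proximal, distal) with k cycles x 101 frames, each frame
interval i contributes per cycle the vector
(delta proximal, delta distal). The coefficient of correspondence is
r_i = a_i * m_i where

- a_i is the circular mean resultant length of the vector orientations
  across cycles (directional consistency);
- m_i = 1 - SD(l)/mean(l) of the vector magnitudes across cycles
  (population SD; magnitude consistency), clipped to [0, 1].

Conventions for degenerate intervals: if every cycle's vector is zero the
interval gets r = 1 (no movement is perfectly repeatable); zero-length
vectors are excluded from the circular mean but retained in the magnitude
statistics. r is invariant to cycle order, to a common positive scaling of
all angles, and to additive offsets. One published variant weights the
magnitude term by the maximum magnitude instead of the mean; the
coefficient-of-variation form used here was chosen because it is
scale-free, and the choice is confined to one function. Summary statistics
(mean, max) are reported over a configurable stride-percent window
(default the full 0-100%).

## Nonparametric 1-D statistical mapping

Subject-level r curves (one per subject x direction) are compared
node-wise with a one-way repeated-measures ANOVA F map (subject as block,
sphericity left to the permutation null). The null permutes direction
labels within subject, identically across nodes (curve-level
exchangeability — the only label-permutation scheme consistent with smooth
curves). The family-wise critical value is the empirical (1 - alpha)
quantile (method "higher") of the max-over-nodes statistic across
permutations, with the identity labeling always included; contiguous
supra-critical runs are clusters, and a cluster's p-value is the
proportion of permutations whose largest supra-critical cluster extent is
at least the observed extent (floored at 1/n_perm). Post hoc paired
contrasts use |t| maps with a within-subject sign-flip null at
Bonferroni-adjusted alpha (alpha/3 for three pairs); with n subjects the
2^n sign patterns are enumerated exhaustively whenever the requested
permutation count allows, making the result seed-independent. Zero-variance
nodes get t = 0 and are flagged rather than infinite. The default
permutation count is 10,000 (1,000 in the heavier simulation suites).
Shapiro-Wilk screening (scipy) routes non-normal samples to this
nonparametric branch; the parametric random-field branch is out of scope
because the emulated study's data failed normality.

## LSTM predictor

The cell is the standard gated recurrence (forget/input/output gates and
candidate cell state over the concatenated [h_{t-1}, x_t]); three cells
are stacked and a linear readout maps the top layer's hidden state at each
step to one predicted value, so a 101-step window yields the 100-interval
target curve. Implementation is plain numpy: forward, full
backpropagation through time, and Adam (lr 0.001, default decay
parameters), with Glorot-uniform initialization and forget-gate bias +1.
Gradients are validated against numerical differentiation; the batched
step is validated against a separate single-vector reference cell.

Per-direction configurations: 90 degrees -> 100 units/layer, budget 600
epochs; 135 -> 120 units, 700; 180 -> 120 units, 750; batch size 1024;
mean squared error loss. The training sample unit is a sliding window
over the 101-step, 18-channel IMU sequence: with 157 training trials and
the headline window length of 8 steps (40 ms at 200 Hz, stride 1) an epoch
holds ~14,700 windows, so the 1024-sample batch performs real minibatch
updates (with whole-sequence samples the batch size would exceed the
sample count and degrade to one full-batch update per epoch, which
converges far too slowly at these epoch budgets). The window length is a
free parameter of this implementation (the emulated protocol names none);
8 was chosen because the benchmark target is a pointwise function of the
channels, so little temporal context is needed, and per-update cost scales
linearly with window length on one CPU. The split is 70/20/10 *by trial*
to prevent window leakage (train and validation floored, remainder to
test: 225 trials -> 157/45/23). Full-curve predictions average all windows
covering each interval. The returned model is the one from the epoch with
the lowest validation loss (standard early-stopping checkpointing; the
held-out error otherwise fluctuates with the exact stopping epoch).
Optional plateau stopping monitors windowed validation loss and never
triggers before a quarter of the epoch budget; the headline runs use
reduced budgets of 70/80/120 epochs (~1000-1800 minibatch updates), sized
for single-CPU runtime, with the largest budget on the 180-degree model
whose reference RMSE band is the tightest.

The learning-rate default follows the convention of reading the source
protocol's "greater than 0.001" as 0.001; it is configurable.

**Evaluation.** CMC is the between-protocol coefficient of multiple
correlation with P = 2 protocols (predicted vs measured), pooling all
(curve, frame) pairs of the evaluated split; a negative radicand is
clipped to 0 and flagged, identical constant curves are defined as 1 and
flagged. RMSE is reported in min-max-scaled target units. Conventional
CMC bands: 0.95-1 "perfect similarity".

**Benchmark target.** The headline accuracy runs use a low-noise benchmark
mapping: the target curve is a fixed smooth functional of the trial's own
18 filtered IMU channels — channels divided by fixed typical scales
(7 m/s^2 accelerometer, 80 deg/s gyroscope), mixed by fixed weights, and
squashed through tanh into (0.15, 0.85) — plus Gaussian observation noise
(SD 0.01 in scaled units). This gives a known, direction-independent
signal-to-noise level, so the measured CMC/RMSE characterize the
predictor, not an arbitrary target. The pipeline's default target mode
instead predicts the subject's vector-coding variability curve.

## Scaled run sizes

All simulation suites are sized for a single CPU. The headline accuracy
runs use the full 225 trials per direction with the per-direction unit
counts and epoch budgets above and plateau stopping (patience 15 epochs);
in practice they stop well before the budget. The statistical-mapping
simulations use 1,000 permutations with 200 replicates (type-I error) and
20 replicates (effect recovery). Problem sizes used by the acceptance
script are recorded in its output.

## What passing tests show — and what they do not

The synthetic generator reproduces the *structure* the analysis assumes
(smooth periodic kinematics, direction-dependent late-swing variability,
double-peak vGRF, kinematics-coupled IMU channels), not real tissue
artefact, sensor drift, marker occlusion, inter-lab protocol variation, or
true biological coupling between joints. Passing the recovery suites shows
the estimators and tests behave correctly under their assumptions and can
detect effects of the emulated size; it does not certify performance on
real cutting-movement recordings. Known limitations: the coefficient of
correspondence saturates near the noise floor for nearly-static couplings;
the permutation ANOVA assumes complete subjects (no missing directions);
the LSTM training cost scales linearly with window count, so very dense
window strides are slow on one CPU.
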
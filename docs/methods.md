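# Methods

This note documents the generative model, the decoder and its training,
the task and metric semantics, the directional-SNR analysis, and the
numerical and design choices behind them — including what the synthetic
loop does and does not say about real closed-loop BCI use.

## Synthetic population

Real finger iBCIs record spike-band power (SBP) from ~192 electrodes; no
public generative model exists for those signals, so the package defines
one with exactly the structure the downstream theory assumes:

```
x[n] = b + T v[n] + W p(v[n]) + ε[n]
```

- `T` (`n_channels × dof`) — linear tuning gains, drawn i.i.d.
  `N(0, tuning_sd²)`. Units: SBP per ROM-unit/s. SBP units are arbitrary;
  only relative structure matters downstream, so the baseline `b`
  defaults to 1.0 per channel.
- `W` (optional) — gains on pairwise velocity products
  `p(v) = (v_i v_j)_{i<j}`. Interactions are a controlled nonlinearity:
  with them, population dimensionality exceeds the linear count, giving a
  qualitative handle on super-linear dimensionality growth with
  simultaneously moving fingers.
- `ε` — i.i.d. Gaussian noise, per-channel SD `noise_sd`. This is the
  ideal case of the channel-scaling theory (below); real arrays have
  correlated noise and nonstationarity, which this generator deliberately
  omits.

Defaults (`tuning_sd = 1`, `noise_sd = 2` for closed-loop work, 5 for the
scaling experiment, `baseline = 1`) are package choices: no tuning-strength
or noise statistics are published for the recorded arrays, so they are
set to give a per-channel SNR well below 1 — individual channels are
nearly useless, populations are good, which is the regime of interest —
and they remain configurable everywhere.

`analytic_participation_ratio` gives the closed-form effective
dimensionality `(Σλ)²/Σλ²` of `T Σ_v Tᵀ + diag(σ²)`; it is the oracle
against which the sample estimator is tested (they agree within 2% at
10⁶ bins).

## Decoder

Architecture (input `E_N × 3`, three most-recent 50-ms bins):

1. time-feature layer: a `3 × 16` weight matrix shared across channels
   (a length-3 temporal convolution), ReLU;
2. flatten to `E_N·16`, then four fully connected layers of widths
   `(256, 256, 256, dof)` by default — the widths are a package choice
   (they are not published); ReLU after every layer but the last;
3. batch normalization + 50% dropout after each intermediate ReLU;
4. the final linear layer has **no bias**, and the final batchnorm is
   **variance-only**: it never subtracts a mean (train or eval) and has no
   bias parameter. Any persistent output offset must therefore be produced
   by the preceding blocks, where the MSE loss penalizes it.

Training: Kaiming initialization; Adam on MSE. Supervised defaults
(lr 1e-3, 200 epochs, batch 64) are package choices; the ReFIT update is
fixed at 500 iterations, lr 1e-4, weight decay 1e-2. Open-loop labels are
the cued trajectory's instantaneous velocities, standardized per DOF
before the loss, which matches the output contract (zero mean, unit
variance if ideally trained). After fitting, the empirical mean/SD of the
raw outputs over the training set are stored for normalization, and the
per-DOF gain is set to the training-label SD — restoring physical ROM/s —
with a separate global speed scale for manual tuning.

ReFIT relabeling is per-DOF by default: label = |decoded| with the sign of
(target − position), zero when that DOF is inside its target (the
stationary emphasis of the training task motivates the zero; it is
switchable off). A vector mode is provided that instead rotates a
DOF-group's joint velocity onto the target direction, preserving the
group magnitude — relevant for the 2-D thumb; per-axis is the default
because nothing published selects between them. ReFIT labels are
standardized per DOF before the update exactly as in supervised training,
and the output statistics and gains are recomputed afterwards, keeping the
output contract invariant.

Two properties worth noting, both consequences of the optimizer rather
than bugs:

- an update on labels the decoder already produces is *functionally*
  near-stationary (decoded outputs change by ~2% RMS, correlation
  > 0.999) but not parameter-stationary: Adam steps are
  gradient-scale-invariant, so weight decay and residual label mismatch
  still move parameters by several percent;
- the mean-free output contract holds on the distribution the decoder was
  trained on (|mean| ≲ 2% of SD); far off-distribution inputs can produce
  larger means, since only the training objective enforces the contract.

## Tasks and the simulated user

Positions live in `u ∈ [0, 1]` per DOF, neutral 0.5; the screen convention
`s = 2u − 1` is a display transform. One internal frame avoids sign bugs.
Time advances in 50-ms bins; positions integrate decoded velocity and
clamp to [0, 1].

- open-loop trials: minimum-jerk profiles (the standard smooth
  motor-control primitive with zero endpoint velocity) from neutral to
  full flexion/extension in 2 s, 1 s hold; uncued DOF stay at neutral.
- closed-loop 2-D: paired center-out/back trials, target width 20% ROM,
  hold 500 ms, timeout 10 s.
- 4-DOF variants: two (or one) of the three finger groups get new random
  targets per out-trial, the rest hold; a fully random variant has no
  pairing. Random target centers are drawn uniformly in
  `[width/2, 1 − width/2]` so targets always fit inside the range.
- T_TRAIN (decoder bootstrapping): hold 1.5 s, timeout 5 s, unselected
  group frozen at center, end-of-trial snap to center, every other trial
  fully stationary.

Hold semantics: the success counter requires *consecutive* inside bins and
resets on any exit. Entry times are credited at the start of the first
inside bin, so `completion − last_entry = hold` holds exactly, and
`acquisition = time_to_target + orbiting` is additive by construction.

The simulated user forms a unit intent vector toward the targets
(components inside a dead zone — by default the target half-width — are
zeroed) and attempts `intent × user_speed` with optional Gaussian motor
noise. This parametric stand-in closes the loop but is far kinder than a
human: no reaction time, no visual feedback delay, no learning, no
fatigue. Consequently the simulated sessions over-perform real ones, and
passing tests certify algorithmic correctness and trends — not human-level
performance numbers.

## Metrics

- time to target: cue → first all-inside bin; acquisition: cue → start of
  the successful hold (hold excluded); orbiting: their difference.
- path-length efficiency: net displacement / traversed path length in
  joint space — bounded in [0, 1] by the triangle inequality. (A variant
  that divides by the straight-line distance to the target *center* can
  exceed 1 when a trial stops at the target edge, so it is not used.)
- throughput: Fitts bits `Σ_cued log₂(D/W + 1)` per second of acquisition
  time, averaged over successful trials; the index formula is the
  convention of the finger-BCI literature and a Welford variant is
  provided. Back-trials that start on target contribute 0 bits.
- individuation: mean Go-window (200–700 ms) speed of each group under
  each single-group cue, rows normalized by their maximum.
- participation ratio on mean-centered activity; the Go-window restriction
  is configurable by passing the bins of interest.
- normalized cross-correlation: zero-lag inner product without mean
  removal, averaged across DOF; zero-norm traces yield NaN rather than an
  exception.
- mean ± s.e.m. uses sample SD/√n over trials.

## Directional SNR and channel scaling

Per bin, the predicted velocity `v̂` splits against the unit intent `v`
into a signed parallel magnitude `‖v̂_s‖ = v̂·v` and an orthogonal noise
magnitude `‖v̂_n‖ = sin(θ)‖v̂‖`;
`dSNR = mean(‖v̂_s‖)/sqrt(var(‖v̂_n‖) + mean(‖v̂_n‖)²)`. The empirical
pipeline is 6-fold cross-validation with contiguous folds (deterministic);
per fold, PCA with 20 components is fitted on the training folds only and
a linear regression maps the reduced features to intents. The regression
is fitted on the PCA-reduced features (the dimensionality reduction is the
entire point of the PCA step). PCA components are clamped to
`min(20, n_channels, n_training_bins)` so the sweep can reach 5 channels.

Channel sweep: counts from 5 to `E_N` in steps of `E_N/20` (rounded,
deduplicated, the full count always included), 25 random subsets per
count, averaged. The power law `dSNR = B·N_c^m` is fitted by least squares
on log–log axes using the highest 75% of counts; R² is the coefficient of
determination of that linear fit (NaN for a flat curve). Degenerate flags:
zero noise power → `inf`; no valid rows → NaN.

Under linear tuning and i.i.d. Gaussian noise the exponent is ideally 0.5;
the simulated pipeline at full scale (192 channels, 5,000 bins) fits
m ≈ 0.49–0.52 with R² ≈ 0.999 across seeds. Noise *shared* across
channels (e.g. a noisy behavioral intent driving the whole population)
caps the recoverable information and flattens the curve — the mechanism by
which real slopes fall below 0.5; a test exercises exactly this
construction. Note that concentrating the tuning in a few channels does
*not* flatten the curve under random subsampling, because the expected
number of informative channels in a subset grows with subset size.

Bins with zero intent (all DOF inside their targets) are excluded from
dSNR datasets; the Go-window restriction (200–700 ms) removes most of
them already.

## Quadcopter layer

Finger-to-command mapping: `command = gain · (2u − 1) · cap` per DOF, with
gains (0.6, 0.8, 0.4, 0.6), caps ±10 m/s and ±90 deg/s, then clamped. The
gain applies to the normalized displacement before the cap — the printed
full-flexion commands (6 m/s forward, 54 deg/s yaw) pin this ordering.
Sign conventions (flexion → forward, abduction → right, index–middle
flexion → up) are package defaults and fully configurable.

Neutral "gravity": inside 10% of ROM of neutral, a constant
0.05 ROM-units/s (configurable; only "low-amplitude" is specified) is
added toward neutral; config validation enforces
`amplitude × 50 ms < zone width` so gravity alone never crosses neutral in
one bin.

The quadcopter is first-order kinematic: velocity commands integrate
directly (the control semantics are velocity-level; aerodynamics are out
of scope). Yaw integrates first and the body-frame translation is rotated
at the *half-step* yaw — a midpoint rule, second-order accurate, which
keeps 50-ms circular arcs within 2% of the continuous solution where a
first-order rule errs by ~4% at 90 deg/s. Ring crossing intersects each
50-ms segment with the ring plane and tests the hit against the disc
radius. The obstacle course is a parameterized two-ring layout (the
original course geometry is not numerically specified); random rings are
drawn uniformly in a configurable box with random orientation and a 20-s
per-ring timeout.

Gravity is applied in the quadcopter context only (switchable), matching
its purpose of keeping idle fingers still during flight.

## Sessions, configuration, reproducibility

The training protocol is: open-loop supervised training → (for 4-DOF
tasks) closed-loop T_TRAIN blocks with ReFIT updates until the success
gate (default 80%, configurable) → the target task, with a ReFIT update
after every closed-loop block. Decoder versions increase at each update.
Every stochastic component draws its seed from the single session seed,
so sessions, curves and logs are bit-reproducible; trial logs are
JSON-lines (one trial per line, per-bin arrays inlined — desk-scale
sessions are small), configs are YAML with unknown keys rejected, and
arrays (populations, decoders) are portable `.npz` containers with a
version field.

Problem sizes used in the test suite (24–64 channels, 20–50 trials per
block, 64-wide hidden layers, tens of epochs) are chosen so the whole
suite certifies the full pipeline in about a minute of CPU; the
channel-scaling experiment alone runs at the full published scale
(192 channels, 5,000 bins, 25 subsets per count).

## Known limitations

- The simulated user has no reaction time, feedback delay, or learning;
  absolute performance metrics are optimistic and only structural claims
  transfer to real use.
- The generator omits correlated noise, slow drift and unit instability;
  decoder robustness to nonstationarity is representable only as explicit
  retraining on new data.
- The open-loop classification analyses, rendering, physics-engine
  dynamics and any human-data numbers are out of scope.
- dSNR assumes unit-norm intents; blocks where the user is mostly on
  target contribute few bins.
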
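# Methods

`gaitid` implements closed-set person identification from the gait signal of
a body-worn inertial sensor (typically a phone in a trouser pocket): a
preprocessing chain that makes tri-axial streams orientation-invariant, a
fixed-length windowing scheme, a stacked-LSTM classifier, and the evaluation
protocols used to study it.  This note records the model, the defaults and
why they were chosen, the numerical decisions, and what the bundled
synthetic data can and cannot show.

## Orientation-invariant projection

A phone rests in an unknown, arbitrary but (approximately) fixed orientation,
so the raw X/Y/Z axes are not comparable across recordings.  Gravity
dominates the accelerometer's low-frequency content: the per-axis mean over
a centred sliding window of 2m samples estimates the gravity vector in the
sensor frame,

    x̄_m(i), ȳ_m(i), z̄_m(i)  =  mean of samples [i − m, i + m]
    ĝ(i) = (x̄_m, ȳ_m, z̄_m) / ‖(x̄_m, ȳ_m, z̄_m)‖ ,

and the scalar projections

    acc_g(i) = acc(i) · ĝ(i)        (vertical acceleration, m/s²)
    w_g(i)   = ω(i) · ĝ(i)          (vertical rotation, rad/s)

are invariant under any fixed rotation R of the device, because windowed
means rotate covariantly ((R·acc)-means = R·(acc-means)) and dot products
are rotation-invariant.  The package asserts this property to 1e-9 over
random rotations; it is exact up to float rounding, not approximate.
The gyroscope is always projected onto the gravity direction estimated from
the *accelerometer* of the same recording — gyroscope means carry no
gravity information.

Parameters:

* `half_window_m` — default 150 samples, i.e. a 2m = 300-sample ≈ 6 s
  estimation window at the nominal 50 Hz.  Long enough that the gait
  oscillation (≥ 1.4 Hz cadence) averages out of the gravity estimate,
  short enough to track slow re-orientations of the device.  At the series
  edges the window shrinks (truncated means) so the output keeps the input
  length.
* `trim_samples` — default 150 per end (3 s).  The first and last moments
  of a recording contain starting/stopping transients with near-zero
  information; they are cut after projection.  The default also removes
  exactly the edge samples whose gravity windows were truncated.
* The projection is signed; no absolute value is taken.
* A windowed mean of near-zero norm (< 1e-12) aborts with an error naming
  the sample — it indicates a dead or stationary sensor, not walking data.

## Windowing and splitting

Projected series are cut into windows of T = 150 samples (3 s at 50 Hz,
0.02 s per sample) with stride ⌊T/2⌋ (half-segment overlap) by default;
stride = T gives overlap-free packaging.  Trailing partial windows are
discarded: window counts follow ⌊(L − T)/stride⌋ + 1.  With both
accelerometer and gyroscope channels, windows are T × 2 tensors whose
columns are (acc_g, w_g) at the same instants.

Labels are integer subject indices, one-hot encoded for the categorical
cross-entropy loss.  The train/test split is a seeded uniform random
permutation with test size round(n · 0.3) (round-half-even); the same seed
always reproduces the same partition.  Because overlapping windows share
samples, an i.i.d. split leaks some test information into training;
`split_train_test_blocked` is provided as a contiguous per-subject
alternative for leakage-sensitive analyses.  The default remains the random
partition, which is what the reported protocols use.

## The identifier

Architecture (input T × F, F ∈ {1, 2}):

1. LSTM with u₁ memory units, emitting its hidden state at every timestep;
2. LSTM with u₂ memory units, emitting only its final state — forced by the
   published parameter counts, since a per-timestep dense head would scale
   the dense parameters with T;
3. fully connected ReLU layers (widths per preset);
4. softmax output with one neuron per subject.

Presets (all with T = 150, F = 1, K = 15):

| preset | LSTM units | dense | trainable params |
|--------|-----------|--------|------------------|
| ID1 | 50, 100 | 100, 90 | 91,355 |
| ID2 | 50, 100 | 100, 60 | 87,875 |
| ID3 | 50, 100 | 100, 90, 60 | 96,365 |
| ID4 | 50, 100 | 100, 60, 30 | 89,255 |
| ID5 | 100, 100 | 100, 90 | 141,755 |

`count_trainable_params` computes the counts analytically — LSTM:
4·(h·(d+h) + h); dense: d·h + h — and the test suite checks that the built
models hold exactly these tallies.

Training: Adam (step size 1e-3, β₁ 0.9, β₂ 0.999 — conventional defaults),
categorical cross-entropy, batch size 32, default 75 epochs (100 in the
window-size sweep preset).  A seeded 5 % validation split is carved from the
training windows before fitting and never trained on.  Weight
initialisation: Glorot-uniform kernels with fans taken from the full
(d, 4h) kernel shape, row-orthonormal recurrent kernels, zero biases with
forget-gate bias 1.  All randomness flows from a single integer seed, and
the implementation is plain numpy in float32 (float64 available via
`dtype`), so training histories are bit-reproducible on a platform.

### Input conditioning

Vertical acceleration oscillates about standard gravity, so the raw windows
have a constant ≈ +9.81 m/s² offset.  Fed directly into an LSTM, that
offset saturates the gate nonlinearities at initialisation and stalls
training: in our measurements the identical cohort converges within ~8
epochs when the offset is absent but needs 50+ epochs with it, for every
mainstream initialisation convention we tried.  The classifier therefore
subtracts the physics constant g = 9.81 m/s² from vertical-acceleration
input channels (and 0 from zero-mean channels such as vertical rotation)
before the recurrence.  This is an exact reparameterisation of the first
layer's bias initialisation (z = (x − s)W + b ≡ xW + (b − sW)), uses no
data statistics, and leaves the window tensors themselves untouched — there
is no per-window normalisation or standardisation anywhere in the pipeline.

## Evaluation protocols

* `seeded_repeats` — for each split seed in a group, repeatedly re-split /
  re-train / re-test; reports per-run accuracies, their mean and the
  *population* variance within the group.  By default each repeat draws its
  own training seed ("different executions"); with `vary_training_seed=False`
  repeats are bit-identical and the variance is exactly 0.
* `sensor_ablation` — accelerometer-only, gyroscope-only and fused (F = 2)
  models trained and scored on the identical split indices.
* `window_size_sweep` — for each window length T, re-window (stride ⌊T/2⌋),
  re-split with the same seed (re-windowing changes n, so the partition must
  be redrawn), rebuild the architecture with window_len = T, retrain, and
  report n_train / n_test / accuracy and the window duration T/fs.

Accuracies are kept in [0, 1] internally and formatted as percentages only
for display.  All tables are pandas DataFrames and round-trip CSV
losslessly.

## Synthetic gait generator

The generator is a signal-level surrogate, not a biomechanical model: its
purpose is to carry subject-discriminative quasi-periodic structure through
the exact preprocessing above.  Per subject, body-frame vertical
acceleration is

    a_z(t) = g + Σ_{k=1..3} A_k sin(2π k f t + φ_k) + ε,   ε ~ N(0, σ²)

with cadence f ∈ [1.4, 2.6] Hz, fundamental amplitude A₁ ∈ [1, 3] m/s²
with geometric decay for the harmonics, plus smaller independent horizontal
components; the gyroscope oscillates about zero analogously.  Both streams
are rotated into the sensor frame by a random proper rotation.  Noise is
drawn in the body frame *before* rotation, so orientation-invariance holds
to float rounding on simulated data, which makes it testable as an exact
property.  Defaults emulate the study conditions: ~10 min of walking at
50 Hz (30,000 samples) per subject.

Cohort "easy" mode spaces cadences ≥ 0.15 Hz apart with σ ∈ [0.05, 0.15]
m/s²; "hard" draws cadences freely (overlap allowed) with σ ∈ [0.3, 0.8].
For cohorts too large to honour the 0.15 Hz gap inside the cadence range
(> 9 subjects), easy mode falls back to maximal even spacing.

What the generator does **not** emulate: step-to-step timing variability,
asymmetry between left and right steps, terrain or speed changes, sensor
drift and clock jitter, soft-tissue artefacts, or realistic inter-subject
amplitude correlations.  Synthetic separability is therefore optimistic:
passing tests show the pipeline, the optimisation and the protocols work
end to end, not that real-world accuracy will match the published numbers,
which require the original 15-subject walking corpus.

## Problem sizes used in tests and the acceptance script

The bundled checks run the full pipeline at reduced scale, chosen so each
protocol exercises every code path with comfortably separable data: the
end-to-end identification check uses 8 easy subjects × 120 s at 50 Hz
(600 windows), ID1, 25 epochs, batch 32, median of 3 runs; the sweep
compares 0.24 s against 3 s windows on the same corpus; the ablation uses
5 subjects × 90 s at 25 epochs.  These sizes are the package's own test
conditions, not recommendations for real studies, where the published
protocol (75–100 epochs, ~10 min of walking per subject) applies.

## Known limitations

* Closed-set identification only: no verification mode, no ROC/EER metrics,
  no open-set rejection.
* No attitude filtering (Kalman/complementary) or magnetometer fusion; the
  gravity estimate is the windowed mean only, which assumes the device
  orientation is approximately constant within the estimation window.
* The i.i.d. split of overlapping windows (the studied protocol) gives
  optimistic accuracy relative to the blocked split.
* Timestamp gaps larger than 3 nominal periods are logged, never repaired;
  resampling is linear interpolation only.
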
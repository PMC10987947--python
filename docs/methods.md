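# Methods

`emgkin` estimates continuous finger-joint kinematics from surface
electromyography (sEMG) and studies how such a regressor transfers
across subjects. This note documents the models, the signal pipeline,
the synthetic cohort generator, and the numerical choices, so that the
results the package computes can be interpreted — and their limits
understood — without reading the source.

## Signal pipeline

Raw recordings pair a 12-channel sEMG signal (2 kHz) with data-glove
joint angles (10 joints, degrees, 20 Hz). Features are the RMS
amplitude envelope over a sliding window (default 100 ms, step 50 ms;
windows are 0-based half-open sample intervals). Labels are obtained by
linear interpolation of the glove channels, sampled at each window's
centre timestamp, so features and labels align one-to-one.

Two normalizations are supported, both fitted on the training split
only and frozen for test and new-subject data:

* **μ-law companding** (default). Each channel's RMS is divided by its
  training-set maximum (clipped to [0, 1] at test time) and passed
  through F(x) = sign(x)·ln(1 + μ|x|)/ln(1 + μ) with μ = 2²⁰. The map
  is odd, strictly increasing, fixes 0 and ±1, and strongly expands
  small amplitudes — where most informative sEMG energy sits — while
  compressing between-subject gain differences.
* **Z-score** per channel, as the comparison condition.

Each movement contributes six trials; four are randomly assigned to
training and two to testing, with one partition shared by all of a
subject's movements (seeded, reproducible).

## Regressor families

All five families implement the same contract: a normalized feature
sequence `[batch, T, 12]` maps to angle estimates `[batch, T, 10]`, and
every family ends in the same tail — a penultimate fully-connected
layer with Mish activation producing a per-window feature vector
(width `d_feat`), then a linear head. The shared tail makes the
penultimate-feature handle (used by the adversarial calibration), the
fine-tuning freeze set, and the evaluation code family-agnostic.

* **RoFormer** (the primary model): a 1-D convolution (kernel 3,
  stride 1, same padding) lifts the 12 channels to `d_model`, followed
  by a pre-norm residual transformer encoder — per layer,
  `Z' = MSA(LN(Z)) + Z`, `Z_out = MLP(LN(Z')) + Z'` with a
  linear→Mish→linear MLP. Attention is bidirectional (no causal mask).
  **Rotary position embedding** acts on the queries and keys of every
  attention layer: coordinate pair (2i, 2i+1) at position m is rotated
  by m·θᵢ, θᵢ = base^(−2i/d), base 10⁴. Rotations are orthogonal, so
  Q/K row norms are preserved and attention logits depend only on
  relative position; values carry no positional information. Default
  geometry: 2 layers, 5 heads.
* **Absolute-PE transformer**: the identical encoder with sinusoidal or
  learnable embeddings added once at the input instead of RoPE — the
  comparison surface for position-embedding ablations (parameter shapes
  are identical apart from the embedding table).
* **LSTM**: stacked LSTM layers (full-scale: 5 layers, hidden 32).
* **TCN**: dilated causal convolutions with residual blocks, dilation
  doubling per layer, channels (32, 64, 64, 32, 10) at full scale. The
  published channel list names four values for five layers; the middle
  value is duplicated and the list is exposed in the spec.
* **CNN-attention**: three parallel same-padded convolutions (kernels
  3/5/7), concatenated, average-pooled (width 2), passed through three
  stacked attention modules of three heads each, then nearest-neighbour
  upsampled back to the input length so the family honours the shared
  sequence-preserving contract.

### Training

Adam on mean-squared error over all joints and windows, learning rate
halved at a scheduled epoch. Labels are standardized per joint inside
the training loop (statistics stored with the model; predictions are
returned in degrees): Adam's per-weight step is O(lr), so regressing
raw degree-scale targets would need impractically many updates at any
reasonable rate. Training sequences are non-overlapping chunks of each
trial (default 150 windows at full scale); prediction on a long series
chunks it at the trained context length, since attention optimized on
short contexts does not transfer to much longer ones.

Two profiles exist. The **full-scale profile** follows the published
schedule: batch 64, 400 epochs, lr 1e-4 (cross-subject) / 3e-4
(subject-specific) halved at epoch 200, calibration at lr 1e-3 for
50 epochs. The **desk profile** — used by the test-suite and the
reproduction script — compresses this to tens of epochs on tiny nets
(d_model 40, 25-window contexts, batch 8, lr 1e-3 halved mid-run,
calibration lr 1e-4 for 50 epochs). The lower desk calibration rate is
deliberate: with only hundreds of target windows, 1e-3 Adam steps
destroy the pretrained solution (measured train CC 0.65 vs 0.82).

## Transfer calibration

A cross-subject model is trained on the pooled training trials of the
source subjects, then adapted to a held-out subject:

* **noTL**: the pooled model is evaluated on the new subject directly.
* **FT**: every parameter except the final head is frozen; the head is
  fit to the new subject's four training trials per movement (MSE).
* **ATL** (adversarial transfer learning): three players. The frozen
  source network and a trainable copy initialized from it produce
  per-window penultimate features F_s (source batches) and F_t (target
  batches). A domain discriminator — MLP, two hidden layers of 64,
  Mish, sigmoid output clamped to [1e-7, 1−1e-7] — estimates
  P(feature is from the source domain). Per batch, the discriminator
  takes one Adam step on
  `L_DD = mean(−log DD(F_s) − log(1 − DD(F_t)))`, then the target
  network takes one step on `L_mapping + L_subject` where
  `L_mapping = mean(−log DD(F_t))` rewards source-like target features
  and `L_subject = w · mean_batch Σ_joints (ŷ − y)²` (w = 1 by
  default; the value is not fixed by any external constraint and is
  exposed in the calibration config) keeps the network faithful to the
  new subject's labels. The two updates are alternating GAN-style
  steps with separate optimizers — matching the separately-written
  discriminator and generator objectives — rather than a
  gradient-reversal layer. Expectations are per-batch means. The total
  `L_total = L_DD + L_mapping + L_subject` is logged per epoch together
  with discriminator accuracy; the source network's weight digest is
  checked bit-identical before and after calibration.

Because `L_subject` is part of the objective, calibration on the target
trials can improve accuracy even when there is no domain shift; the
null-shift control therefore checks that calibration does not *hurt*
and that the discriminator ends near chance (accuracy 0.4–0.6), rather
than expecting no change.

## Metrics

Per joint over the pooled test windows of a (subject, movement):
Pearson CC; NRMSE = RMSE divided by the observed range of the measured
angle (the scaling that guarantees [0, 1] for in-range predictors);
R² = 1 − SS_res/SS_tot, reported as-is when negative since clipping
would hide failure modes. Joint-averaged values and across-subject
mean ± SD are derived from these. Both aggregation orders (pool windows
across movements vs. average per-movement scores) are available because
the convention differs between studies.

## Synthetic cohorts

No public recording ships with the package, so every study runs on a
seeded generator that emulates the statistical structure the method
assumes:

1. **Kinematics**: each movement is a grasp — per-joint sigmoidal
   rest→target→rest trajectories (targets in 25–90°, rest 5°) with
   per-joint transition times staggered within the movement and small
   trial-level timing jitter. Staggered timing matters: it decorrelates
   the ten joints, so decoding requires resolving individual muscles
   rather than one overall activation level.
2. **Activation**: six muscles read out normalized angles and absolute
   velocities through a sparse non-negative synergy matrix (shared by
   the cohort); every joint is guaranteed at least one solid readout
   weight, since an unactuated joint would be unrecoverable from any
   electrode. A per-subject exponent near 1 distorts the
   activation-envelope relation.
3. **sEMG**: each channel is a band-limited (20–450 Hz Butterworth at
   2 kHz) unit-RMS noise carrier, amplitude-modulated by a per-subject
   non-negative mixing of the muscle activations, scaled by a
   per-channel gain, plus additive sensor noise.

Subjects differ by log-normal perturbations of mixing and gain and by
their exponent — amplitude idiosyncrasies of the kind that make
cross-subject sEMG transfer hard. A held-out subject is perturbed from
the cohort mean by `shift_magnitude`; the perturbation direction is
fixed per seed and scales linearly, so shift levels are comparable, and
zero shift reproduces the cohort mean exactly.

What the generator does **not** emulate: motor-unit physiology,
electrode displacement, fatigue, crosstalk structure, label noise from
glove calibration, and the full repertoire/variability of real grasps.
Passing studies demonstrate that the implementation behaves as the
method intends under its own assumptions — not that the published
real-data accuracy figures would be reproduced on Ninapro DB2, which
requires the external download and full-scale training.

## Desk-scale study conditions

The reproduction script (`scripts/acceptance.py`) and the heavier tests
run three studies, all with 5-second trials, 100 ms/50 ms windows,
μ-law normalization, and the desk profile:

* **Recoverability**: one subject, 3 movements; median held-out-trial
  CC over 5 seeds (expected ≥ 0.8 — the generator is neither trivial
  nor impossible).
* **Shift degradation**: 3 source subjects, 2 movements; one pooled
  model per seed evaluated on held-out subjects at shifts 0/3/6 (the
  source pool is independent of the shift, so one model serves all
  levels). Median noTL CC decreases monotonically.
* **Transfer ladder**: at shift 6, noTL ≤ FT ≤ ATL with a median
  ATL−noTL gain ≥ 0.05, the source digest unchanged, and discriminator
  accuracy near chance under the null-shift control.

## Numerical choices

LayerNorm ε = 1e-5; softmax with max-subtraction; sigmoid via tanh;
probability clamp 1e-7; Adam (0.9, 0.999, ε 1e-8); μ-law precondition
|x| ≤ 1 enforced with an explicit error naming the offending maximum;
zero-variance channels and constant reference series are errors, not
silent NaNs. All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`, and generated cohorts are bit-reproducible
from their manifest.

## Known limitations

Training runs on a single CPU via `autograd`; there is no GPU path, so
full-scale (400-epoch, 10-subject) replication is slow though exact in
specification. The LSTM family pays a large constant factor for its
per-timestep Python loop. The Ninapro DB2 reader maps files into the
package's recording type but the movement/joint/subject selections of
any particular published experiment are not knowable from the
literature and must be chosen by the user.
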
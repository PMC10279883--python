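# Methods

## Model

One 30-s epoch of single-channel EEG, sampled at fs Hz, is a vector of
fs·30 samples (3,000 at 100 Hz, 6,000 at 200 Hz). The representation
extractor is:

1. **Dual-filter CNN.** Two convolutional branches act on the raw epoch.
   The first layer of one branch uses a short kernel (default fs/2
   samples) to capture high-frequency content; the other uses a long
   kernel (default 4·fs) for slow rhythms. Subsequent layers use a common
   small kernel. Both branches share the same stride and max-pool
   schedule with 'same'-style padding, so their output shapes are equal
   by construction and the branch outputs are merged by **elementwise
   sum** — this follows the model's feature equation as written, even
   though the structurally similar DeepSleepNet concatenates; a
   `merge: concat` option is provided. Activation is ReLU throughout
   (the activation is not named in the model description; ReLU is used
   in its other components).
2. **GRU.** The (B, T, F) feature sequence is consumed by a GRU with zero
   initial hidden state; the final hidden state is the representation
   c_t. The representation width equals the GRU hidden size; the default
   configuration uses 960 so that the projection, prediction and
   classifier widths ("960 units") are consistent. How the 960-d
   representation arises is otherwise unspecified; final-hidden-state is
   the simplest consistent reading.

The CNN depth/width is unspecified in the method description; defaults
(3 conv layers, 32 channels, strides 6/1/1, pools 4/4/2) follow the
DeepSleepNet-style design it cites. Every knob is in `EncoderConfig`.
A `tiny` preset (2 conv layers, 8 channels, 32-d GRU) is the desk-scale
configuration used by the tests and benchmark; a `micro` variant
(300-sample epochs, 8-d GRU) appears in the test suite only.

## Training scheme

Online branch: f_θ → g_θ (Linear→BatchNorm→ReLU→Linear, all widths = d)
→ p_θ (two affine layers; as specified there is no intermediate
nonlinearity, so the head is effectively a single affine map — an
optional `predictor_activation='relu'` is provided). Target branch:
f_ε → g_ε, structurally identical to the online encoder+projection and
initialized as an exact copy of it (initialization is unstated; copying
is the standard choice for online/target schemes).

Per step, with positive pair (x, x′):

* L = ½·[ ℓ(p_θ(g_θ(f_θ(x))), g_ε(f_ε(x′))) + ℓ(p_θ(g_θ(f_θ(x′))), g_ε(f_ε(x))) ],
  where ℓ(a, b) = ‖ā − b̄‖² on row-wise L2-normalized vectors
  (= 2 − 2·cos), batch-averaged. Rows with norm < 1e-12 are guarded and
  warned about.
* Adam (lr 1e-4) updates θ only; the target branch is run without graph
  construction, so ∂L/∂ε ≡ 0 structurally.
* EMA: ε ← τ·ε + (1 − τ)·θ with τ = 0.1 by default — taken literally
  from the update rule and stated decay rate. Note that τ = 0.1 makes
  the target track the online network within a few steps; BYOL-style
  methods typically use τ ≥ 0.99. With the predictor asymmetry and the
  stop-gradient this still avoids collapse (the training log records a
  per-step representation-spread monitor), but the knob is exposed and
  the discrepancy deliberately not "fixed".

Both branches run batch normalization on batch statistics within a step
(no running averages; the special-casing is unspecified, and the encoder
itself — the only part used downstream — contains no BN). Batches are
drawn by shuffling the pool of pairs each training epoch; a trailing
partial batch is dropped so every step sees a full batch (mixup needs a
partner and BN wants more than one row). Anchors are the raw epochs;
views their augmented copies; for time shift the pair is (epoch t,
epoch t+1) with no same-stage filtering — ignoring stage transitions is
part of the method's continuity assumption.

Defaults follow the stated experimental settings: batch 32, 200 training
epochs, Adam lr 1e-4, seed 2022, τ = 0.1, mixup γ = 0.4, mask counts
100/1,000, 10-fold CV, sequence GRU of 64 units over windows of 5,
classifier hidden width 64, probe epochs 200.

## Augmentation blocks

* `time_shift` — pairs (t, t+1); the final epoch is dropped (no
  wraparound).
* `mixup` — (1−γ)xᵢ + γx_k, partner k uniform over the batch *excluding
  i* (self-selection would give an identical pair).
* `gaussian` — x + g, g ~ N(0, σ²) i.i.d. per sample point, superimposed
  directly (not mixed by ratio). σ defaults to 0.1 on normalized
  (unit-variance) input; the noise scale is described only as "small".
* `random_mask` — exactly n distinct sample points per row set to 0
  (a "patch" is one sample point, per the N-samples = N-patches reading);
  length unchanged.
* `scaling` — pointwise product with ρ ~ N(1, σ²) per sample point
  (default σ = 0.1), reading "point by point" literally; a per-epoch
  single-ρ mode is available since the text admits both readings.
* `none` — identity, for ablations.

Augmentation operates on normalized signals.

## Normalization

Zero-mean/unit-variance standardization (x − μ)/σ. The scope of μ, σ is
not stated; the default is **per epoch** (the common convention for 30-s
sleep epochs, making every network input comparable), with
`per_recording` as an option. Population standard deviation is used so
the operation is exactly idempotent. A constant unit (σ = 0) is guarded
with ε = 1e-8 and a warning rather than an exception, since synthetic
fixtures may legitimately contain silent epochs.

## Evaluation protocol

The online encoder is frozen; representations are extracted in inference
mode. The probe is, optionally, a 64-unit GRU over the causal window of 5
representations ending at the scored epoch (edges left-padded by
repeating the recording's first epoch; windows never cross recording
boundaries; recordings shorter than the window are skipped with a
warning), followed by a two-affine-layer classifier with ReLU between
and 5 outputs, trained with cross-entropy and Adam. The stated classifier
widths ("960 and 64 units") are incoherent when the 64-unit sequence GRU
precedes it, so the classifier is implemented as hidden width 64 on
whatever input precedes it (960-d representations without the sequence
net, the 64-d GRU output with it). The final configured probe epoch is
the fold's result — no early stopping or best-epoch selection.

Cross-validation partitions **subjects** by default: the splitting unit
of the original evaluations is unreported and subject-wise splitting is
the defensible default (epoch-wise splitting, which can leak subject
identity, is available for parity). Summary metrics are computed on the
pooled confusion matrix — pooling is what reproduces the published
summary numbers from the published per-dataset matrices exactly — and
per-fold metrics are also reported. κ is computed from the pooled matrix;
classes with an empty row or column score 0 with a warning.

## Synthetic data

The generator emulates two properties the method depends on: (1) stage
continuity — a first-order Markov hypnogram that stays with probability
p_stay = 0.9 and otherwise jumps uniformly to one of the other four
stages (the uniform law is stationary for this chain), and (2)
stage-dependent signal character — each epoch is a sum of stage-template
sinusoids with a fresh random phase plus white noise (σ = 0.5), so
adjacent same-stage epochs are spectrally similar but not identical
waveforms. Default templates: W 10 Hz, N1 6 Hz, N2 13 Hz, N3 1 Hz at
2.5× amplitude, REM 6 + 2.5 Hz.

What it does **not** emulate: K-complexes and spindle morphology, 1/f
background, artifacts, realistic stage-transition structure (e.g. W↔N1
preference), or fragmented sleep. Passing tests on this data show the
pipeline is correct and that the time-shift objective extracts
stage-discriminative structure when the continuity assumption holds;
they say nothing about accuracy on real PSG.

Subjects derive seeds as base + 1000·index so their hypnogram and signal
streams never collide.

## Benchmark problem sizes

The representation-quality benchmark uses 10 subjects × 200 epochs at
100 Hz, the tiny encoder preset, 7 train / 3 held-out subjects,
5 pretraining passes over the pair pool (≈ 215 steps at batch 32) and a
50-epoch linear probe without the sequence net. These sizes keep a full
three-condition comparison (time shift / identity / random encoder) to
roughly half a minute on one CPU while leaving the ordering of the
conditions stable across seeds.

## Numerical choices

* float64 end to end; all randomness through `numpy.random.Generator`
  seeded from the run seed, so runs are bitwise reproducible
  single-threaded.
* Glorot-uniform init for affine layers, He-normal for convolutions,
  uniform ±1/√h for GRU matrices; biases zero.
* Max pooling is non-overlapping and drops a trailing remainder;
  convolutions pad to ceil(L/stride) output length.
* Loss norm guard 1e-12; normalization σ-guard 1e-8; BN ε 1e-5;
  Adam (β₁, β₂, ε) = (0.9, 0.999, 1e-8).
* Continuous signals are segmented into 30-s epochs with any trailing
  partial epoch dropped and logged.

## Known limitations

* The full-scale 960-d configuration trains in pure numpy; it is
  CPU-practical only for modest datasets. The tiny preset is the
  intended desk-scale configuration.
* EDF reading extracts a single named channel; EDF writing, multi-channel
  fusion, band-pass filtering and artifact rejection are out of scope.
* The predictor as specified is affine; whether that weakens the
  anti-collapse asymmetry on real data is untested here.
* τ = 0.1 is faithful to the stated decay rate but unusual for
  online/target methods; users wanting BYOL-like dynamics should raise it.
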
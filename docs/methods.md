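# Methods

## Problem and model

`afnet` detects atrial fibrillation (AF) in fixed-length single-lead ECG
segments. AF has two robust electrophysiological signatures: highly
irregular RR intervals (the timing between R peaks loses its sinus
regularity) and the absence of organized P waves, often replaced by a
low-amplitude 4–9 Hz fibrillatory oscillation. The model is built so that
each signature has a dedicated reader:

1. **1-D DenseNet backbone** — local morphology. A stem convolution
   (kernel 7, stride 2, `k0 = 24` output maps) feeds three dense blocks of
   eight dense layers each. A dense layer computes
   BN → ReLU → 1×1 conv (bottleneck, width `4k`) → BN → ReLU → conv
   (kernel 3, stride 1, same-padding) producing `k = 12` new feature maps
   that are concatenated onto its input, so the channel count entering
   layer `l` of a block whose input had `c0` channels is exactly
   `c0 + k(l−1)`. Every block is followed by a transition layer
   (BN → ReLU → 1×1 conv keeping `floor(0.5·c)` channels → non-overlapping
   1×2 average pooling). For a 5000-sample segment the time axis follows
   the floor chain 5000 → 2500 → 1250 → 625 → 312 and the channel count
   ends at 87.
2. **Bidirectional LSTM** — global rhythm. The backbone output is read
   time-major by a forward and a backward LSTM of 64 units each; their
   per-step states are concatenated into a 128-dimensional feature vector.
3. **Attention pooling** — a learned global query `Q` is scored against
   every step vector `K_i` with one of three similarity functions:
   multiplicative `Qᵀ W_α K_i`, cascade `W_α [Q : K_i]`, or perceptron
   `v_αᵀ tanh(W_α Q + U_α K_i)` (the default). Scores are
   softmax-normalized (max-subtracted) and the weighted sum of step
   vectors is the pooled context.
4. **Classifier** — the context is concatenated with the global average
   of the backbone channels (fusing the recurrent summary with a direct
   morphology summary) and a single logistic unit outputs
   `ŷ = σ(w·feat + b) ∈ (0,1)`, the AF probability.

Training minimizes per-sample binary cross entropy
`L = −[y log ŷ + (1−y) log(1−ŷ)]` (equivalently `−log P(y|x)` with
`P(y|x) = ŷ^y (1−ŷ)^{1−y}`), averaged over minibatches, with SGD
(momentum 0.9, batch 64). The learning rate starts at 0.1 and is
multiplied by 0.1 when training reaches half and again at three-quarters
of the epoch budget (milestones at `floor(E/2)` and `floor(3E/4)`).
Data are shuffled once by seed and split 6:2:2 into
train/validation/test with the floor/floor/remainder rule (6877 records
give 4126/1375/1376; no standard rounding reproduces other published
partitions of that size, so the rule is declared rather than imitated).
A stratified variant that preserves the class ratio per split is
available but off by default.

### Design choices where the design was open

* **128 total vs per direction.** The per-step bidirectional feature
  length is fixed at 128 (64 per direction). The alternative reading
  (128 per direction, 256 total) was rejected: the pooled "global feature
  vector of each local focus" is the concatenated vector, and 128 is its
  length.
* **Attention wiring.** The query is a learned free vector rather than a
  function of the final recurrent state; all three scoring functions are
  implemented and selectable, with the perceptron form as default since
  it is the only one with dedicated `U_α`/`v_α` parameters.
* **Fusion topology.** Attention context ‖ backbone global-average →
  linear unit. This realizes CNN-local + RNN-global feature fusion with
  one testable topology.
* **Backbone constants not otherwise fixed**: stem `k0 = 2k = 24`,
  kernel 7, stride 2; dense conv kernel 3; bottleneck width `4k`;
  `floor()` for both compressed channels and pooled length; a transition
  after every block, including the last.
* **Denoising placement.** Filtering is a preprocessing stage outside the
  trainable graph, not a layer inside it.
* **Single-logit logistic output** rather than a two-way softmax: the
  loss is written in terms of a scalar `ŷ`.
* **Epoch/batch disambiguation**: the operative schedule is 100 epochs at
  batch 64 (defaults; the desk-scale study below uses 20 epochs).

## Implementation notes

The network layers (convolution, batch normalization, LSTM, attention,
the optimizer) are implemented directly on numpy arrays with explicit
forward/backward passes; every backward pass is pinned by
finite-difference gradient checks in the test suite (float64, relative
tolerance ~1e-7). Convolutions are evaluated as one channel-mixing
matmul per kernel tap with shifted accumulation (no im2col copies);
batch-norm statistics use the one-pass `E[x²] − E[x]²` form with the
variance clipped at zero against cancellation (eps 1e-5 guards constant
channels); the two LSTM directions share a fused time loop. Activations
are float32; gradient-check paths run in float64. Predictions are
clamped to `[1e-12, 1 − 1e-12]` before the log, so the loss is finite for
any input; a non-finite training loss aborts with a diagnostic rather
than propagating NaNs.

WFDB I/O writes/reads the minimal single-signal format-16 dialect
(.hea/.dat, gain 200 adu/mV recorded in the header, label carried as a
`#` comment); readers also accept the `ECG.data` and `val` .mat payload
conventions of the public challenge datasets, and a plain CSV dialect
(`fs=...,lead=...,label=...` header, one sample per line).

## Synthetic data generator

The generator emulates exactly the structure the detector must learn:

| feature | NSR | AF |
|---|---|---|
| RR intervals | truncated normal, mean 0.8 s, sd 0.03 s, floor 0.3 s | i.i.d. gamma, mean 0.7 s, CV 0.25 |
| P wave | Gaussian bump, 0.15 mV at −130 ms | absent |
| baseline | clean | 6 Hz, 0.05 mV fibrillatory sinusoid |

Beats are sums of five Gaussian bumps (P, Q, R, S, T with fixed default
amplitudes/offsets/widths in mV and s); records default to 10 s at
500 Hz, matching common challenge recording conventions. Three noise
processes are added: a 0.3 Hz baseline-wander sinusoid (0.10 mV, random
phase; deliberately below the 0.5 Hz high-pass edge so the denoising
test is meaningful), a 50 Hz powerline sinusoid (0.05 mV), and white
Gaussian EMG noise (sd 0.03 mV). Class imbalance defaults to
`af_fraction = 1/6` (≈1:5 AF:non-AF). A four-class mode adds OTHER
(rate-shifted, amplitude-jittered sinus rhythm) and NOISE (no cardiac
activity) records for challenge-style scoring. Every record is a pure
function of `(config, seed)` via independent spawned substreams.

What the generator does **not** emulate: inter-patient morphology
variation, electrode motion artifacts, paroxysmal (intermittent) AF
inside one record, ectopic beats, or any rhythm class beyond the four
above. Passing tests on synthetic data therefore demonstrate that the
pipeline is implemented correctly and that the architecture can learn
the canonical AF signatures — not clinical-grade performance on real
ECG.

## Preprocessing

Default denoising is a zero-phase (forward–backward) order-4 Butterworth
band-pass, 0.5–40 Hz: the drift band and mains interference are removed
while QRS energy passes. Zero-phase application preserves wave latencies
(the timing cues the recurrent stage uses) and squares the magnitude
response, so effective attenuation is twice the designed single-pass
value in dB. Records are then center-truncated or symmetrically
zero-padded to `target_len` (default 5000) and z-scored; constant
segments map to all-zeros instead of dividing by zero.

## Metrics

Binary metrics with AF positive: `ACC = (TN+TP)/(TN+TP+FN+FP)`,
`Sens = TP/(TP+FN)`, `Spec = TN/(TN+FP)`. A ratio whose denominator is
empty is reported as absent (`None`), not zero. Challenge-style scoring
computes one-vs-rest confusions per class from a single multi-class
prediction, `F1_c = 2TP/(2TP+FP+FN)` (0 when the denominator is 0), and
the overall score `F1 = (F1_N + F1_A + F1_O)/3`; noise records are
scored (their misclassification erodes the other classes' F1) but the
noise class's own F1 never enters the mean. The k-fold harness assigns
seeded folds, trains a fresh model per fold with a 3:1 inner
train/validation cut, and pools the element-wise sum of fold confusions.

## Desk-scale reference study

`afnet.experiments.run_scaled_study` is the package's end-to-end
evidence at a size one CPU handles in minutes: 400 synthetic records at
defaults (1:5 imbalance), default preprocessing, a reduced backbone of
2 dense blocks × 4 layers with the standard recurrent head, trained for
20 epochs (batch 64, the standard LR schedule scaled to the 20-epoch
budget). Validation accuracy reaches ≥ 0.90 (typically 1.00 — the
synthetic classes are cleanly separable, which is by construction), and
an RR-irregularity threshold baseline on the same records confirms
separability ≥ 0.90 independently of the network. These problem sizes
are the package's declared reference configuration for tests and the
acceptance script.

## Known limitations

* Pure-numpy training is single-threaded and memory-bandwidth-bound;
  the default 3-block model on thousands of records is hours of CPU, so
  large-scale results should be reproduced with a GPU framework.
* Batch-norm running statistics assume minibatches of more than a few
  records; evaluation uses the running estimates, so very short training
  runs on tiny batches can leave them poorly calibrated.
* The logistic output is a probability only in the trained-model sense;
  no calibration step is applied.
* The WFDB reader handles the single-signal format-16 dialect this
  package writes (plus first-channel extraction from interleaved files),
  not the full WFDB specification.
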
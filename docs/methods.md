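# Methods

## The model

`sensornet` classifies multi-channel fixed-rate sensor windows (IMU, EEG and
similar wearable signals) from their time-frequency content. A raw window
`X ∈ R^{C×L}` — C sensor channels, L samples — is converted channel by channel
into a stack of log-magnitude spectrograms `S ∈ R^{C×H×W}` and fed to a trunk
of three *attention iterations*, followed by a head-importance gate and a
two-layer softmax classifier.

Each iteration:

1. **Dense layer.** 1×1 convolutions over the head axis project the input
   into query, key and value head tensors `Q, K, V ∈ R^{C×M×H×W}`. At the
   first iteration the single input head is expanded by a double-layer block
   (M scalar filters, then M groups of 1×1×M filters); later iterations use a
   single 1×1×M mixing convolution per projection. All of these share their
   weights across the channel axis C, which is what makes the trunk's
   parameter count independent of the number of sensors.
2. **Attention layer.** Every head's per-channel map is unfolded into
   patches with a sliding *attention kernel* (default 2×2, stride equal to
   the kernel side). With `Patch_Size = kh·kw` and
   `B = Π_d ⌊(size_d − kernel_d)/stride + 1⌋` sliding positions, patches have
   shape `(C, Patch_Size, B)`. For each head and group `b` the cross-channel
   score is

       A[i, j, b] = softmax_j( sigmoid(q_i)_b · (k_j)_b ),

   the dot product running over the patch axis and the sigmoid applied to
   the query only (no 1/√d temperature). Channel `i`'s output patch is
   `Σ_j A[i, j, b] (v_j)_b`; the aggregation runs over the key channel only,
   so the channel axis survives and the patches fold back to `(C, M, H, W)`.
   The softmax is computed with max subtraction, which preserves values
   exactly.
3. **Adaptive pooling.** Adaptive average pooling (bins
   `[⌊i·n/out⌋, ⌈(i+1)·n/out⌉)`, exact block means in the divisible case)
   reduces `(M, H, W)`. The final iteration instead permutes
   `C×M×H×W → M×C×H×W` and pools `(C, H, W)` to `(1, 1, 1)`: one scalar per
   head, for any C.

The default head schedule is 64 → 128 → 256 with spatial halving 48 → 24 →
12, so the trunk emits a 256-vector. The **head-importance gate** computes
`V = sigmoid(W v + b) ⊙ v` with a 256→256 fully connected layer, letting the
model down-weight uninformative heads. The classifier is 256 → hidden
(rectifier) → K (softmax), trained with cross-entropy evaluated in the log
domain.

Because attention is symmetric in the channel index, the dense-layer weights
are channel-shared, and the last pooling averages over C, the final feature
vector is invariant to permuting the input channels, and one trained trunk
runs unchanged on inputs with a different channel count. Fine-tuning to a new
task replaces and re-initialises only the final classification layer; all
weights are then optimised at the reduced learning rate.

### Parameter accounting

Default configuration (48×48 spectrograms, 2×2 kernel, heads 64/128/256,
8 classes):

| block | count |
|---|---|
| Q/K/V projections, iteration 1 (double layer, ×3) | 3 · (1·64+64 + 64·64+64) = 12,864 |
| projections, iteration 2 (64→128, ×3) | 3 · (64·128+128) = 24,960 |
| projections, iteration 3 (128→256, ×3) | 3 · (128·256+256) = 99,072 |
| head-importance gate (256→256) | 65,792 |
| classifier 256→2368→8 | 627,528 |
| **total** | **830,216** |

The classifier hidden width defaults to 2368: the architecture is designed to
a 0.83 M parameter budget, and with the trunk and gate fixed the remaining
budget solves 265·h + 8 ≈ 830,216 − 202,696, i.e. h ≈ 2368. The width is
configurable. Serialised as float32 the default model is ≈3.3 MB on disk.

### The standard multi-head comparator

For ablations, `multihead="standard"` swaps the 1×1 head-mixing convolutions
(iterations 2 and 3) for per-position fully connected aggregation: each
spatial position owns its own M→M′ mixing matrix. This is the classical
"every connection has its own weight" alternative; it produces the same
output shapes but is orders of magnitude larger at every stage (e.g.
24²·128·65 ≈ 4.8 M weights versus 8,320 for one 64→128 projection), which is
the efficiency argument for the convolutional head generation.

## Spectrogram conversion

Per channel: Hann-windowed STFT with segment length L/8 rounded to the
nearest power of two (minimum 16) and 50% overlap; magnitudes floored at
ε = 1e-8 before the log; bilinear resize to the target (H, W), default
48×48; per-channel min-max normalisation to [0, 1]. Row 0 is the lowest
frequency band. The resize is what makes the network insensitive to the raw
signal length (an 80-sample and a 6000-sample window both become H×W
images); the min-max step removes the signal's absolute scale (log-amplitude
shifts cancel exactly, except where magnitudes approach the ε floor) and
keeps the sigmoid–softmax attention in a stable input range. A 48×48 target
is the default because smaller images start to merge nearby frequency bands
while larger ones mostly add interpolated pixels.

## Patch algebra

Extraction uses no padding — windows that do not fit are dropped, exactly as
the floor in the group-count formula implies. Group order and within-patch
order are both row-major. The default stride equals the kernel side, making
fold∘extract an exact identity (pure rearrangement, zero numerical error);
overlapping strides are supported, with folding assigning every position the
mean of its covering windows and the adjoint handled accordingly.

## Training

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8), learning rate 1e-3 from scratch and
1e-4 for fine-tuning, 100 epochs, batch size 128, seed 123 by default; no
schedule, weight decay or early stopping. The dataset is split 80/20
stratified by label with the run seed. Runs are bit-reproducible for a fixed
seed on a platform; the test harness pins BLAS to one thread so results do
not depend on the host's core count. Optimizer moments are kept in float64
while weights are float32.

The network is implemented on a small reverse-mode automatic-differentiation
core over numpy (`sensornet/_autodiff.py`) — tensors, broadcast arithmetic,
binary einsum, patch extract/fold, adaptive pooling and the nonlinearities,
each with a hand-written adjoint. Every adjoint, and the end-to-end loss
gradient of a tiny model, is verified against central finite differences in
the test suite.

## Synthetic study conditions

The generator emulates the time-frequency structure that separates activity
or sleep-stage classes: class k assigns each channel a *set* of carrier
frequencies, and the defaults give three qualitatively different spectral
signatures — narrow low-frequency ("still"-like), two-component harmonic
("walk"-like) and four-component broadband ("run"-like). Channels share each
carrier's random phase to degree `channel_coupling` (default 0.7), so
cross-channel attention sees correlated structure; white noise with sd 0.3
(carrier amplitude 1) is added. Defaults: 600 windows of 3 channels × 512
samples at 64 Hz, exactly balanced labels, fully deterministic per seed.

The synthetic experiments run a reduced model — 16×16 spectrograms, heads
16/32/64, hidden width 128 — matched to the scale of that task; the learning
check trains 50 epochs at batch 128 and reads held-out accuracy. The
transfer study pretrains on a 4-channel source task (50 epochs) and compares,
over three seeds, fine-tuning against scratch training on a 3-channel target
task with a disjoint carrier palette under a matched small budget (n = 200,
10 epochs). Batch size 32 is used for the n = 200 runs — batch 128 would
leave a single full batch per epoch. Windows are pure stationary sinusoid
mixtures; real IMU/EEG data are non-stationary, have correlated broadband
noise and class overlap, so passing these checks demonstrates that the
architecture and optimisation behave as designed, not that real-data
accuracies transfer.

## Numerical choices and edge cases

- Attention softmax and cross-entropy both use max-subtraction /
  log-domain forms; attention rows sum to 1 within 1e-6 by construction.
- All-zero signals produce a constant spectrogram normalised to 0 rather
  than NaN (the ε floor in the log, and a zero map when max = min).
- A constant spectrogram yields uniform attention weights 1/C — the
  symmetric fixed point, not an error.
- Adaptive pooling falls back to explicit ragged bins when the target does
  not divide the input; the divisible path is exact block averaging.
- Checkpoints are a single `.npz` container of float32 arrays plus an
  embedded JSON config; loading into a different class count keeps every
  trunk weight bit-exact and re-initialises only the final layer.

## Design choices where the design was open

- The printed form of the attention aggregation sums over both channel
  indices, which would collapse the channel axis and make the subsequent
  fold back to `(C, H, W)` impossible; the implementation aggregates over
  the key channel only, the standard attention reading consistent with the
  rest of the pipeline.
- Scalar filters of the first dense layer are shared across channels rather
  than indexed by channel; per-channel scalars would tie the trunk to a
  fixed C and break trunk portability.
- All projections carry biases; Q, K, V are independently parameterised;
  the three iterations do not share parameters.
- STFT segmentation, the resize-to-target step and the min-max
  normalisation are this package's choices (recorded above), as is the
  per-position-unshared form of the standard multi-head comparator.

## Known limitations

- Training is CPU-bound numpy; it is sized for the synthetic studies, not
  for multi-GB sensor corpora.
- No augmentation, wavelet/mel representations, positional encodings, or
  deployment-oriented quantisation.
- The attention cost grows as C² per patch group; very large channel counts
  (dense EEG montages) were not profiled.
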
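# Methods

## Problem setting

The package detects humpback whale vocalizations in short, fixed windows of
hydrophone audio. The unit of decision is a 6-second window advanced every
3 seconds; a deployed monitor therefore refreshes its prediction twice per
window length, and a call has at least two chances to appear (nearly)
whole. Short windows make the task harder than song-level detection:
the classifier sees fragments of calls against variable backgrounds rather
than minutes of harmonic continuity.

## Signal chain

1. **Standardization.** Input WAVs are mixed down to mono (arithmetic
   channel mean), polyphase-resampled to 44.1 kHz and quantized once to
   the 16-bit amplitude grid; amplitudes are floats in [−1, 1] from then
   on so no integer math propagates. Standardization is idempotent.
2. **Analysis rate.** Audio is resampled to 22,050 Hz, making a 6 s window
   exactly 6 × 22,050 = 132,300 samples.
3. **Windowing.** Windows start at 0, 3, 6, … s; a trailing remainder
   shorter than 6 s is discarded. The window count for duration *d* is
   ⌊(d − 6)/3⌋ + 1 (0 below 6 s); the property suite cross-checks this
   against brute-force enumeration of valid starts.
4. **Source-based split.** Whole recordings are shuffled by seed and
   assigned 70/15/15 to train/val/test. Sizes are round-half-away of
   n×ratio for val and test, remainder to train. Splitting after
   windowing would place near-duplicate windows on both sides of the
   train/test boundary; `check_no_leakage` audits any segment manifest
   for sources straddling splits.
5. **Truncation.** Within one source at most `max_segments` windows
   (default 40) are kept, in temporal order, so a single long recording
   cannot dominate its class. The default is a package choice; the
   appropriate cap depends on the corpus duration distribution.

## Feature images

Both feature kinds are rendered to the same 125×50×3 standardized tensor:

* **Mel spectrogram.** Power STFT with FFT 2048, hop 2646, Hann window and
  *centering disabled*: frames = 1 + ⌊(132300 − 2048)/2646⌋ = 50 exactly
  (centered framing would give 51). 125 unit-peak triangular mel filters
  span 0–10 kHz on the break-point mel scale m = 2595 log₁₀(1 + f/700).
  Power is converted to dB relative to the per-segment maximum with an
  80 dB floor.
* **Delta-MFCC.** MFCCs are the orthonormal DCT-II of the log-mel
  spectrum; 20 coefficients are kept by default (the count is
  configurable; common practice ranges 13–40). The first-order delta uses
  the standard regression window of width 9 with edge replication — a
  cepstral ramp linear in time maps to a constant equal to its slope.
  The 20×50 matrix is resized to 125 rows by linear interpolation at
  render time.
* **Rendering & standardization.** Matrices are min–max scaled per image
  (so positively affine-related matrices render identically), mapped
  through a perceptually uniform colormap (default `magma`,
  configurable), oriented with the lowest band at the bottom row, and
  per-image standardized to mean 0 / sd 1 (a constant image maps to
  zeros). Training always consumes float images; 8-bit export is an I/O
  path only, avoiding double quantization.

## Augmentation

Training windows only. Four operators each fire with independent
probability ½; if a round fires none, the whole Bernoulli vector is
redrawn, so conditioned on acceptance each operator's frequency is
(½)/(1 − (½)⁴) = 8/15 ≈ 0.533 — verified by simulation in the test suite.
Draws are uniform within:

| operator | range | note |
|---|---|---|
| Gaussian noise σ | 1–1.5 % of digital full scale | "full amplitude" is read as full scale (1.0), the usual convention in augmentation tooling, not the clip's own peak |
| pitch shift | −12…+12 semitones | length-preserving: polyphase resample then phase-vocoder stretch (hop 512, FFT 2048); the resample ratio is approximated by a rational with denominator ≤ 64 (< 0.3 % rate error) |
| high-pass cutoff | 1–2 kHz | Butterworth order 4, causal SOS filtering |
| time shift | ±3 s | circular (rollover) integer-sample shift |

Outputs are clipped to [−1, 1] and always exactly 132,300 samples. Each
original yields five variants, reproducible from (seed, segment index,
variant index); a degenerate no-op outcome (e.g. a zero-sample shift as
the only operator) is redrawn, so no variant is bit-identical to its
original. Augmentation operates on 22,050 Hz windows after segmentation
(the pre-rendered-dataset pattern: augment once, train many times).
`expand_training` refuses sources outside the training split.

## Architectures

**Compact CNN** (125×50×3 → 2 softmax): four convolutional blocks —
(16, 6×6, tanh), (32, 4×4, ReLU), (64, 3×3, ReLU) each followed by 2×2
max-pool, batch norm and dropout 0.5/0.4/0.3; then (64, 3×3, linear) +
flatten + dropout 0.2 — under a dense-64 ReLU / dense-2 softmax head.
Convolutions use stride 1 with 'same' padding so the 6×6 kernel is valid
at every stage; the fourth block's convolution has no listed activation
and is linear by default (configurable). The first convolution holds
16 × (6·6·3 + 1) = 1,744 parameters, asserted in the tests.

**ViT**: 90 non-overlapping 8×8 patches (15×6 grid; 5 remainder rows and
2 columns dropped) flattened to 192-float tokens, embedded to dimension
64, plus a learned positional embedding per patch index. Four pre-norm
encoder blocks: LayerNorm → 4-head attention (per-head key dim 64,
dropout 0.1) with residual, then LayerNorm → MLP 128→64 with GELU and
dropout 0.1 with residual. Head: LayerNorm, global average pooling over
tokens (no class token — pooling makes one redundant), MLP 2048/1024 GELU
with dropout 0.3, dense-2 softmax. With positional embeddings zeroed the
pooled logits are invariant to patch permutation (attention and average
pooling are permutation-equivariant), which the tests exploit as a wiring
check.

Both models are built on a small numpy layer library (`whalesong.nn`):
im2col convolutions processed one kernel row at a time (the row window is
contiguous in NHWC memory, keeping the copies cheap and the GEMM
contraction axis wide), slice-based max pooling, batch/layer norm,
inverted dropout, erf-based GELU, multi-head attention with hand-derived
backward passes (checked against central finite differences in the test
suite), and AdamW with decoupled weight decay. All math is float32;
softmax inputs are clamped at −60 before exponentiation because float32
subnormals degrade CPU throughput severely.

## Training

AdamW, base learning rate 10⁻³, weight decay 0.004, batch 128, sparse
categorical cross-entropy. The CNN trains 10 epochs at constant rate; the
ViT up to 30 epochs under a linear warm-up from 0 over the first 2 epochs
into cosine decay to 0, with early stopping (patience 5 on validation
loss) and restoration of the best-validation-loss checkpoint. A config
switch applies either schedule to either architecture. One seed covers
shuffling and dropout; weight initialization (Glorot uniform) is seeded at
build time, and two runs from the same seeds produce identical histories.

**Batch-norm recalibration.** At desk scale an epoch is only a handful of
optimizer steps, so momentum-tracked running statistics always lag the
current weights; the resulting train/eval mismatch can shift every logit
by a constant — rankings (AUC) survive but the decision boundary does
not. Before each validation pass, and therefore inside every checkpoint,
the batch-norm inference statistics are re-estimated exactly over (up to
1024) training images with dropout off — the same recalibration recipe
weight-averaging methods use. Checkpoints capture these buffers alongside
the weights.

## Evaluation

All summary metrics are computed directly from the 2×2 confusion counts
(precision, recall, F1 and supports per class; macro = unweighted mean;
weighted = support-weighted mean; accuracy = trace/total; MCC with the
0/0 → 0 convention, flagged). Zero-denominator cases return 0 and are
flagged. Because "FPR"/"FNR" flip meaning with the choice of positive
class, the report instead names both class-conditional error rates: the
fraction of true humpback windows misclassified and the fraction of true
no-call windows misclassified. Tables print class scores at integer
percent and rates at two decimals. ROC and PR curves (scikit-learn) come
with trapezoidal AUC — equal to the pairwise concordance probability,
which the tests verify to 10⁻⁹ — and average precision.

## Synthetic corpus

The generator emulates a curated PAM corpus statistically, not
acoustically: call sources are sequences of harmonic FM units (fundamental
uniform in 150–800 Hz, 2–4 partials with amplitudes decaying by 0.6 per
partial, exponential sweeps up to ±1 octave per unit, unit lengths
0.5–2 s with 0.3–1.5 s gaps, Hann envelopes) over a pink-noise bed; unit
SNR is drawn from 8–15 dB, a high-SNR regime representative of curated
foreground recordings. No-call sources cycle through pink noise, vessel
tonals (2–4 carriers in 20–200 Hz under 0.1–0.5 Hz amplitude modulation —
the low-frequency confounder real detectors trip on) and impulsive click
trains. Defaults: 20 sources per class, durations uniform in 4–90 s, with
the first source of each class forced below one window so the
zero-segment path is always exercised; sources are generated directly at
22,050 Hz. Everything is deterministic from (params, seed).

What passing tests on this corpus do and do not show: they demonstrate the
pipeline is wired correctly end-to-end and that the architectures can
learn band-structured harmonic cues against structured noise at realistic
SNR; they do not demonstrate performance on ocean recordings, which add
propagation effects, chorus overlap, recorder idiosyncrasies and far
larger within-class variability.

## Problem sizes and defaults

The default experiment (20+20 sources, per-source cap 40, 70/15/15 split)
yields roughly 400 training windows — ~2,000 after 5× augmentation — and
~100 windows each for validation and test; an end-to-end CNN run takes a
few minutes on one CPU core, chosen so that the full study loop remains a
desk-scale computation. Per-source corpus sizes, durations, SNR, the
truncation cap, MFCC count, colormap, batch-norm momentum and the
recalibration subset size are all configurable.

## Known limitations

* The phase-vocoder pitch shifter is serviceable for augmentation but not
  transcription-grade; transients smear, and the rational-ratio
  approximation adds up to 0.3 % frequency error.
* Per-source labels assume each recording is wholly call or no-call, as in
  a manually clipped corpus; windows of a call source that happen to fall
  in an inter-unit gap inherit the call label (label noise analogous to
  real curated data).
* Metrics from single small test splits carry large sampling error; the
  synthetic defaults favor runtime over tight confidence intervals.
* MobileNetV2-style transfer learning requires externally supplied
  pretrained weights; an adapter can wrap any callable classifier, but no
  pretrained path ships with the package.
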
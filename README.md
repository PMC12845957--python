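# whalesong

Short-window detection of humpback whale vocalizations in passive acoustic
monitoring (PAM) audio.

Hydrophone deployments produce hundreds of hours of recordings in which
whale calls occupy a small fraction of the timeline, embedded in pink-ish
ambient noise, vessel tonals and impulsive transients. `whalesong`
implements a complete detection pipeline for this setting, aimed at
bioacousticians and ML practitioners who need a reproducible, inspectable
baseline rather than a black box:

* **Standardization & windowing** — audio is standardized to mono /
  44.1 kHz / 16-bit, resampled to 22,050 Hz, and cut into 6 s analysis
  windows advanced every 3 s (132,300 samples per window), so a deployed
  monitor refreshes its prediction every three seconds and every call gets
  at least two chances to be seen whole.
* **Leakage-safe splitting** — whole recordings ("sources") are assigned
  70/15/15 to train/validation/test *before* windowing. Adjacent windows
  of one recording are nearly identical; splitting after windowing
  inflates test metrics. A `check_no_leakage` audit verifies any segment
  manifest.
* **Feature images** — each window becomes a 125×50×3 image: either a
  log-power mel spectrogram (FFT 2048, hop 2646, Hann, 125 mel bands to
  10 kHz, centering disabled so exactly 50 frames) or first-order
  delta-MFCCs rendered through a colormap, then per-image standardized.
* **Waveform augmentation** — training windows are expanded 5× by a
  stochastic pipeline of Gaussian noise (σ ∈ 1–1.5 % full scale), pitch
  shift (±12 semitones), high-pass filtering (1–2 kHz) and rollover time
  shift (±3 s), each firing with probability ½ and redrawn until at least
  one fires. Validation and test audio is never augmented.
* **Two classifiers, built from scratch in numpy** — a compact 4-block CNN
  (16/32/64/64 filters, 6×6→3×3 kernels, tanh then ReLU, max-pooling,
  batch norm, decreasing dropout, dense-64 head) and a small Vision
  Transformer (90 non-overlapping 8×8 patches → 64-d tokens with learned
  positions → 4 pre-norm encoder blocks with 4-head attention → average
  pooling → 2048/1024 GELU head). Training uses AdamW (lr 10⁻³, weight
  decay 0.004, batch 128, sparse categorical cross-entropy); the ViT adds
  a 2-epoch linear warm-up into cosine decay, early stopping (patience 5
  on validation loss) and best-checkpoint restoration.
* **Evaluation** — confusion matrix, per-class precision/recall/F1 with
  supports, macro/weighted averages, Matthews correlation coefficient
  (MCC), explicitly *named* class-conditional error rates (fraction of
  true humpback windows missed; fraction of true no-call windows
  misflagged), ROC and precision–recall curves with areas.
* **Synthetic corpus** — a deterministic generator of call-like sources
  (harmonic FM units, 150–800 Hz fundamentals with decaying partials, at a
  configured SNR over a pink-noise bed) and confounder sources (pink
  noise, low-frequency vessel tonals, click trains), so the whole pipeline
  is exercised end-to-end with no data download.

For a 2×2 confusion matrix with counts TP, FN, FP, TN the headline
statistic is

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

which stays honest under the class imbalance typical of PAM test sets.

## Worked example

```python
from whalesong import ConfusionMatrix, summarize
import numpy as np

# test-set confusion counts of a trained detector:
# 263 of 270 humpback windows and 1198 of 1207 no-call windows correct
report = summarize(ConfusionMatrix(np.array([[263, 7], [9, 1198]])))
print(report.format_table())
```

prints

```
Class            Precision %  Recall %    F1 %  Support
humpback                  97        97      97      270
no_call                   99        99      99     1207
macro avg                 98        98      98     1477
weighted avg              99        99      99     1477
accuracy: 98.92%   MCC: 0.96
error rate (true humpback): 2.59%   error rate (true no-call): 0.75%
```

— i.e. the detector misses 2.59 % of true whale windows and misflags
0.75 % of true no-call windows, with an overall accuracy of 98.92 % and an
MCC of 0.96 on a 1477-window test set.

The scripts in `examples/` walk each capability: corpus generation and
windowing, feature images, augmentation draws, end-to-end training with
the printed report, and sliding-window detection over a long recording.
A thin CLI (`whalesong synth/prepare/split/augment/featurize/train/
evaluate/predict`) chains the same stages through files on disk.

## Layout

```
src/whalesong/
  audio_io.py      WAV read/write, standardization, resampling
  segmentation.py  windowing, source splits, truncation, leakage audit
  features.py      mel / delta-MFCC feature images
  augmentation.py  stochastic waveform augmentation
  nn.py            numpy layers, attention, AdamW
  models.py        the CNN and ViT architectures
  training.py      schedules, training loop, checkpointing, predict
  evaluation.py    metric suite and curves
  synthetic.py     synthetic corpus generator
  pipeline.py      end-to-end orchestration
  cli.py           command-line stages
```

See `docs/methods.md` for the modelling choices, defaults and limitations.
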
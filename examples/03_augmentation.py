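"""Apply the stochastic training-set augmentation to one window.

Each of the four operators (Gaussian noise at 1-1.5% full scale, pitch
shift within +/-12 semitones, 1-2 kHz high-pass, +/-3 s rollover time
shift) fires independently with probability 0.5; if none fires the draw is
repeated, so every variant differs from its original.  Conditioned on
acceptance each operator's frequency is (1/2)/(1-(1/2)^4) = 8/15 ~ 0.533.
"""

import numpy as np

from whalesong import AugmentConfig, SynthParams, apply_augmentations, synth_call_source, window_clip
from whalesong.audio_io import ANALYSIS_RATE, AudioClip

clip = synth_call_source(12.0, SynthParams(), seed=11, source_id="demo")
segment = window_clip(clip)[0]
audio = AudioClip(segment.samples, ANALYSIS_RATE, "demo", "humpback")

rng = np.random.default_rng(0)
for i in range(5):
    variant, record = apply_augmentations(audio, AugmentConfig(), rng)
    draws = ", ".join(f"{k}={v:.3g}" for k, v in record["draws"].items())
    print(f"variant {i}: ops={record['operators']} ({draws}); "
          f"len={len(variant.samples)} (unchanged), "
          f"max|x|={np.abs(variant.samples).max():.3f}")
# Five such variants per training window expand the training set 5x;
# validation and test audio is never augmented.
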
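"""Render mel-spectrogram and delta-MFCC feature images for one call window.

Shows the 125x50 geometry (125 mel bands x 50 frames from FFT 2048 /
hop 2646 with centering disabled) and the per-image standardization the
classifiers expect (mean 0, sd 1).
"""

import numpy as np

from whalesong import (
    SynthParams,
    delta_mfcc,
    featurize_segment,
    mel_spectrogram,
    synth_call_source,
    window_clip,
)

clip = synth_call_source(12.0, SynthParams(), seed=4, source_id="demo")
segment = window_clip(clip)[0]

mel = mel_spectrogram(segment)
print(f"mel matrix: {mel.shape} (bands x frames), dB range "
      f"[{mel.values.min():.1f}, {mel.values.max():.1f}]")

dm = delta_mfcc(segment)
print(f"delta-MFCC matrix: {dm.shape} (cepstral rows x frames); "
      "resized to 125 rows when rendered")

for kind in ("mel", "delta_mfcc"):
    img = featurize_segment(segment, kind=kind)
    print(f"{kind:>10s} image: {img.pixels.shape}, mean {img.pixels.mean():+.2e}, "
          f"sd {img.pixels.std():.6f}")
# Both kinds produce the same 125x50x3 standardized tensor, so either can
# feed the CNN or the ViT unchanged.
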
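"""Shared fixtures: tones, segments and small synthetic corpora."""

from __future__ import annotations

import numpy as np
import pytest

from whalesong.audio_io import ANALYSIS_RATE, AudioClip
from whalesong.segmentation import SEGMENT_SAMPLES, Segment


def make_tone(freq_hz: float, duration_s: float, sample_rate: int, amplitude: float = 0.5) -> np.ndarray:
    t = np.arange(int(round(duration_s * sample_rate))) / sample_rate
    return amplitude * np.sin(2.0 * np.pi * freq_hz * t)


@pytest.fixture
def tone_segment():
    """A full 6 s segment holding a 1 kHz tone at the analysis rate."""

    def _make(freq_hz: float = 1000.0, amplitude: float = 0.5) -> Segment:
        samples = make_tone(freq_hz, SEGMENT_SAMPLES / ANALYSIS_RATE, ANALYSIS_RATE, amplitude)
        return Segment("tone", 0.0, samples[:SEGMENT_SAMPLES], "humpback")

    return _make


@pytest.fixture
def noise_segment():
    def _make(seed: int = 0, scale: float = 0.1) -> Segment:
        rng = np.random.default_rng(seed)
        return Segment("noise", 0.0, scale * rng.standard_normal(SEGMENT_SAMPLES), "no_call")

    return _make


@pytest.fixture
def tone_clip():
    def _make(freq_hz: float, duration_s: float, sample_rate: int, label: str = "unknown") -> AudioClip:
        return AudioClip(
            make_tone(freq_hz, duration_s, sample_rate), sample_rate, source_id="tone", label=label
        )

    return _make
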
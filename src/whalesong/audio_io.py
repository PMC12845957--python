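"""Reading, writing and standardizing hydrophone audio.

Every downstream stage of the detection pipeline assumes mono waveforms with
a known sample rate and amplitudes in [-1, 1].  Field recordings arrive in a
mix of channel layouts and rates, so ingestion standardizes each file to
mono / 44.1 kHz / 16-bit amplitude precision before it is resampled to the
22,050 Hz analysis rate used for feature extraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

STANDARD_RATE = 44_100
ANALYSIS_RATE = 22_050

#: Labels understood by the pipeline.  ``unknown`` marks un-annotated audio
#: (e.g. field recordings fed to ``predict``).
LABELS = ("humpback", "no_call", "unknown")

_PCM16_SCALE = 32768.0  # one LSB of 16-bit audio is 1/32768 of full scale


@dataclass
class AudioClip:
    """A labeled waveform tied to the recording ("source") it came from.

    ``samples`` is float, shape ``(n,)`` for mono or ``(n, channels)`` for
    multi-channel input awaiting standardization.
    """

    samples: np.ndarray
    sample_rate: int
    source_id: str
    label: str = "unknown"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be a positive integer")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


class AudioFormatError(ValueError):
    """Raised for files that are not readable PCM WAV."""


def read_wav(path: str | Path, source_id: str, label: str = "unknown") -> AudioClip:
    """Read a PCM WAV file into an :class:`AudioClip` at its native rate.

    Multi-channel audio is preserved; call :func:`standardize` to mix down.
    Integer PCM is rescaled to [-1, 1); float WAV is taken as-is.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:
        raise AudioFormatError(f"{path}: not a readable PCM WAV ({exc})") from exc
    if data.dtype == np.int16:
        samples = data / _PCM16_SCALE
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise AudioFormatError(f"{path}: unsupported WAV encoding {data.dtype}")
    return AudioClip(samples=samples, sample_rate=int(rate), source_id=source_id, label=label)


def write_wav(path: str | Path, clip: AudioClip) -> None:
    """Write a clip as 16-bit PCM WAV (the archival format of the pipeline)."""
    pcm = np.clip(np.round(clip.samples * _PCM16_SCALE), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), clip.sample_rate, pcm)


def quantize_16bit(samples: np.ndarray) -> np.ndarray:
    """Snap float amplitudes to the 16-bit grid and rescale to [-1, 1]."""
    return np.clip(np.round(samples * _PCM16_SCALE), -32768, 32767) / _PCM16_SCALE


def standardize(clip: AudioClip) -> AudioClip:
    """Standardize to mono, 44.1 kHz, 16-bit amplitude precision.

    Channel mixdown is the arithmetic mean.  Amplitudes are quantized to the
    16-bit grid exactly once, then held as floats so no further integer math
    propagates through the pipeline.  Idempotent.
    """
    if clip.n_samples == 0:
        raise ValueError("cannot standardize an empty clip")
    samples = clip.samples
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    mono = replace(clip, samples=samples)
    if mono.sample_rate != STANDARD_RATE:
        mono = resample(mono, STANDARD_RATE)
    return replace(mono, samples=quantize_16bit(mono.samples))


def resample(clip: AudioClip, target_rate: int) -> AudioClip:
    """Polyphase (anti-aliased) resampling to ``target_rate``.

    The output sample count is ``round(duration_s * target_rate)``; content
    above the target Nyquist frequency is suppressed by the polyphase
    low-pass.  Resampling to the native rate is the identity.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == clip.sample_rate:
        return clip
    ratio = Fraction(target_rate, clip.sample_rate)
    out = resample_poly(clip.samples, ratio.numerator, ratio.denominator, axis=0)
    n_expected = round(clip.n_samples * target_rate / clip.sample_rate)
    if out.shape[0] > n_expected:
        out = out[:n_expected]
    elif out.shape[0] < n_expected:
        pad = [(0, n_expected - out.shape[0])] + [(0, 0)] * (out.ndim - 1)
        out = np.pad(out, pad)
    return replace(clip, samples=out, sample_rate=target_rate)


def dominant_frequency(samples: np.ndarray, sample_rate: int) -> float:
    """Frequency (Hz) of the largest magnitude bin of the real DFT."""
    spectrum = np.abs(np.fft.rfft(samples))
    spectrum[0] = 0.0  # ignore DC
    freqs = np.fft.rfftfreq(len(samples), d=1.0 / sample_rate)
    return float(freqs[int(np.argmax(spectrum))])
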
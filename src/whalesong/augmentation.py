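"""Stochastic waveform augmentation for the training split.

Four operators, each applied with independent probability 0.5 to a 6 s
training segment: Gaussian noise (sd drawn from 1-1.5% of digital full
scale), pitch shift (-12..+12 semitones, length-preserving phase vocoder),
high-pass filtering (Butterworth, cutoff drawn from 1-2 kHz) and a circular
time shift of up to +/-3 s with rollover.  If a round applies no operator the
whole Bernoulli vector is redrawn, so every emitted variant differs from its
original.  Each original yields five independently augmented variants;
validation and test audio is never augmented.

"1-1.5% of the signal's full amplitude" is taken as a fraction of digital
full scale (1.0), the usual convention in augmentation tooling, not of the
clip's own peak.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy.signal import butter, resample_poly, sosfilt

from .audio_io import ANALYSIS_RATE, AudioClip
from .segmentation import SEGMENT_SAMPLES, Segment

OPERATORS = ("noise", "pitch", "highpass", "timeshift")

#: Order of the Butterworth high-pass (the cutoff is what is varied).
HIGHPASS_ORDER = 4


@dataclass(frozen=True)
class AugmentConfig:
    """Draw ranges and probabilities for the four operators."""

    p_apply: tuple[float, float, float, float] = (0.5, 0.5, 0.5, 0.5)
    noise_sd_range: tuple[float, float] = (0.01, 0.015)  # fraction of full scale
    pitch_range_semitones: tuple[float, float] = (-12.0, 12.0)
    highpass_cutoff_range_hz: tuple[float, float] = (1000.0, 2000.0)
    timeshift_range_s: tuple[float, float] = (-3.0, 3.0)
    variants_per_clip: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0.0 <= p <= 1.0 for p in self.p_apply):
            raise ValueError("operator probabilities must lie in [0, 1]")
        if not any(p > 0 for p in self.p_apply):
            raise ValueError("at least one operator must have p_apply > 0")


# ---------------------------------------------------------------------------
# individual operators; every one returns exactly len(input) samples
# ---------------------------------------------------------------------------

def add_gaussian_noise(samples: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    return samples + rng.normal(0.0, sd, size=samples.shape)


def _stft(y: np.ndarray, n_fft: int, hop: int) -> np.ndarray:
    window = np.hanning(n_fft)
    pad = np.pad(y, (n_fft // 2, n_fft // 2))
    n_frames = 1 + (len(pad) - n_fft) // hop
    idx = hop * np.arange(n_frames)[:, None] + np.arange(n_fft)[None, :]
    return np.fft.rfft(pad[idx] * window, axis=1).T


def _istft(spec: np.ndarray, n_fft: int, hop: int) -> np.ndarray:
    window = np.hanning(n_fft)
    n_frames = spec.shape[1]
    out = np.zeros(n_fft + hop * (n_frames - 1))
    wsum = np.zeros_like(out)
    frames = np.fft.irfft(spec, n=n_fft, axis=0).T * window
    for t in range(n_frames):
        out[t * hop : t * hop + n_fft] += frames[t]
        wsum[t * hop : t * hop + n_fft] += window**2
    out = out / np.maximum(wsum, 1e-8)
    return out[n_fft // 2 : -(n_fft // 2)]


def _phase_vocoder(spec: np.ndarray, rate: float, hop: int, n_fft: int) -> np.ndarray:
    """Time-stretch a complex STFT by 1/rate with phase accumulation."""
    n_bins, n_frames = spec.shape
    steps = np.arange(0, n_frames, rate)
    omega = 2.0 * np.pi * hop * np.arange(n_bins) / n_fft
    out = np.zeros((n_bins, len(steps)), dtype=complex)
    phase = np.angle(spec[:, 0])
    padded = np.pad(spec, ((0, 0), (0, 2)))
    for i, step in enumerate(steps):
        k = int(step)
        frac = step - k
        mag = (1.0 - frac) * np.abs(padded[:, k]) + frac * np.abs(padded[:, k + 1])
        out[:, i] = mag * np.exp(1j * phase)
        dphi = np.angle(padded[:, k + 1]) - np.angle(padded[:, k]) - omega
        dphi -= 2.0 * np.pi * np.round(dphi / (2.0 * np.pi))
        phase = phase + omega + dphi
    return out


def pitch_shift(samples: np.ndarray, semitones: float, sample_rate: int = ANALYSIS_RATE) -> np.ndarray:
    """Length-preserving pitch shift (resample + phase-vocoder stretch)."""
    if abs(semitones) < 1e-9:
        return samples.copy()
    factor = 2.0 ** (semitones / 12.0)
    n = len(samples)
    n_fft, hop = 2048, 512
    # speed playback up by `factor` (pitch * factor, duration / factor) ...
    frac = Fraction(1.0 / factor).limit_denominator(64)  # <0.3% rate error, cheap polyphase
    sped = resample_poly(samples, frac.numerator, frac.denominator)
    # ... then stretch duration back with a phase vocoder (pitch preserved)
    rate = len(sped) / n
    stretched = _istft(_phase_vocoder(_stft(sped, n_fft, hop), rate, hop, n_fft), n_fft, hop)
    if len(stretched) >= n:
        return stretched[:n]
    return np.pad(stretched, (0, n - len(stretched)))


def highpass(samples: np.ndarray, cutoff_hz: float, sample_rate: int = ANALYSIS_RATE) -> np.ndarray:
    sos = butter(HIGHPASS_ORDER, cutoff_hz, btype="highpass", fs=sample_rate, output="sos")
    return sosfilt(sos, samples)


def time_shift(samples: np.ndarray, shift_samples: int) -> np.ndarray:
    """Circular (rollover) shift: content pushed past the end re-enters at the start."""
    return np.roll(samples, shift_samples)


# ---------------------------------------------------------------------------
# stochastic pipeline
# ---------------------------------------------------------------------------

def apply_augmentations(
    clip: AudioClip,
    config: AugmentConfig = AugmentConfig(),
    rng: np.random.Generator | None = None,
) -> tuple[AudioClip, dict]:
    """Augment one clip; guaranteed to apply at least one operator.

    The Bernoulli vector over the four operators is redrawn whenever no
    operator fires (and, as a degenerate-input guard, whenever the output is
    bit-identical to the input, e.g. a zero-sample time shift).  Output
    length equals input length; amplitudes are clipped to [-1, 1].  Returns
    the augmented clip and a record of the operators and parameter draws.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if clip.samples.ndim != 1:
        raise ValueError("augmentation expects mono audio")
    x = clip.samples
    for _ in range(1000):
        fired = rng.random(4) < np.asarray(config.p_apply)
        if not fired.any():
            continue
        y = x.copy()
        record: dict = {"operators": [], "draws": {}}
        if fired[0]:
            sd = rng.uniform(*config.noise_sd_range)
            y = add_gaussian_noise(y, sd, rng)
            record["operators"].append("noise")
            record["draws"]["noise_sd"] = sd
        if fired[1]:
            semis = rng.uniform(*config.pitch_range_semitones)
            y = pitch_shift(y, semis, clip.sample_rate)
            record["operators"].append("pitch")
            record["draws"]["pitch_semitones"] = semis
        if fired[2]:
            cutoff = rng.uniform(*config.highpass_cutoff_range_hz)
            y = highpass(y, cutoff, clip.sample_rate)
            record["operators"].append("highpass")
            record["draws"]["highpass_cutoff_hz"] = cutoff
        if fired[3]:
            lo, hi = config.timeshift_range_s
            shift = int(round(rng.uniform(lo, hi) * clip.sample_rate))
            y = time_shift(y, shift)
            record["operators"].append("timeshift")
            record["draws"]["timeshift_samples"] = shift
        y = np.clip(y, -1.0, 1.0)
        if np.array_equal(y, x):
            continue  # degenerate no-op (e.g. zero shift on its own); redraw
        return replace(clip, samples=y), record
    raise RuntimeError("augmentation failed to modify the clip in 1000 rounds")


def expand_training(
    segments: list[Segment],
    config: AugmentConfig = AugmentConfig(),
    split_of: dict[str, str] | None = None,
    include_originals: bool = False,
) -> tuple[list[Segment], list[dict]]:
    """Emit ``variants_per_clip`` augmented variants per training segment.

    ``split_of`` (source_id -> split) is the leakage guard: any segment whose
    source is not in the training split is refused.  Variant ``i`` of segment
    ``s`` is reproducible from ``(config.seed, s, i)`` alone.  Returns the
    expanded segment list and one metadata record per variant (parent index,
    variant index, operators, draws).
    """
    if split_of is not None:
        offenders = sorted({s.source_id for s in segments if split_of.get(s.source_id) != "train"})
        if offenders:
            raise ValueError(
                f"refusing to augment non-training sources (leakage): {offenders}"
            )
    out: list[Segment] = []
    records: list[dict] = []
    root = np.random.SeedSequence(config.seed)
    for s_idx, seg in enumerate(segments):
        if include_originals:
            out.append(seg)
            records.append({"parent_segment": s_idx, "variant_index": -1, "operators": [], "draws": {}})
        for v_idx in range(config.variants_per_clip):
            rng = np.random.default_rng(np.random.SeedSequence(entropy=root.entropy, spawn_key=(s_idx, v_idx)))
            clip = AudioClip(seg.samples, ANALYSIS_RATE, seg.source_id, seg.label)
            aug, record = apply_augmentations(clip, config, rng)
            out.append(Segment(seg.source_id, seg.start_s, aug.samples, seg.label))
            record.update({"parent_segment": s_idx, "variant_index": v_idx})
            records.append(record)
    return out, records


def records_to_rows(records: list[dict]) -> list[dict]:
    """Flatten augmentation records for the CSV manifest."""
    return [
        {
            "parent_segment": r["parent_segment"],
            "variant_index": r["variant_index"],
            "operators_applied": ";".join(r["operators"]),
            "draw_parameters": json.dumps(r["draws"]),
        }
        for r in records
    ]
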
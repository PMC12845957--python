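"""Time-frequency feature images for the classifiers.

Each 6 s segment becomes a 125x50x3 image: 125 mel bands (or cepstral rows
resized to 125) by 50 time frames by 3 color channels.  The frame count is
exact by construction: with FFT size 2048, hop 2646 and *no* centering,
``1 + floor((132300 - 2048) / 2646) = 50``.  Centered framing would give 51
frames, so centering is disabled throughout.

The mel scale here is the common break-point form ``m = 2595 log10(1 + f/700)``.
Filter-bank triangles are unit-peak (no area normalization).  Log-power is
referenced to the per-segment maximum with an 80 dB floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from matplotlib import colormaps
from scipy.fft import dct
from scipy.ndimage import zoom

from .audio_io import ANALYSIS_RATE
from .segmentation import SEGMENT_SAMPLES, Segment

DB_FLOOR = 80.0


@dataclass(frozen=True)
class SpectroParams:
    """Spectrogram configuration shared by mel and MFCC pipelines."""

    sample_rate: int = ANALYSIS_RATE
    n_fft: int = 2048
    hop: int = 2646  # 132,300 / 50 exactly -> 50 frames per segment
    n_mels: int = 125
    f_min: float = 0.0
    f_max: float = 10_000.0
    n_mfcc: int = 20

    def n_frames(self, n_samples: int = SEGMENT_SAMPLES) -> int:
        if n_samples < self.n_fft:
            return 0
        return 1 + (n_samples - self.n_fft) // self.hop


@dataclass
class FeatureMatrix:
    """A 2-D feature array: rows are frequency/cepstral bins, columns frames."""

    values: np.ndarray
    kind: str  # "mel" or "delta_mfcc"

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class FeatureImage:
    """125x50x3 float image fed to the classifiers.

    Row 0 is the *top* of the displayed image, i.e. the highest frequency;
    the lowest band sits at the bottom row (index 124).
    """

    pixels: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected HxWx3 pixels, got {self.pixels.shape}")


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(params: SpectroParams) -> np.ndarray:
    """Unit-peak triangular mel filters, shape (n_mels, n_fft//2 + 1)."""
    n_bins = params.n_fft // 2 + 1
    fft_freqs = np.fft.rfftfreq(params.n_fft, d=1.0 / params.sample_rate)
    mel_edges = np.linspace(hz_to_mel(params.f_min), hz_to_mel(params.f_max), params.n_mels + 2)
    hz_edges = mel_to_hz(mel_edges)
    fb = np.zeros((params.n_mels, n_bins))
    for i in range(params.n_mels):
        lo, mid, hi = hz_edges[i], hz_edges[i + 1], hz_edges[i + 2]
        rising = (fft_freqs - lo) / max(mid - lo, 1e-12)
        falling = (hi - fft_freqs) / max(hi - mid, 1e-12)
        fb[i] = np.clip(np.minimum(rising, falling), 0.0, None)
    return fb


def _power_spectrogram(samples: np.ndarray, params: SpectroParams) -> np.ndarray:
    """Hann-windowed power STFT without centering, shape (n_bins, n_frames)."""
    n = len(samples)
    n_frames = params.n_frames(n)
    if n_frames == 0:
        raise ValueError(f"segment of {n} samples is shorter than one FFT frame")
    window = np.hanning(params.n_fft)
    idx = params.hop * np.arange(n_frames)[:, None] + np.arange(params.n_fft)[None, :]
    frames = samples[idx] * window
    spec = np.abs(np.fft.rfft(frames, axis=1)) ** 2
    return spec.T


def power_to_db(power: np.ndarray, floor_db: float = DB_FLOOR) -> np.ndarray:
    """Log-power in dB relative to the array maximum, floored at -floor_db."""
    ref = max(power.max(), 1e-30)
    db = 10.0 * np.log10(np.maximum(power, 1e-30) / ref)
    return np.maximum(db, -floor_db)


def _check_segment(segment: Segment, params: SpectroParams) -> None:
    if len(segment.samples) != SEGMENT_SAMPLES:
        raise ValueError(f"expected a {SEGMENT_SAMPLES}-sample segment")


def mel_spectrogram(segment: Segment, params: SpectroParams = SpectroParams()) -> FeatureMatrix:
    """Log-power mel spectrogram of one segment: (n_mels, 50) dB values."""
    _check_segment(segment, params)
    spec = _power_spectrogram(segment.samples, params)
    mel = mel_filterbank(params) @ spec
    return FeatureMatrix(values=power_to_db(mel), kind="mel")


def mfcc(segment: Segment, params: SpectroParams = SpectroParams()) -> np.ndarray:
    """MFCCs: orthonormal DCT-II of the log-mel spectrum, (n_mfcc, 50)."""
    if params.n_mfcc < 2:
        raise ValueError("n_mfcc must be >= 2")
    mel_db = mel_spectrogram(segment, params).values
    return dct(mel_db, type=2, norm="ortho", axis=0)[: params.n_mfcc]


def delta(coeffs: np.ndarray, width: int = 9) -> np.ndarray:
    """First-order regression delta along the time axis.

    Uses the standard regression window of half-width M = (width-1)//2 with
    edge-replication padding; a cepstral ramp linear in time yields a
    constant delta equal to the slope (exact away from the edges).
    """
    if width < 3 or width % 2 == 0:
        raise ValueError("width must be an odd integer >= 3")
    m = (width - 1) // 2
    padded = np.pad(coeffs, ((0, 0), (m, m)), mode="edge")
    kernel = np.arange(-m, m + 1, dtype=np.float64)
    denom = 2.0 * np.sum(np.arange(1, m + 1, dtype=np.float64) ** 2)
    out = np.zeros_like(coeffs, dtype=np.float64)
    for n in range(1, m + 1):
        out += n * (padded[:, m + n : m + n + coeffs.shape[1]] - padded[:, m - n : m - n + coeffs.shape[1]])
    return out / denom


def delta_mfcc(
    segment: Segment, params: SpectroParams = SpectroParams(), n_mfcc: int | None = None
) -> FeatureMatrix:
    """First-order delta of the MFCCs, (n_mfcc, 50); resized to 125 rows at render time."""
    if n_mfcc is not None:
        params = replace(params, n_mfcc=n_mfcc)
    return FeatureMatrix(values=delta(mfcc(segment, params)), kind="delta_mfcc")


def render_rgb(
    matrix: FeatureMatrix,
    colormap_name: str = "magma",
    out_shape: tuple[int, int] = (125, 50),
) -> FeatureImage:
    """Render a feature matrix as a 125x50x3 color image.

    Values are min-max scaled to [0, 1] per image (so positively affine-related
    matrices render identically), mapped through the named colormap, and
    resized along the row axis if needed (linear interpolation, used by the
    delta-MFCC path).  An all-constant matrix renders at mid-scale.  Row 0 of
    the matrix is the lowest frequency band; the image is flipped so the low
    band lands on the bottom row.
    """
    values = np.asarray(matrix.values, dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise ValueError("feature matrix contains non-finite values")
    span = values.max() - values.min()
    if span <= 0:
        scaled = np.full_like(values, 0.5)
    else:
        scaled = (values - values.min()) / span
    if scaled.shape != out_shape:
        factors = (out_shape[0] / scaled.shape[0], out_shape[1] / scaled.shape[1])
        scaled = np.clip(zoom(scaled, factors, order=1, grid_mode=True, mode="nearest"), 0.0, 1.0)
        if scaled.shape != out_shape:  # zoom rounding guard
            scaled = scaled[: out_shape[0], : out_shape[1]]
    rgb = colormaps[colormap_name](scaled)[..., :3]
    return FeatureImage(pixels=rgb[::-1].copy(), standardized=False)


def standardize_image(img: FeatureImage, from_8bit: bool = False) -> FeatureImage:
    """Per-image standardization: zero mean, unit variance (epsilon-guarded).

    ``from_8bit`` first rescales by 1/255 for images round-tripped through
    8-bit export.  Constant images map to all zeros.  Idempotent after the
    first pass.
    """
    pixels = img.pixels / 255.0 if from_8bit else img.pixels
    mean = pixels.mean()
    sd = pixels.std()
    if sd < 1e-12:
        return FeatureImage(pixels=np.zeros_like(pixels), standardized=True)
    return FeatureImage(pixels=(pixels - mean) / sd, standardized=True)


def featurize_segment(
    segment: Segment,
    kind: str = "mel",
    params: SpectroParams = SpectroParams(),
    colormap_name: str = "magma",
) -> FeatureImage:
    """Segment -> standardized 125x50x3 image, for either feature kind."""
    if kind == "mel":
        matrix = mel_spectrogram(segment, params)
    elif kind == "delta_mfcc":
        matrix = delta_mfcc(segment, params)
    else:
        raise ValueError(f"unknown feature kind {kind!r}")
    return standardize_image(render_rgb(matrix, colormap_name))
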
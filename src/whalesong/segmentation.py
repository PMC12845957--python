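"""Fixed-window segmentation and leakage-safe source splitting.

Detection operates on 6-second analysis windows advanced every 3 seconds, so
predictions refresh twice per window while each call gets multiple chances
to be seen whole.  Whole recordings ("sources") are assigned to
train/validation/test *before* windowing: temporally adjacent windows from
one recording are nearly identical, and letting them straddle splits leaks
evaluation data into training.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .audio_io import ANALYSIS_RATE, AudioClip

WINDOW_S = 6.0
HOP_S = 3.0
SEGMENT_SAMPLES = int(WINDOW_S * ANALYSIS_RATE)  # 132,300
DEFAULT_RATIOS = (0.70, 0.15, 0.15)
SPLITS = ("train", "val", "test")

#: Default per-source segment cap applied to over-long recordings so that a
#: single long file cannot dominate its class (threshold is a package
#: default; tune per corpus).
DEFAULT_MAX_SEGMENTS = 40


@dataclass
class Segment:
    """One 6-second analysis window cut from a source recording."""

    source_id: str
    start_s: float
    samples: np.ndarray  # exactly SEGMENT_SAMPLES floats at 22,050 Hz
    label: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.shape != (SEGMENT_SAMPLES,):
            raise ValueError(
                f"segment must hold exactly {SEGMENT_SAMPLES} samples, got {self.samples.shape}"
            )


@dataclass
class SplitManifest:
    """Source-level split assignment: the anti-leakage ledger."""

    assignment: dict[str, str]
    ratios: tuple[float, float, float] = DEFAULT_RATIOS
    seed: int = 0

    def sources_in(self, split: str) -> list[str]:
        return sorted(s for s, sp in self.assignment.items() if sp == split)

    def split_of(self, source_id: str) -> str:
        return self.assignment[source_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"source_id": list(self.assignment), "split": list(self.assignment.values())}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SplitManifest":
        df = pd.read_csv(path)
        return cls(assignment=dict(zip(df["source_id"].astype(str), df["split"])))


def window_clip(clip: AudioClip, window_s: float = WINDOW_S, hop_s: float = HOP_S) -> list[Segment]:
    """Cut a 22,050 Hz mono clip into overlapping fixed windows.

    Windows start at 0, hop_s, 2*hop_s, ...; a trailing remainder shorter
    than a full window is dropped.  For the 6 s / 3 s defaults the count is
    ``floor((duration - 6) / 3) + 1`` (zero below 6 s).
    """
    if clip.sample_rate != ANALYSIS_RATE:
        raise ValueError(
            f"window_clip expects {ANALYSIS_RATE} Hz audio, got {clip.sample_rate} Hz; resample first"
        )
    if clip.samples.ndim != 1:
        raise ValueError("window_clip expects mono audio")
    win = int(round(window_s * clip.sample_rate))
    hop = int(round(hop_s * clip.sample_rate))
    segments = []
    start = 0
    while start + win <= clip.n_samples:
        segments.append(
            Segment(
                source_id=clip.source_id,
                start_s=start / clip.sample_rate,
                samples=clip.samples[start : start + win],
                label=clip.label,
            )
        )
        start += hop
    return segments


def assign_splits(
    source_ids: list[str],
    ratios: tuple[float, float, float] = DEFAULT_RATIOS,
    seed: int = 0,
) -> SplitManifest:
    """Shuffle sources by seed and partition into train/val/test.

    Split sizes are round-half-away-from-zero of ``n * ratio`` for val and
    test; the remainder goes to train.  Deterministic given the seed.
    """
    if not source_ids:
        raise ValueError("cannot split an empty source list")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    order = list(source_ids)
    rng.shuffle(order)
    n = len(order)
    n_val = int(np.floor(n * ratios[1] + 0.5))
    n_test = int(np.floor(n * ratios[2] + 0.5))
    n_train = n - n_val - n_test
    if n_train < 0:
        raise ValueError("ratios leave no room for a training split")
    assignment = {}
    for i, sid in enumerate(order):
        if i < n_train:
            assignment[sid] = "train"
        elif i < n_train + n_val:
            assignment[sid] = "val"
        else:
            assignment[sid] = "test"
    return SplitManifest(assignment=assignment, ratios=ratios, seed=seed)


def cap_source(segments: list[Segment], max_segments: int | None = DEFAULT_MAX_SEGMENTS) -> list[Segment]:
    """Keep at most the first ``max_segments`` windows of one source.

    Over-long recordings otherwise dominate their class after windowing.
    ``None`` disables the cap.
    """
    if max_segments is None:
        return list(segments)
    if max_segments < 0:
        raise ValueError("max_segments must be non-negative")
    sources = {s.source_id for s in segments}
    if len(sources) > 1:
        raise ValueError(f"cap_source expects segments of one source, got {sorted(sources)}")
    ordered = sorted(segments, key=lambda s: s.start_s)
    return ordered[:max_segments]


def check_no_leakage(manifest: SplitManifest, segment_rows) -> dict[str, set[str]]:
    """Audit segment-level split assignments for cross-split sources.

    ``segment_rows`` is a segment manifest - a DataFrame or iterable of
    mappings with ``source_id`` and ``split`` fields (the table written next
    to every featurized dataset).  The report lists each source whose
    segments occupy more than one split; an empty report means no leakage.
    Splitting at the source *before* windowing (``assign_splits`` +
    inheriting the source's split) yields an empty report by construction;
    windowing first and splitting segments at random does not.
    """
    if isinstance(segment_rows, pd.DataFrame):
        segment_rows = segment_rows.to_dict("records")
    seen: dict[str, set[str]] = defaultdict(set)
    for row in segment_rows:
        sid, split = str(row["source_id"]), str(row["split"])
        if sid not in manifest.assignment:
            raise KeyError(f"segment source {sid!r} missing from manifest")
        seen[sid].add(split)
    return {sid: splits for sid, splits in seen.items() if len(splits) > 1}


def segments_to_frame(segments: list[Segment], manifest: SplitManifest | None = None) -> pd.DataFrame:
    """Tabulate segments (source_id, split, start_s, label) for manifests."""
    rows = []
    for seg in segments:
        rows.append(
            {
                "source_id": seg.source_id,
                "split": manifest.split_of(seg.source_id) if manifest else "",
                "start_s": seg.start_s,
                "label": seg.label,
            }
        )
    return pd.DataFrame(rows, columns=["source_id", "split", "start_s", "label"])
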
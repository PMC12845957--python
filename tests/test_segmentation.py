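"""Windowing arithmetic and leakage-safe splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from whalesong.audio_io import ANALYSIS_RATE, AudioClip
from whalesong.segmentation import (
    SEGMENT_SAMPLES,
    SplitManifest,
    assign_splits,
    cap_source,
    check_no_leakage,
    window_clip,
)


def _clip(duration_s: float, source_id: str = "s", label: str = "no_call") -> AudioClip:
    n = int(round(duration_s * ANALYSIS_RATE))
    return AudioClip(np.zeros(n), ANALYSIS_RATE, source_id, label)


def brute_force_starts(n_samples: int, win: int = SEGMENT_SAMPLES, hop: int = 3 * ANALYSIS_RATE):
    """Enumerate every valid window start directly."""
    return [s for s in range(0, n_samples + 1, hop) if s + win <= n_samples]


class TestWindowing:
    @pytest.mark.parametrize(
        "duration_s,expected",
        [(6.0, 1), (12.0, 3), (5.9, 0), (8.9, 1), (9.0, 2), (60.0, 19)],
    )
    def test_window_count(self, duration_s, expected):
        segs = window_clip(_clip(duration_s))
        assert len(segs) == expected
        assert [s.start_s for s in segs] == [3.0 * i for i in range(expected)]

    @settings(max_examples=40, deadline=None)
    @given(n_extra=st.integers(min_value=0, max_value=40 * ANALYSIS_RATE))
    def test_count_matches_brute_force_enumeration(self, n_extra):
        n = n_extra
        clip = AudioClip(np.zeros(n), ANALYSIS_RATE, "h", "no_call")
        segs = window_clip(clip)
        starts = brute_force_starts(n)
        assert len(segs) == len(starts)
        assert [int(s.start_s * ANALYSIS_RATE) for s in segs] == starts

    def test_consecutive_windows_share_66150_samples(self):
        rng = np.random.default_rng(0)
        clip = AudioClip(rng.standard_normal(9 * ANALYSIS_RATE), ANALYSIS_RATE, "o", "no_call")
        a, b = window_clip(clip)
        assert np.array_equal(a.samples[3 * ANALYSIS_RATE :], b.samples[: 3 * ANALYSIS_RATE])
        assert 3 * ANALYSIS_RATE == 66_150

    def test_wrong_rate_rejected(self):
        clip = AudioClip(np.zeros(44_100 * 6), 44_100, "w", "no_call")
        with pytest.raises(ValueError, match="resample"):
            window_clip(clip)


class TestAssignSplits:
    def test_twenty_sources_give_14_3_3(self):
        manifest = assign_splits([f"s{i}" for i in range(20)], seed=0)
        sizes = {sp: len(manifest.sources_in(sp)) for sp in ("train", "val", "test")}
        assert sizes == {"train": 14, "val": 3, "test": 3}

    def test_degenerate_all_train(self):
        manifest = assign_splits(["a", "b", "c"], ratios=(1.0, 0.0, 0.0), seed=1)
        assert manifest.sources_in("train") == ["a", "b", "c"]

    def test_deterministic_given_seed(self):
        ids = [f"s{i}" for i in range(31)]
        assert assign_splits(ids, seed=7).assignment == assign_splits(ids, seed=7).assignment
        assert assign_splits(ids, seed=7).assignment != assign_splits(ids, seed=8).assignment

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assign_splits([])

    @settings(max_examples=30, deadline=None)
    @given(n=st.integers(min_value=1, max_value=200), seed=st.integers(0, 2**31 - 1))
    def test_is_a_partition(self, n, seed):
        ids = [f"s{i}" for i in range(n)]
        manifest = assign_splits(ids, seed=seed)
        assert sorted(manifest.assignment) == sorted(ids)
        assert set(manifest.assignment.values()) <= {"train", "val", "test"}


class TestCapSource:
    def _segments(self, n):
        return window_clip(_clip(6 + 3 * (n - 1) + 0.5, source_id="long"))

    def test_prefix_rule(self):
        segs = self._segments(100)
        capped = cap_source(segs, 40)
        assert len(capped) == 40
        assert [s.start_s for s in capped] == [3.0 * i for i in range(40)]

    def test_none_is_identity_and_zero_empties(self):
        segs = self._segments(5)
        assert cap_source(segs, None) == segs
        assert cap_source(segs, 0) == []

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cap_source(self._segments(2), -1)


def _inherited_rows(manifest, source_segment_counts):
    """Segment rows built the safe way: each window inherits its source split."""
    rows = []
    for sid, count in source_segment_counts.items():
        rows.extend({"source_id": sid, "split": manifest.split_of(sid)} for _ in range(count))
    return rows


class TestLeakage:
    def test_source_first_split_never_leaks(self):
        manifest = assign_splits(["a", "b"], seed=0)
        rows = _inherited_rows(manifest, {"a": 9, "b": 6})
        assert check_no_leakage(manifest, rows) == {}

    def test_cross_split_source_detected(self):
        manifest = SplitManifest(assignment={"a": "train", "b": "test"})
        rows = [
            {"source_id": "a", "split": "train"},
            {"source_id": "a", "split": "test"},  # adjacent windows straddle splits
            {"source_id": "b", "split": "test"},
        ]
        report = check_no_leakage(manifest, rows)
        assert list(report) == ["a"]
        assert report["a"] == {"train", "test"}

    def test_unknown_source_rejected(self):
        manifest = SplitManifest(assignment={"a": "train"})
        with pytest.raises(KeyError):
            check_no_leakage(manifest, [{"source_id": "ghost", "split": "train"}])

    def test_fuzzed_corpora_never_leak(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(3, 40))
            ids = [f"s{i}" for i in range(n)]
            manifest = assign_splits(ids, seed=int(rng.integers(2**31)))
            counts = {sid: int(rng.integers(0, 12)) for sid in ids}
            assert check_no_leakage(manifest, _inherited_rows(manifest, counts)) == {}
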
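"""Augmentation operators and the at-least-one rejection rule."""

import numpy as np
import pytest

from whalesong.audio_io import ANALYSIS_RATE, AudioClip, dominant_frequency
from whalesong.augmentation import (
    AugmentConfig,
    add_gaussian_noise,
    apply_augmentations,
    expand_training,
    highpass,
    pitch_shift,
    time_shift,
)
from whalesong.segmentation import SEGMENT_SAMPLES, Segment

from conftest import make_tone


def _seg_clip(seed=0, scale=0.1):
    rng = np.random.default_rng(seed)
    return AudioClip(scale * rng.standard_normal(SEGMENT_SAMPLES), ANALYSIS_RATE, "s", "humpback")


class TestOperators:
    def test_every_operator_preserves_length(self):
        x = _seg_clip().samples
        rng = np.random.default_rng(1)
        assert len(add_gaussian_noise(x, 0.012, rng)) == SEGMENT_SAMPLES
        assert len(pitch_shift(x, 7.3)) == SEGMENT_SAMPLES
        assert len(pitch_shift(x, -12.0)) == SEGMENT_SAMPLES
        assert len(highpass(x, 1500.0)) == SEGMENT_SAMPLES
        assert len(time_shift(x, 12345)) == SEGMENT_SAMPLES

    def test_noise_only_path_sd_in_range(self):
        clip = _seg_clip()
        cfg = AugmentConfig(p_apply=(1.0, 0.0, 0.0, 0.0))
        out, record = apply_augmentations(clip, cfg, np.random.default_rng(3))
        assert record["operators"] == ["noise"]
        sd = np.std(out.samples - clip.samples)
        assert 0.009 <= sd <= 0.016  # draw range 1-1.5% of full scale

    def test_rollover_click_moves_modularly(self):
        # unit click at t=4 s shifted +3 s in a 6 s clip re-enters at t=1 s
        x = np.zeros(SEGMENT_SAMPLES)
        x[4 * ANALYSIS_RATE] = 1.0
        y = time_shift(x, 3 * ANALYSIS_RATE)
        assert y[1 * ANALYSIS_RATE] == 1.0
        assert np.count_nonzero(y) == 1

    @pytest.mark.parametrize("semitones,expected", [(12.0, 880.0), (-12.0, 220.0)])
    def test_pitch_shift_moves_a_tone(self, semitones, expected):
        tone = make_tone(440.0, 6.0, ANALYSIS_RATE)[:SEGMENT_SAMPLES]
        shifted = pitch_shift(tone, semitones)
        f = dominant_frequency(shifted[ANALYSIS_RATE:-ANALYSIS_RATE], ANALYSIS_RATE)
        assert abs(f - expected) < 15.0

    def test_highpass_suppresses_low_keeps_high(self):
        low = make_tone(200.0, 6.0, ANALYSIS_RATE)[:SEGMENT_SAMPLES]
        high = make_tone(4000.0, 6.0, ANALYSIS_RATE)[:SEGMENT_SAMPLES]
        assert np.std(highpass(low, 1500.0)) < 0.05 * np.std(low)
        assert np.std(highpass(high, 1500.0)) > 0.9 * np.std(high)


class TestRejectionRule:
    def test_at_least_one_operator_always_fires(self):
        clip = _seg_clip()
        rng = np.random.default_rng(0)
        cfg = AugmentConfig()
        for _ in range(20):
            out, record = apply_augmentations(clip, cfg, rng)
            assert len(record["operators"]) >= 1
            assert not np.array_equal(out.samples, clip.samples)
            assert np.max(np.abs(out.samples)) <= 1.0

    def test_conditional_marginal_is_8_over_15(self):
        """P(operator fires | >=1 fires) = (1/2) / (1 - (1/2)^4) = 8/15."""
        # short clips keep 10,000 full-pipeline draws affordable
        clip = AudioClip(
            0.1 * np.random.default_rng(0).standard_normal(441), ANALYSIS_RATE, "s", "humpback"
        )
        cfg = AugmentConfig()
        rng = np.random.default_rng(123)
        n = 10_000
        fired = np.zeros(4)
        for _ in range(n):
            _, record = apply_augmentations(clip, cfg, rng)
            for k, op in enumerate(("noise", "pitch", "highpass", "timeshift")):
                fired[k] += op in record["operators"]
        p = 8.0 / 15.0
        se = np.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(fired / n - p) <= 3 * se)

    def test_all_zero_probabilities_rejected(self):
        with pytest.raises(ValueError):
            AugmentConfig(p_apply=(0.0, 0.0, 0.0, 0.0))


class TestExpandTraining:
    def _segments(self, n=4):
        rng = np.random.default_rng(7)
        return [
            Segment(f"src{i % 2}", 3.0 * i, 0.1 * rng.standard_normal(SEGMENT_SAMPLES), "humpback")
            for i in range(n)
        ]

    def test_five_variants_per_segment(self):
        segs = self._segments(4)
        out, records = expand_training(segs, AugmentConfig(seed=5))
        assert len(out) == 20
        assert len(records) == 20
        assert all(len(s.samples) == SEGMENT_SAMPLES for s in out)
        assert all(s.label == "humpback" for s in out)

    def test_reproducible_from_seed(self):
        segs = self._segments(2)
        out1, _ = expand_training(segs, AugmentConfig(seed=11))
        out2, _ = expand_training(segs, AugmentConfig(seed=11))
        for a, b in zip(out1, out2):
            assert np.array_equal(a.samples, b.samples)

    def test_no_variant_identical_to_original(self):
        segs = self._segments(4)
        out, records = expand_training(segs, AugmentConfig(seed=2))
        for rec, var in zip(records, out):
            parent = segs[rec["parent_segment"]]
            assert not np.array_equal(var.samples, parent.samples)

    def test_refuses_non_training_sources(self):
        segs = self._segments(2)
        split_of = {"src0": "train", "src1": "test"}
        with pytest.raises(ValueError, match="leakage"):
            expand_training(segs, AugmentConfig(seed=0), split_of=split_of)

    def test_include_originals_flag(self):
        segs = self._segments(2)
        out, records = expand_training(segs, AugmentConfig(seed=3), include_originals=True)
        assert len(out) == 2 * 6
        originals = [r for r in records if r["variant_index"] == -1]
        assert len(originals) == 2
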
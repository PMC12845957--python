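"""Metric suite: exact worked examples, reference cross-checks, curve oracles."""

import numpy as np
import pytest
from sklearn.metrics import f1_score, matthews_corrcoef, precision_score, recall_score

from whalesong.evaluation import (
    CLASSES,
    ConfusionMatrix,
    confusion,
    evaluate_predictions,
    roc_pr,
    summarize,
)

#: the published confusion counts of the augmented-mel compact CNN:
#: 263/270 humpback windows and 1198/1207 no-call windows correct
REPORTED_COUNTS = np.array([[263, 7], [9, 1198]])


def mann_whitney_auc(scores, y):
    """Pairwise concordance probability, the ROC-area oracle."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (greater + 0.5 * ties) / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        labels = ["humpback"] * 3 + ["no_call"] * 5
        cm = confusion(labels, labels)
        assert np.array_equal(cm.counts, [[3, 0], [0, 5]])

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(0)
        t = [CLASSES[i] for i in rng.integers(0, 2, 500)]
        p = [CLASSES[i] for i in rng.integers(0, 2, 500)]
        cm = confusion(t, p)
        for i, ti in enumerate(CLASSES):
            for j, pj in enumerate(CLASSES):
                assert cm.counts[i, j] == sum(1 for a, b in zip(t, p) if a == ti and b == pj)

    def test_reported_counts_reconstruct(self):
        t = ["humpback"] * 270 + ["no_call"] * 1207
        p = (
            ["humpback"] * 263 + ["no_call"] * 7
            + ["humpback"] * 9 + ["no_call"] * 1198
        )
        assert np.array_equal(confusion(t, p).counts, REPORTED_COUNTS)

    def test_errors(self):
        with pytest.raises(ValueError):
            confusion(["humpback"], [])
        with pytest.raises(ValueError):
            confusion(["whale?"], ["humpback"])


class TestSummarize:
    def test_published_worked_example(self):
        report = summarize(ConfusionMatrix(REPORTED_COUNTS))
        assert round(100 * report.accuracy, 2) == 98.92
        assert round(report.mcc, 2) == 0.96
        hump = report.per_class["humpback"]
        assert (round(100 * hump.precision), round(100 * hump.recall), round(100 * hump.f1)) == (97, 97, 97)
        assert round(100 * report.error_rate_humpback, 2) == 2.59
        assert round(100 * report.error_rate_nocall, 2) == 0.75

    def test_perfect_matrix(self):
        report = summarize(ConfusionMatrix(np.array([[10, 0], [0, 20]])))
        assert report.accuracy == 1.0
        assert report.mcc == 1.0

    def test_single_class_predictions_degenerate_mcc(self):
        report = summarize(ConfusionMatrix(np.array([[30, 0], [70, 0]])))
        assert report.mcc == 0.0
        assert report.mcc_degenerate

    def test_agrees_with_sklearn_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            counts = rng.integers(0, 50, size=(2, 2))
            if counts.sum() == 0 or counts.sum(axis=1).min() == 0:
                continue
            report = summarize(ConfusionMatrix(counts))
            y_true, y_pred = [], []
            for i in range(2):
                for j in range(2):
                    y_true += [i] * counts[i, j]
                    y_pred += [j] * counts[i, j]
            assert report.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-12)
            for i, name in enumerate(CLASSES):
                s = report.per_class[name]
                assert s.precision == pytest.approx(
                    precision_score(y_true, y_pred, pos_label=i, zero_division=0), abs=1e-12
                )
                assert s.recall == pytest.approx(
                    recall_score(y_true, y_pred, pos_label=i, zero_division=0), abs=1e-12
                )
                assert s.f1 == pytest.approx(
                    f1_score(y_true, y_pred, pos_label=i, zero_division=0), abs=1e-12
                )

    def test_swapping_positive_class_swaps_error_rates_only(self):
        counts = np.array([[40, 10], [5, 45]])
        a = summarize(ConfusionMatrix(counts, positive_class="humpback"))
        b = summarize(ConfusionMatrix(counts, positive_class="no_call"))
        assert a.accuracy == b.accuracy
        assert abs(a.mcc) == abs(b.mcc)
        assert a.error_rate_humpback == b.error_rate_humpback
        assert a.error_rate_nocall == b.error_rate_nocall

    def test_equal_supports_make_weighted_equal_macro(self):
        counts = np.array([[37, 13], [8, 42]])
        report = summarize(ConfusionMatrix(counts))
        assert report.weighted_avg.f1 == pytest.approx(report.macro_avg.f1, abs=1e-12)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            summarize(ConfusionMatrix(np.zeros((2, 2), dtype=int)))


class TestCurves:
    def test_perfect_separation_gives_auc_one(self):
        labels = ["humpback"] * 5 + ["no_call"] * 5
        scores = [0.9, 0.8, 0.95, 0.85, 0.99, 0.1, 0.2, 0.05, 0.3, 0.15]
        out = roc_pr(scores, labels)
        assert out["roc"]["auc"] == pytest.approx(1.0)
        assert out["pr"]["average_precision"] == pytest.approx(1.0)

    def test_auc_equals_concordance_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(10, 80))
            scores = rng.random(n)
            y = rng.integers(0, 2, n)
            if len(set(y)) < 2:
                continue
            labels = [CLASSES[0] if v == 1 else CLASSES[1] for v in y]
            auc = roc_pr(scores, labels)["roc"]["auc"]
            assert auc == pytest.approx(mann_whitney_auc(scores, y), abs=1e-9)

    def test_single_class_truth_names_missing_class(self):
        with pytest.raises(ValueError, match="humpback"):
            roc_pr([0.2, 0.4], ["no_call", "no_call"])

    def test_scores_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            roc_pr([1.2, 0.1], ["humpback", "no_call"])


class TestEvaluatePredictions:
    def test_full_report_from_probabilities(self):
        rng = np.random.default_rng(3)
        n = 50
        y = rng.integers(0, 2, n)
        p_hump = np.clip(0.8 * (y == 0) + 0.1 + 0.1 * rng.random(n), 0, 1)
        probs = np.stack([p_hump, 1 - p_hump], axis=1)
        labels = [CLASSES[i] for i in y]
        out = evaluate_predictions(labels, probs)
        assert out["confusion"].total == n
        assert out["report"].accuracy == 1.0
        assert out["report"].loss is not None

    def test_single_class_truth_skips_curves_but_reports_metrics(self):
        probs = np.array([[0.9, 0.1], [0.7, 0.3], [0.2, 0.8]])
        out = evaluate_predictions(["humpback"] * 3, probs)
        assert out["curves"] is None
        assert out["report"].accuracy == pytest.approx(2 / 3)
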
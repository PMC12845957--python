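"""Detection metrics: confusion matrix, classification report, MCC, ROC/PR.

Summary metrics are computed directly from the 2x2 confusion counts in
exact (integer / Fraction-free float) arithmetic.  Because the orientation
of "FNR" and "FPR" is ambiguous when the positive class is left implicit,
the report always carries *named* class-conditional error rates: the
fraction of true humpback windows misclassified and the fraction of true
no-call windows misclassified.  ROC and PR curves go through scikit-learn.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve

CLASSES = ("humpback", "no_call")


@dataclass
class ConfusionMatrix:
    """2x2 counts indexed (true class, predicted class) over ``classes``."""

    counts: np.ndarray
    classes: tuple[str, str] = CLASSES
    positive_class: str = "humpback"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2) or (self.counts < 0).any():
            raise ValueError("confusion matrix must be 2x2 with non-negative counts")
        if self.positive_class not in self.classes:
            raise ValueError(f"positive_class {self.positive_class!r} not in {self.classes}")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ClassScores:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass
class EvalReport:
    accuracy: float
    loss: float | None
    per_class: dict[str, ClassScores]
    macro_avg: ClassScores
    weighted_avg: ClassScores
    error_rate_humpback: float  # fraction of true humpback windows missed
    error_rate_nocall: float  # fraction of true no-call windows misflagged
    mcc: float
    mcc_degenerate: bool
    zero_division_flags: list[str]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def format_table(self) -> str:
        """Classification report with integer-percent scores, per convention."""
        lines = [f"{'Class':<16s}{'Precision %':>12s}{'Recall %':>10s}{'F1 %':>8s}{'Support':>9s}"]
        for name, s in self.per_class.items():
            lines.append(
                f"{name:<16s}{round(100 * s.precision):>12d}{round(100 * s.recall):>10d}"
                f"{round(100 * s.f1):>8d}{s.support:>9d}"
            )
        for name, s in (("macro avg", self.macro_avg), ("weighted avg", self.weighted_avg)):
            lines.append(
                f"{name:<16s}{round(100 * s.precision):>12d}{round(100 * s.recall):>10d}"
                f"{round(100 * s.f1):>8d}{s.support:>9d}"
            )
        lines.append(f"accuracy: {100 * self.accuracy:.2f}%   MCC: {self.mcc:.2f}")
        lines.append(
            f"error rate (true humpback): {100 * self.error_rate_humpback:.2f}%   "
            f"error rate (true no-call): {100 * self.error_rate_nocall:.2f}%"
        )
        return "\n".join(lines)


def confusion(true_labels, predicted_labels, classes: tuple[str, str] = CLASSES) -> ConfusionMatrix:
    """Tally a 2x2 confusion matrix from label sequences."""
    true_labels, predicted_labels = list(true_labels), list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences differ in length")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((2, 2), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"label outside alphabet {classes}: {(t, p)!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=classes)


def _prf(tp: int, fp: int, fn: int, flags: list[str], name: str) -> tuple[float, float, float]:
    if tp + fp == 0:
        flags.append(f"precision[{name}]: zero denominator")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        flags.append(f"recall[{name}]: zero denominator")
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def matthews_corrcoef_2x2(counts: np.ndarray) -> tuple[float, bool]:
    """MCC from 2x2 counts; the degenerate 0/0 case returns (0.0, True)."""
    tp, fn = int(counts[0, 0]), int(counts[0, 1])
    fp, tn = int(counts[1, 0]), int(counts[1, 1])
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0, True
    return (tp * tn - fp * fn) / math.sqrt(denom), False


def summarize(cm: ConfusionMatrix, losses: np.ndarray | None = None) -> EvalReport:
    """Full metric suite from confusion counts (loss from per-segment CEs if given)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    flags: list[str] = []
    per_class: dict[str, ClassScores] = {}
    for i, name in enumerate(cm.classes):
        tp = int(cm.counts[i, i])
        fp = int(cm.counts[1 - i, i])
        fn = int(cm.counts[i, 1 - i])
        p, r, f1 = _prf(tp, fp, fn, flags, name)
        per_class[name] = ClassScores(p, r, f1, support=int(cm.counts[i].sum()))
    supports = np.array([s.support for s in per_class.values()], dtype=float)
    scores = np.array([[s.precision, s.recall, s.f1] for s in per_class.values()])
    macro = ClassScores(*scores.mean(axis=0), support=cm.total)
    weights = supports / supports.sum()
    weighted = ClassScores(*(weights @ scores), support=cm.total)

    pos = cm.classes.index(cm.positive_class)
    neg = 1 - pos
    err_pos = cm.counts[pos, neg] / cm.counts[pos].sum() if cm.counts[pos].sum() else 0.0
    err_neg = cm.counts[neg, pos] / cm.counts[neg].sum() if cm.counts[neg].sum() else 0.0
    if cm.positive_class == "humpback":
        err_hump, err_nocall = err_pos, err_neg
    else:
        err_hump, err_nocall = err_neg, err_pos
    mcc, degenerate = matthews_corrcoef_2x2(cm.counts)
    if degenerate:
        flags.append("mcc: degenerate denominator, reported as 0")
    accuracy = float(np.trace(cm.counts)) / cm.total
    loss = float(np.mean(losses)) if losses is not None else None
    return EvalReport(
        accuracy=accuracy,
        loss=loss,
        per_class=per_class,
        macro_avg=macro,
        weighted_avg=weighted,
        error_rate_humpback=float(err_hump),
        error_rate_nocall=float(err_nocall),
        mcc=float(mcc),
        mcc_degenerate=degenerate,
        zero_division_flags=flags,
    )


def roc_pr(scores, true_labels, positive_class: str = "humpback") -> dict:
    """ROC and precision-recall curves with areas, from per-window scores.

    ``scores`` are probabilities of the positive class.  The ROC area is the
    trapezoidal area, equal to the pairwise concordance probability.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if t == positive_class else 0 for t in true_labels])
    present = set(np.unique(y))
    if present != {0, 1}:
        missing = positive_class if 1 not in present else "negative class"
        raise ValueError(f"cannot compute ROC: only one class present (missing {missing})")
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    fpr, tpr, roc_thresh = roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    precision, recall, pr_thresh = precision_recall_curve(y, scores)
    ap = float(average_precision_score(y, scores))
    return {
        "roc": {"fpr": fpr, "tpr": tpr, "thresholds": roc_thresh, "auc": auc},
        "pr": {"precision": precision, "recall": recall, "thresholds": pr_thresh, "average_precision": ap},
    }


def evaluate_predictions(true_labels, probabilities, positive_class: str = "humpback") -> dict:
    """Labels + humpback probabilities -> report, curves, decisions."""
    probabilities = np.asarray(probabilities, dtype=float)
    predicted = [CLASSES[i] for i in (probabilities[:, 0] < 0.5).astype(int)]
    cm = confusion(true_labels, predicted)
    idx = [CLASSES.index(t) for t in true_labels]
    losses = -np.log(np.clip(probabilities[np.arange(len(idx)), idx], 1e-12, None))
    report = summarize(cm, losses=losses)
    if len(set(true_labels)) == 2:
        curves = roc_pr(probabilities[:, 0], true_labels, positive_class)
    else:
        curves = None  # single-class truth: ROC/PR undefined
    return {"confusion": cm, "report": report, "curves": curves, "predicted": predicted}
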
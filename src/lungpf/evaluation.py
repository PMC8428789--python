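"""Classification metrics for three-class nodule diagnosis.

Provides the 3x3 confusion matrix (rows = truth, columns = prediction, class
order benign / early_stage / advanced_stage), per-class precision and recall
with Wilson 95% confidence intervals, overall accuracy, the generalized
(Gorodkin) multiclass Matthews correlation coefficient, one-vs-rest ROC AUC
by the rank (Mann-Whitney) statistic with half-credit ties, and the binary
collapse (benign vs malignant).  Undefined ratios (zero denominators) are
reported as ``None`` rather than raising.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata
from statsmodels.stats.proportion import proportion_confint

from .likelihood import ClassLabel

LABEL_ORDER = (ClassLabel.BENIGN, ClassLabel.EARLY_STAGE, ClassLabel.ADVANCED_STAGE)


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3x3 count matrix; rows = truth, columns = prediction."""

    counts: tuple  # 3 rows of 3 ints

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (3, 3) or np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("confusion matrix must be a 3x3 array of nonnegative integers")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)

    @property
    def total(self) -> int:
        return int(self.as_array().sum())


def _to_label(x) -> ClassLabel:
    return x if isinstance(x, ClassLabel) else ClassLabel(x)


def confusion(truth: Sequence, predicted: Sequence) -> ConfusionMatrix3:
    """Count matrix: entry [i][j] = nodules of truth class i predicted as class j."""
    if len(truth) != len(predicted):
        raise ValueError(f"length mismatch: {len(truth)} truth vs {len(predicted)} predicted labels")
    index = {label: i for i, label in enumerate(LABEL_ORDER)}
    m = np.zeros((3, 3), dtype=np.int64)
    for t, p in zip(truth, predicted):
        m[index[_to_label(t)], index[_to_label(p)]] += 1
    return ConfusionMatrix3(counts=tuple(tuple(int(v) for v in row) for row in m))


def _ratio(num: float, den: float) -> Optional[float]:
    return None if den == 0 else num / den


def wilson_interval(successes: int, total: int, confidence: float = 0.95):
    """Wilson score interval for a binomial proportion."""
    if total == 0:
        return None
    lo, hi = proportion_confint(successes, total, alpha=1 - confidence, method="wilson")
    return (float(lo), float(hi))


def per_class_metrics(cm: ConfusionMatrix3) -> dict:
    """Per-class precision/recall (+95% Wilson CIs) and overall accuracy.

    Zero denominators yield ``None`` for the affected metric.
    """
    m = cm.as_array()
    diag = np.diag(m)
    col = m.sum(axis=0)
    row = m.sum(axis=1)
    out = {"per_class": {}, "accuracy": _ratio(float(diag.sum()), float(cm.total))}
    for i, label in enumerate(LABEL_ORDER):
        out["per_class"][label.value] = {
            "precision": _ratio(float(diag[i]), float(col[i])),
            "precision_ci95": wilson_interval(int(diag[i]), int(col[i])),
            "recall": _ratio(float(diag[i]), float(row[i])),
            "recall_ci95": wilson_interval(int(diag[i]), int(row[i])),
        }
    return out


def binary_metrics_from_counts(pos_total: int, pos_correct: int, neg_total: int, neg_correct: int) -> dict:
    """Accuracy / sensitivity / specificity from raw correct counts."""
    for total, correct, side in ((pos_total, pos_correct, "positive"), (neg_total, neg_correct, "negative")):
        if correct > total:
            raise ValueError(f"{side} correct count {correct} exceeds total {total}")
        if min(total, correct) < 0:
            raise ValueError("counts must be nonnegative")
    if pos_total == 0 or neg_total == 0:
        raise ValueError("both class totals must be > 0")
    return {
        "accuracy": (pos_correct + neg_correct) / (pos_total + neg_total),
        "sensitivity": pos_correct / pos_total,
        "specificity": neg_correct / neg_total,
    }


def multiclass_mcc(cm: ConfusionMatrix3) -> Optional[float]:
    """Generalized (Gorodkin) Matthews correlation coefficient of a 3x3 matrix.

    Covariance-form numerator over the geometric mean of the truth- and
    prediction-side variance terms; returns ``None`` when either variance
    term vanishes (e.g. a single-class truth or prediction).
    """
    C = cm.as_array().astype(float)
    if cm.total == 0:
        return None
    t = C.sum(axis=1)  # truth counts
    p = C.sum(axis=0)  # prediction counts
    n = C.sum()
    cov = np.trace(C) * n - float(t @ p)
    var_t = n**2 - float(t @ t)
    var_p = n**2 - float(p @ p)
    if var_t <= 0 or var_p <= 0:
        return None
    return float(cov / math.sqrt(var_t * var_p))


def roc_auc(scores: Sequence[float], truth: Sequence[int]) -> Optional[float]:
    """Mann-Whitney AUC of ``scores`` against a binary indicator, ties half-credited."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(truth).astype(bool)
    if scores.shape != y.shape:
        raise ValueError("scores and truth must have matching lengths")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)  # average ranks: half credit for ties
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def one_vs_rest_aucs(scores: Sequence[float], truth: Sequence) -> dict:
    """Per-class one-vs-rest AUCs from the final diagnostic scores.

    The benign class scores low, so its AUC is computed on the negated score
    (lower score = more benign-like); early and advanced use the score
    directly.
    """
    labels = [_to_label(t) for t in truth]
    scores = np.asarray(scores, dtype=float)
    out = {}
    for label in LABEL_ORDER:
        ind = np.array([t == label for t in labels])
        s = -scores if label is ClassLabel.BENIGN else scores
        out[label.value] = roc_auc(s, ind)
    return out


def evaluation_report(truth: Sequence, predicted: Sequence, scores: Optional[Sequence[float]] = None) -> dict:
    """Full evaluation report: confusion, per-class metrics, MCC, AUCs, binary collapse."""
    cm = confusion(truth, predicted)
    report = {
        "n": cm.total,
        "confusion_matrix": [list(row) for row in cm.counts],
        "label_order": [label.value for label in LABEL_ORDER],
        **per_class_metrics(cm),
        "mcc": multiclass_mcc(cm),
    }
    # binary collapse: benign (negative) vs malignant (early + advanced, positive)
    labels_t = [_to_label(t) for t in truth]
    labels_p = [_to_label(p) for p in predicted]
    pos = [t is not ClassLabel.BENIGN for t in labels_t]
    pos_total = sum(pos)
    neg_total = len(pos) - pos_total
    if pos_total and neg_total:
        pos_correct = sum(
            1 for t, p, is_pos in zip(labels_t, labels_p, pos) if is_pos and p is not ClassLabel.BENIGN
        )
        neg_correct = sum(
            1 for t, p, is_pos in zip(labels_t, labels_p, pos) if not is_pos and p is ClassLabel.BENIGN
        )
        report["binary_collapse"] = binary_metrics_from_counts(
            pos_total, pos_correct, neg_total, neg_correct
        )
    else:
        report["binary_collapse"] = None
    if scores is not None:
        report["one_vs_rest_auc"] = one_vs_rest_aucs(scores, truth)
    return report


def format_report(report: dict) -> str:
    """Human-readable text rendering of :func:`evaluation_report` output."""
    lines = []
    order = report["label_order"]
    lines.append(f"n = {report['n']}")
    lines.append("confusion matrix (rows = truth, cols = predicted):")
    header = " " * 16 + "".join(f"{c:>16}" for c in order)
    lines.append(header)
    for name, row in zip(order, report["confusion_matrix"]):
        lines.append(f"{name:>16}" + "".join(f"{v:>16d}" for v in row))

    def fmt(v):
        return "undefined" if v is None else f"{v:.4f}"

    for name in order:
        pc = report["per_class"][name]
        lines.append(f"{name}: precision {fmt(pc['precision'])}  recall {fmt(pc['recall'])}")
    lines.append(f"accuracy: {fmt(report['accuracy'])}")
    lines.append(f"MCC: {fmt(report['mcc'])}")
    if report.get("one_vs_rest_auc"):
        aucs = ", ".join(f"{k}={fmt(v)}" for k, v in report["one_vs_rest_auc"].items())
        lines.append(f"one-vs-rest AUC: {aucs}")
    if report.get("binary_collapse"):
        b = report["binary_collapse"]
        lines.append(
            "binary collapse (malignant vs benign): "
            f"accuracy {fmt(b['accuracy'])}  sensitivity {fmt(b['sensitivity'])}  "
            f"specificity {fmt(b['specificity'])}"
        )
    return "\n".join(lines)


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2)
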
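"""Multiclass one-vs-rest metrics and macro averages, on the percent scale.

For each class c, the 6x6 confusion matrix collapses to a one-vs-rest
2x2 table (TP, FP, FN, TN) and yields:

    accuracy    = 100 * (TP + TN) / total        (one-vs-rest accuracy)
    precision   = 100 * TP / (TP + FP)
    recall      = 100 * TP / (TP + FN)
    specificity = 100 * TN / (TN + FP)
    f_score     = 2 * precision * recall / (precision + recall)
    mcc         = 100 * (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

MCC is scaled by 100 so every field shares the percent scale. A zero
denominator yields 0 with a warning. The macro average is the unweighted
arithmetic mean over classes; formatted output rounds half-up to two
decimals while full precision is kept internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .data import CLASS_NAMES


@dataclass
class ClassMetrics:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f_score: float
    mcc: float

    def as_dict(self, rounded: bool = False) -> dict[str, float]:
        out = {f.name: getattr(self, f.name) for f in fields(self)}
        if rounded:
            out = {k: round2(v) for k, v in out.items()}
        return out


def round2(x: float) -> float:
    """Two-decimal half-up rounding used for formatted/tabulated output.

    Values are first quantized at 1e-9 so binary float error just below a
    .xx5 boundary does not flip the half-up direction.
    """
    d = Decimal(repr(float(x))).quantize(Decimal("1e-9"), rounding=ROUND_HALF_UP)
    return float(d.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def confusion_matrix(true_labels, predicted_labels, class_order=CLASS_NAMES) -> np.ndarray:
    """Counts[t][p] over the given class order (rows true, columns predicted)."""
    order = list(class_order)
    index = {lab: i for i, lab in enumerate(order)}
    true_labels, predicted_labels = list(true_labels), list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")
    counts = np.zeros((len(order), len(order)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"label outside class order: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return counts


def _safe_ratio(num: float, den: float, context: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator in {context}; reporting 0", stacklevel=3)
        return 0.0
    return num / den


def binary_counts(matrix: np.ndarray, class_index: int) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, FP, FN, TN) for one class of a confusion matrix."""
    m = np.asarray(matrix)
    tp = int(m[class_index, class_index])
    fp = int(m[:, class_index].sum() - tp)
    fn = int(m[class_index, :].sum() - tp)
    tn = int(m.sum() - tp - fp - fn)
    return tp, fp, fn, tn


def per_class_metrics(matrix: np.ndarray) -> list[ClassMetrics]:
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = int(m.sum())
    if total == 0:
        raise ValueError("confusion matrix is empty")
    out = []
    for c in range(m.shape[0]):
        tp, fp, fn, tn = binary_counts(m, c)
        precision = 100.0 * _safe_ratio(tp, tp + fp, "precision")
        recall = 100.0 * _safe_ratio(tp, tp + fn, "recall")
        specificity = 100.0 * _safe_ratio(tn, tn + fp, "specificity")
        f_score = _safe_ratio(2.0 * precision * recall, precision + recall, "f_score")
        mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mcc = 100.0 * _safe_ratio(tp * tn - fp * fn, mcc_den, "mcc")
        out.append(
            ClassMetrics(
                accuracy=100.0 * (tp + tn) / total,
                precision=precision,
                recall=recall,
                specificity=specificity,
                f_score=f_score,
                mcc=mcc,
            )
        )
    return out


def macro_average(per_class: list[ClassMetrics]) -> ClassMetrics:
    """Unweighted arithmetic mean of each field across classes."""
    if not per_class:
        raise ValueError("no per-class metrics to average")
    return ClassMetrics(
        **{
            f.name: float(np.mean([getattr(c, f.name) for c in per_class]))
            for f in fields(ClassMetrics)
        }
    )


def metrics_report(matrix: np.ndarray, class_names=CLASS_NAMES) -> dict:
    """JSON-shaped report: per-class blocks plus the macro-average block.

    The average block also exposes ``sensitivity`` as an alias for the
    macro recall (the comparison-table name for the same quantity).
    """
    per_class = per_class_metrics(matrix)
    avg = macro_average(per_class)
    report = {
        "schema": "leafdx-metrics-1",
        "classes": {
            name: cm.as_dict(rounded=True) for name, cm in zip(class_names, per_class)
        },
        "average": avg.as_dict(rounded=True),
        "confusion_matrix": np.asarray(matrix).tolist(),
        "n_samples": int(np.asarray(matrix).sum()),
    }
    report["average"]["sensitivity"] = report["average"]["recall"]
    return report
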
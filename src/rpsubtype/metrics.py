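"""Classification metrics: confusion matrices, Acc/F1/MCC, group rollups.

Per-class metrics use the one-vs-rest decomposition:

    Acc = (TP + TN) / (TP + FP + FN + TN)
    F1  = 2 TP / (2 TP + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with the standard convention that MCC (and F1) is 0 when a denominator
factor vanishes. Aggregate F1 defaults to the support-weighted mean of
the one-vs-rest F1 values (macro is reported alongside — under heavy
class imbalance the two can differ a lot). Aggregate MCC is Gorodkin's
multiclass generalization, with the mean one-vs-rest MCC alongside.
Per-class "accuracy" in the confusion-matrix sense (diagonal over row
sum) is reported as recall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .subtypes import SubtypeScheme

__all__ = [
    "BinaryMetrics",
    "AggregateMetrics",
    "MetricsReport",
    "confusion_matrix",
    "binary_metrics",
    "per_class_counts",
    "multiclass_metrics",
    "group_metrics",
    "compute_report",
]


class BinaryMetrics(NamedTuple):
    accuracy: float
    f1: float
    mcc: float


@dataclass
class AggregateMetrics:
    accuracy: float
    f1_weighted: float
    f1_macro: float
    mcc: float
    mcc_ovr_mean: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def confusion_matrix(
    y_true: Sequence, y_pred: Sequence, class_order: Sequence[str]
) -> np.ndarray:
    """C x C integer matrix; entry (i, j) counts true class i predicted as j."""
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred differ in length")
    index = {str(c): i for i, c in enumerate(class_order)}
    C = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(y_true, y_pred):
        try:
            C[index[str(t)], index[str(p)]] += 1
        except KeyError as exc:
            raise ValueError(f"label {exc.args[0]!r} not in class_order") from None
    return C


def binary_metrics(TP: int, FP: int, TN: int, FN: int) -> BinaryMetrics:
    """Accuracy, F1 and MCC from one-vs-rest counts."""
    counts = (TP, FP, TN, FN)
    if any(c < 0 for c in counts):
        raise ValueError("negative counts")
    n = sum(counts)
    if n == 0:
        raise ValueError("all counts are zero")
    acc = (TP + TN) / n
    f1_den = 2 * TP + FP + FN
    f1 = 2 * TP / f1_den if f1_den > 0 else 0.0
    rad = (TP + FP) * (TP + FN) * (TN + FP) * (TN + FN)
    mcc = (TP * TN - FP * FN) / math.sqrt(rad) if rad > 0 else 0.0
    return BinaryMetrics(acc, f1, mcc)


def per_class_counts(confusion: np.ndarray) -> list[dict]:
    """One-vs-rest TP/FP/TN/FN (plus recall and binary metrics) per class."""
    confusion = np.asarray(confusion)
    n = int(confusion.sum())
    out = []
    for i in range(confusion.shape[0]):
        tp = int(confusion[i, i])
        fn = int(confusion[i].sum() - tp)
        fp = int(confusion[:, i].sum() - tp)
        tn = n - tp - fn - fp
        support = tp + fn
        entry = {"TP": tp, "FP": fp, "TN": tn, "FN": fn, "support": support}
        entry["recall"] = tp / support if support else 0.0
        prec_den = tp + fp
        entry["precision"] = tp / prec_den if prec_den else 0.0
        bm = binary_metrics(tp, fp, tn, fn)
        entry.update(accuracy=bm.accuracy, f1=bm.f1, mcc=bm.mcc)
        out.append(entry)
    return out


def multiclass_metrics(confusion: np.ndarray) -> AggregateMetrics:
    """Aggregate accuracy, F1 (weighted + macro) and MCC (Gorodkin + OvR mean)."""
    confusion = np.asarray(confusion, dtype=float)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1] or confusion.size == 0:
        raise ValueError("confusion must be a nonempty square matrix")
    n = confusion.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    acc = float(np.trace(confusion) / n)

    per_class = per_class_counts(confusion.astype(int))
    supports = np.array([pc["support"] for pc in per_class], dtype=float)
    f1s = np.array([pc["f1"] for pc in per_class])
    mccs = np.array([pc["mcc"] for pc in per_class])
    present = supports > 0
    f1_weighted = float(np.average(f1s[present], weights=supports[present]))
    f1_macro = float(f1s[present].mean())
    mcc_ovr = float(mccs[present].mean())

    # Gorodkin multiclass MCC from row/column marginals.
    t = confusion.sum(axis=1)  # true-class counts
    p = confusion.sum(axis=0)  # predicted-class counts
    c = np.trace(confusion)
    num = c * n - float(t @ p)
    den = math.sqrt(n**2 - float(p @ p)) * math.sqrt(n**2 - float(t @ t))
    mcc = num / den if den > 0 else 0.0
    return AggregateMetrics(acc, f1_weighted, f1_macro, float(mcc), mcc_ovr)


def group_metrics(
    confusion: np.ndarray,
    class_order: Sequence[str],
    scheme: SubtypeScheme,
) -> dict[str, AggregateMetrics]:
    """Aggregate metrics per subtype group.

    For each group the confusion matrix is restricted to the rows of the
    group's member classes (its true-label samples); predictions into any
    class — inside or outside the group — are kept, so a sample predicted
    outside its group still counts as that class's error.
    """
    class_order = [str(c) for c in class_order]
    missing = [c for c in class_order if c not in scheme.group_map]
    if missing:
        raise ValueError(f"classes without a group: {missing}")
    confusion = np.asarray(confusion)
    out: dict[str, AggregateMetrics] = {}
    for group in scheme.groups:
        rows = [i for i, c in enumerate(class_order) if scheme.group_map[c] == group]
        if not rows:
            continue
        sub = np.zeros_like(confusion)
        sub[rows] = confusion[rows]
        if sub.sum() == 0:
            continue
        out[group] = multiclass_metrics(sub)
    return out


@dataclass
class MetricsReport:
    """Confusion matrix with per-class, aggregate and group-level metrics."""

    class_order: list[str]
    confusion: np.ndarray = field(repr=False)
    per_class: dict[str, dict] = field(repr=False)
    aggregate: AggregateMetrics
    group: dict[str, AggregateMetrics] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "class_order": self.class_order,
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class,
            "aggregate": self.aggregate.to_dict(),
            "group": {g: m.to_dict() for g, m in self.group.items()},
        }


def compute_report(
    y_true: Sequence,
    y_pred: Sequence,
    class_order: Sequence[str],
    scheme: SubtypeScheme | None = None,
) -> MetricsReport:
    """Full evaluation report for one set of predictions."""
    conf = confusion_matrix(y_true, y_pred, class_order)
    per_class = {
        str(c): pc for c, pc in zip(class_order, per_class_counts(conf))
    }
    agg = multiclass_metrics(conf)
    group = group_metrics(conf, class_order, scheme) if scheme is not None else {}
    return MetricsReport(
        class_order=[str(c) for c in class_order],
        confusion=conf,
        per_class=per_class,
        aggregate=agg,
        group=group,
    )
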
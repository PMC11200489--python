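"""Confusion matrix and per-class precision / recall / F1 reporting.

For each rhythm class s: tp = C[s][s], fn = row sum − tp, fp = column sum −
tp, tn = total − tp − fp − fn, and

    recall = tp / (tp + fn),   precision = tp / (tp + fp),
    F1 = 2 · precision · recall / (precision + recall).

Percentages are reported to 2 decimals and F1 to 4, rounded half-up; the
macro average is the unweighted mean over the 9 classes of the unrounded
values, rounded last. A class with no predicted (or no true) instances gets 0
for the undefined rate and is flagged in ``undefined``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .core import CLASS_NAMES


def _round(x: float, places: int) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(f"1e-{places}"), ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """9×9 counts, C[i][j] = beats of true class i predicted as class j."""

    C: np.ndarray
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=np.int64)
        k = len(self.class_names)
        if self.C.shape != (k, k):
            raise ValueError(f"confusion matrix must be {k}×{k}, got {self.C.shape}")
        if np.any(self.C < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.C.sum())


@dataclass
class ClassMetrics:
    """Per-class and macro-averaged scores (percent scale for P/R)."""

    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    counts: dict[str, dict[str, int]]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "per_class": {
                c: {
                    "precision_pct": self.precision[c],
                    "recall_pct": self.recall[c],
                    "f1": self.f1[c],
                    **self.counts[c],
                }
                for c in self.precision
            },
            "average": {
                "precision_pct": self.macro_precision,
                "recall_pct": self.macro_recall,
                "f1": self.macro_f1,
            },
            "undefined": self.undefined,
        }


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Exact counts in the fixed 9-class order; empty input → zero matrix."""
    t = np.asarray(true_labels, dtype="U8")
    p = np.asarray(predicted_labels, dtype="U8")
    if t.shape != p.shape:
        raise ValueError("true and predicted label lists differ in length")
    bad = (set(t) | set(p)) - set(CLASS_NAMES)
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    if t.size == 0:
        return ConfusionMatrix(np.zeros((9, 9), dtype=np.int64))
    return ConfusionMatrix(_sk_confusion(t, p, labels=list(CLASS_NAMES)))


def score(cm: ConfusionMatrix) -> ClassMetrics:
    """Precision/recall (%, 2 dp) and F1 (4 dp) per class plus macro averages."""
    C = cm.C
    if cm.total == 0:
        raise ValueError("cannot score an all-zero confusion matrix")
    names = cm.class_names
    prec, rec, f1, counts = {}, {}, {}, {}
    undefined: list[str] = []
    p_raw, r_raw, f_raw = [], [], []
    for s, name in enumerate(names):
        tp = int(C[s, s])
        fn = int(C[s].sum() - tp)
        fp = int(C[:, s].sum() - tp)
        tn = cm.total - tp - fn - fp
        if tp + fp == 0 or tp + fn == 0:
            undefined.append(name)
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        p_raw.append(p); r_raw.append(r); f_raw.append(f)
        prec[name] = _round(100 * p, 2)
        rec[name] = _round(100 * r, 2)
        f1[name] = _round(f, 4)
        counts[name] = dict(tp=tp, fp=fp, fn=fn, tn=tn)
    return ClassMetrics(
        precision=prec,
        recall=rec,
        f1=f1,
        counts=counts,
        macro_precision=_round(100 * float(np.mean(p_raw)), 2),
        macro_recall=_round(100 * float(np.mean(r_raw)), 2),
        macro_f1=_round(float(np.mean(f_raw)), 4),
        undefined=undefined,
    )
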
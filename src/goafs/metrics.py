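"""Binary-classification evaluation suite.

Confusion-count bookkeeping plus the error measures used throughout the
package: MAE, RMSE, accuracy (both the error-complement form
1 − MAE and the count form (TP+TN)/n, which coincide for binary
labels), error rate, precision, recall and F1.

Zero-denominator ratios (precision with no positive predictions, recall
with no positive truths) are reported as ``None`` — an explicit
undefined marker — never as silent zeros, so they cannot corrupt
averages downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["ConfusionCounts", "EvalReport", "confusion", "report"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _as_binary(actual: Sequence[int], predicted: Sequence[int],
               positive_label: int) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(actual)
    p = np.asarray(predicted)
    if a.shape != p.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("actual and predicted must be equal-length 1-d vectors")
    labels = set(np.unique(a)) | set(np.unique(p))
    if len(labels - {positive_label}) > 1:
        raise ValueError(f"labels are not binary: {sorted(labels)}")
    return (a == positive_label).astype(int), (p == positive_label).astype(int)


def confusion(actual: Sequence[int], predicted: Sequence[int],
              positive_label: int = 1) -> ConfusionCounts:
    """Tally TP/FP/TN/FN with the standard conventions.

    TP: actual positive predicted positive; FP: actual negative
    predicted positive; FN: actual positive predicted negative;
    TN: actual negative predicted negative.
    """
    a, p = _as_binary(actual, predicted, positive_label)
    return ConfusionCounts(
        tp=int(((a == 1) & (p == 1)).sum()),
        fp=int(((a == 0) & (p == 1)).sum()),
        tn=int(((a == 0) & (p == 0)).sum()),
        fn=int(((a == 1) & (p == 0)).sum()),
    )


@dataclass(frozen=True)
class EvalReport:
    """All metrics for one (actual, predicted) pair.

    ``accuracy`` is (TP+TN)/n; ``accuracy_from_error`` is 1 − MAE; for
    binary labels the two are identical and both are reported so the
    identity is checkable.  ``precision``/``recall``/``f1`` are ``None``
    when their denominators vanish.
    """

    confusion: ConfusionCounts
    accuracy: float
    error_rate: float
    precision: float | None
    recall: float | None
    f1: float | None
    mae: float
    rmse: float
    accuracy_from_error: float
    n: int

    def to_dict(self) -> dict:
        return {
            "tp": self.confusion.tp,
            "fp": self.confusion.fp,
            "tn": self.confusion.tn,
            "fn": self.confusion.fn,
            "accuracy": self.accuracy,
            "error_rate": self.error_rate,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mae": self.mae,
            "rmse": self.rmse,
            "accuracy_from_error": self.accuracy_from_error,
            "n": self.n,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def report(actual: Sequence[int], predicted: Sequence[int],
           positive_label: int = 1) -> EvalReport:
    """Compute the full metric suite for one prediction vector."""
    a, p = _as_binary(actual, predicted, positive_label)
    c = confusion(actual, predicted, positive_label)
    n = c.n
    diff = np.abs(a - p)
    mae = float(diff.mean())
    rmse = float(math.sqrt((diff.astype(float) ** 2).mean()))
    accuracy = (c.tp + c.tn) / n
    # defined as (FN+FP)/n; computed as the exact complement so the
    # identity error_rate == 1 - accuracy holds bit-for-bit
    error_rate = 1.0 - accuracy
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return EvalReport(
        confusion=c,
        accuracy=accuracy,
        error_rate=error_rate,
        precision=precision,
        recall=recall,
        f1=f1,
        mae=mae,
        rmse=rmse,
        accuracy_from_error=1.0 - mae,
        n=n,
    )
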
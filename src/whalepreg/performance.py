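"""Thresholded classification and confusion-matrix evaluation.

A whale-year is classified pregnant when its assigned probability is at
least the 75% threshold.  Performance is evaluated against whales of
known reproductive status: confirmed-pregnant females (PF) are the
positives and presumed non-pregnant females (lactating LF and juvenile
JF) the negatives; mature females of unknown status (MF) are excluded
from evaluation because their truth is unknown.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

DEFAULT_THRESHOLD = 0.75

__all__ = [
    "ConfusionCounts",
    "PerformanceMetrics",
    "classify",
    "evaluate",
    "render_table",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class PerformanceMetrics:
    """The six rates, as unrounded percentages."""

    accuracy: float
    misclassification: float
    tpr: float
    fnr: float
    tnr: float
    fpr: float

    def rounded(self) -> dict:
        """Whole-percent rates, rounded half away from zero (74 from 73.9)."""
        return {k: _round_half_away(v) for k, v in self.__dict__.items()}

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in self.__dict__.items()}


def _round_half_away(x: float):
    if math.isnan(x):
        return float("nan")
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def classify(prob, threshold: float = DEFAULT_THRESHOLD):
    """'pregnant' iff probability >= threshold (inclusive boundary)."""
    p = np.asarray(prob, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    out = np.where(p >= threshold, "pregnant", "not_pregnant")
    return out.item() if np.isscalar(prob) or p.ndim == 0 else out


def evaluate(pred_pregnant, truth_pregnant) -> tuple[ConfusionCounts, PerformanceMetrics]:
    """Confusion counts and rates from boolean predictions and truth.

    ``truth_pregnant`` must cover only known-status records (PF positive,
    LF/JF negative); callers exclude MF before evaluating.
    """
    pred = np.asarray(pred_pregnant, dtype=bool)
    truth = np.asarray(truth_pregnant, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("predictions and truth differ in length")
    if pred.size == 0:
        raise ValueError("empty truth set")
    counts = ConfusionCounts(
        tp=int((pred & truth).sum()),
        tn=int((~pred & ~truth).sum()),
        fp=int((pred & ~truth).sum()),
        fn=int((~pred & truth).sum()),
    )
    pos = counts.positives
    neg = counts.negatives
    metrics = PerformanceMetrics(
        accuracy=100.0 * (counts.tp + counts.tn) / counts.total,
        misclassification=100.0 * (counts.fn + counts.fp) / counts.total,
        tpr=100.0 * counts.tp / pos if pos else float("nan"),
        fnr=100.0 * counts.fn / pos if pos else float("nan"),
        tnr=100.0 * counts.tn / neg if neg else float("nan"),
        fpr=100.0 * counts.fp / neg if neg else float("nan"),
    )
    return counts, metrics


_ROWS = (
    ("accuracy", "(TP + TN)/Tot"),
    ("misclassification", "(FN + FP)/Tot"),
    ("tpr", "TP/(TP + FN)"),
    ("fnr", "FN/(FN + TP)"),
    ("tnr", "TN/(TN + FP)"),
    ("fpr", "FP/(FP + TN)"),
)

_LABELS = {
    "accuracy": "accuracy",
    "misclassification": "misclassification rate",
    "tpr": "true (+) rate",
    "fnr": "false (-) rate",
    "tnr": "true (-) rate",
    "fpr": "false (+) rate",
}


def render_table(results: dict) -> str:
    """Plain-text performance table across models.

    ``results`` maps a model label to (ConfusionCounts, PerformanceMetrics).
    """
    labels = list(results)
    width = max(len(_LABELS[k]) for k, _ in _ROWS) + 2
    head = "performance".ljust(width) + "".join(f"{m:>10}" for m in labels) + "  formula"
    lines = [head, "-" * len(head)]
    for key, formula in _ROWS:
        cells = "".join(f"{results[m][1].rounded()[key]:>9}%" for m in labels)
        lines.append(_LABELS[key].ljust(width) + cells + f"  {formula}")
    for name, attr in (
        ("presumed pregnant", "positives"),
        ("presumed non-pregnant", "negatives"),
        ("total", "total"),
    ):
        cells = "".join(f"{getattr(results[m][0], attr):>10}" for m in labels)
        lines.append(name.ljust(width) + cells)
    return "\n".join(lines)
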
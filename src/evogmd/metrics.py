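"""Confusion-matrix metrics and multi-run summaries.

The positive class is melanoma (label 1) throughout.  Zero-denominator
conventions: precision, recall and F1 are reported as 0 when undefined, which
is what a majority-collapsed model (constant benign prediction) scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "RunSummary",
    "confusion_counts",
    "compute_metrics",
    "evaluate_predictions",
    "summarize_runs",
    "pick_representatives",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    collapsed: bool = False  # all predictions identical (trivial classifier)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "collapsed": self.collapsed,
        }


@dataclass(frozen=True)
class RunSummary:
    """Five-number descriptive statistics of per-run final fitness values;
    the standard deviation uses the sample (n-1) convention."""

    minimum: float
    maximum: float
    mean: float
    median: float
    std: float
    n_runs: int

    def to_dict(self) -> dict:
        return {
            "min": self.minimum,
            "max": self.maximum,
            "mean": self.mean,
            "median": self.median,
            "std": self.std,
            "n_runs": self.n_runs,
            "std_convention": "sample (n-1)",
        }


def confusion_counts(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D sequences of equal length")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} contains non-binary labels")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
    )


def compute_metrics(c: ConfusionCounts, collapsed: bool = False) -> MetricsReport:
    if c.total == 0:
        raise ValueError("no evaluated samples")
    accuracy = (c.tp + c.tn) / c.total
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return MetricsReport(accuracy=accuracy, precision=precision, recall=recall,
                         f1=f1, collapsed=collapsed)


def evaluate_predictions(y_true: Sequence[int], y_pred: Sequence[int]) -> MetricsReport:
    """Counts + metrics in one step, flagging constant-prediction collapse."""
    counts = confusion_counts(y_true, y_pred)
    collapsed = len(np.unique(np.asarray(y_pred))) == 1
    return compute_metrics(counts, collapsed=collapsed)


def summarize_runs(final_fitnesses: Sequence[float]) -> RunSummary:
    values = np.asarray(final_fitnesses, dtype=float)
    if values.size == 0:
        raise ValueError("no run results to summarize")
    std = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return RunSummary(
        minimum=float(values.min()),
        maximum=float(values.max()),
        mean=float(values.mean()),
        median=float(np.median(values)),
        std=std,
        n_runs=int(values.size),
    )


def pick_representatives(runs: Sequence) -> tuple:
    """Select (best, median, worst) runs by final fitness.

    Runs are sorted by (final best fitness, seed) ascending; the median is the
    ceil(R/2)-th order statistic.  Each run must expose ``best_fitness`` and
    ``seed`` (see :class:`evogmd.de.OptimizationResult`).
    """
    if len(runs) == 0:
        raise ValueError("no runs")
    ordered = sorted(runs, key=lambda r: (r.best_fitness, r.seed))
    mid = math.ceil(len(ordered) / 2) - 1
    return ordered[0], ordered[mid], ordered[-1]
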
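"""Binary classification performance measurement.

Scalar measures from the confusion counts (TP, FP, TN, FN):

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    F1        = 2 * precision * recall / (precision + recall)
              = 2 * TP / (2 * TP + FN + FP)
    MCC       = (TP * TN - FP * FN) /
                sqrt((TN + FN)(TN + FP)(TP + FN)(TP + FP))

Zero-division policy: precision, recall and F1 return 0 when their denominator
is 0; MCC returns 0 when any factor under the root is 0.  This keeps reports
total on degenerate predictions.

Threshold-free evaluation sweeps thresholds over the distinct predicted
scores (plus a +inf sentinel): at each threshold the true-positive rate
(TPR = recall) and false-positive rate FPR = FP / (TN + FP) give one ROC
point, and precision/recall give one PR point.  Areas are trapezoidal.  The
ROC curve runs from (0, 0) to (1, 1); the PR curve is anchored at recall = 0
with the first attainable precision rather than an extrapolated 1.0 (recorded
in report metadata, since toolkit conventions differ here).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ScalarMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionCounts:
    """Exact confusion counts from binary labels and binary predictions."""
    y = np.asarray(labels, dtype=np.int8)
    p = np.asarray(predictions, dtype=np.int8)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} predictions")
    if y.size == 0:
        raise ValueError("empty label vector")
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def scalar_metrics(counts: ConfusionCounts) -> ScalarMetrics:
    """The five scalar measures from confusion counts."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    accuracy = (tp + tn) / counts.total if counts.total else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = f1_from_precision_recall(precision, recall)
    denom = (tn + fn) * (tn + fp) * (tp + fn) * (tp + fp)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return ScalarMetrics(
        accuracy=accuracy, precision=precision, recall=recall, f1=f1, mcc=float(mcc)
    )


def roc_pr_curves(
    labels: Sequence[int], scores: Sequence[float]
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Threshold sweep over distinct scores.

    Returns
    -------
    roc : array of (threshold, fpr, tpr) rows, from (inf, 0, 0) to (min, 1, 1)
    pr : array of (threshold, recall, precision) rows, anchored at recall 0
    auroc, aupr : trapezoidal areas under the two curves
    """
    y = np.asarray(labels, dtype=np.int8)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to sweep thresholds")

    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    cum_tp = np.cumsum(y_sorted == 1)
    cum_fp = np.cumsum(y_sorted == 0)
    # one operating point per distinct score: last position of each tie group
    last = np.flatnonzero(np.r_[np.diff(s_sorted) != 0, True])
    thresholds = s_sorted[last]
    tp = cum_tp[last]
    fp = cum_fp[last]

    tpr = tp / n_pos
    fpr = fp / n_neg
    precision = tp / (tp + fp)

    roc = np.column_stack(
        (np.r_[np.inf, thresholds], np.r_[0.0, fpr], np.r_[0.0, tpr])
    )
    pr = np.column_stack(
        (np.r_[np.inf, thresholds], np.r_[0.0, tpr], np.r_[precision[0], precision])
    )
    auroc = float(np.trapezoid(roc[:, 2], roc[:, 1]))
    aupr = float(np.trapezoid(pr[:, 2], pr[:, 1]))
    return roc, pr, auroc, aupr


@dataclass
class MetricsReport:
    """Full evaluation of one set of predictions: counts, the five scalar
    measures, both curves and their areas."""

    counts: ConfusionCounts
    scalars: ScalarMetrics
    roc: np.ndarray = field(repr=False)
    pr: np.ndarray = field(repr=False)
    auroc: float = 0.0
    aupr: float = 0.0
    metadata: dict = field(default_factory=dict)

    def to_dict(self, include_curves: bool = True) -> dict:
        out = {
            "counts": asdict(self.counts),
            **asdict(self.scalars),
            "auroc": self.auroc,
            "aupr": self.aupr,
            "metadata": self.metadata,
        }
        if include_curves:
            out["roc"] = self.roc.tolist()
            out["pr"] = self.pr.tolist()
        return out

    def to_json(self, path, include_curves: bool = True) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(include_curves=include_curves), fh, indent=1)

    def scalar_row(self) -> dict:
        """Flat row of the headline numbers, for summary tables."""
        return {**asdict(self.scalars), "auroc": self.auroc, "aupr": self.aupr,
                "n": self.counts.total}


def evaluate_predictions(
    labels: Sequence[int],
    scores: Sequence[float],
    threshold: float = 0.5,
    metadata: dict | None = None,
) -> MetricsReport:
    """Score probabilistic predictions against binary labels.

    Scalar measures use class labels obtained by thresholding the scores at
    ``threshold`` (default 0.5); curves and areas sweep all thresholds.
    """
    y = np.asarray(labels, dtype=np.int8)
    s = np.asarray(scores, dtype=float)
    counts = confusion(y, (s >= threshold).astype(np.int8))
    roc, pr, auroc, aupr = roc_pr_curves(y, s)
    meta = {"threshold": threshold, "pr_anchor": "first attainable precision at recall 0"}
    meta.update(metadata or {})
    return MetricsReport(
        counts=counts,
        scalars=scalar_metrics(counts),
        roc=roc,
        pr=pr,
        auroc=auroc,
        aupr=aupr,
        metadata=meta,
    )
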
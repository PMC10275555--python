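"""Classification metrics: confusion-matrix rates, pairwise AUC, ROC, k-fold.

Accuracy, sensitivity (true-positive rate) and specificity (true-negative
rate) are the standard confusion-matrix ratios.  The area under the ROC
curve is computed as the Mann-Whitney pairwise statistic,

    A_z = (1 / (n_pos * n_neg)) * sum_v sum_nv I(s_v > s_nv),

the fraction of positive/negative score pairs ranked correctly, with ties
counted one half; it equals the trapezoidal area under the empirical ROC
curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from ._exceptions import UndefinedMetricError, ValidationError

__all__ = [
    "ConfusionMatrix",
    "ROCResult",
    "confusion_metrics",
    "auc_pairwise",
    "roc_curve",
    "stratified_kfold",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        if self.total == 0:
            raise UndefinedMetricError("accuracy undefined with no samples")
        return (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            raise UndefinedMetricError("sensitivity undefined: no positive samples")
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        if self.tn + self.fp == 0:
            raise UndefinedMetricError("specificity undefined: no negative samples")
        return self.tn / (self.tn + self.fp)


def _to_pm1(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    values = set(np.unique(labels).tolist())
    if values.issubset({0, 1}):
        return np.where(labels == 1, 1, -1)
    if values.issubset({-1, 1}):
        return labels.astype(int)
    raise ValidationError(f"labels must be in {{-1,+1}} or {{0,1}}, got {sorted(values)}")


def confusion_metrics(
    y_true: np.ndarray, y_pred: np.ndarray
) -> tuple[ConfusionMatrix, float, float, float]:
    """Confusion matrix plus (accuracy, sensitivity, specificity).

    Raises :class:`UndefinedMetricError` when a rate's denominator is zero
    (a class absent from ``y_true``) rather than silently returning 0.
    """
    y_true = _to_pm1(y_true)
    y_pred = _to_pm1(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValidationError("y_true and y_pred must be equal-length, non-empty")
    cm = ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == -1) & (y_pred == -1))),
        fp=int(np.sum((y_true == -1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == -1))),
    )
    return cm, cm.accuracy, cm.sensitivity, cm.specificity


def auc_pairwise(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Mann-Whitney AUC: fraction of (positive, negative) score pairs with
    the positive ranked higher; ties count 0.5."""
    pos = np.asarray(scores_pos, dtype=np.float64)
    neg = np.asarray(scores_neg, dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both score sets must be non-empty")
    diff = pos[:, None] - neg[None, :]
    wins = np.count_nonzero(diff > 0) + 0.5 * np.count_nonzero(diff == 0)
    return float(wins / (pos.size * neg.size))


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    az: float

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("threshold\tfpr\ttpr\n")
            for t, f, s in zip(self.thresholds, self.fpr, self.tpr):
                fh.write(f"{t!r}\t{f!r}\t{s!r}\n")

    def plot(self, ax=None):
        """Draw the ROC curve (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.fpr, self.tpr, label=f"A_z = {self.az:.3f}")
        ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        return ax


def roc_curve(y_true: np.ndarray, scores: np.ndarray) -> ROCResult:
    """Threshold sweep over decision values, with the pairwise-indicator
    area attached."""
    y = _to_pm1(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    if np.unique(y).size < 2:
        raise ValidationError("ROC needs both classes present")
    fpr, tpr, thresholds = _sk_roc_curve(y, scores)
    az = auc_pairwise(scores[y == 1], scores[y == -1])
    return ROCResult(thresholds=thresholds, fpr=fpr, tpr=tpr, az=az)


def stratified_kfold(labels: np.ndarray, k: int = 10, seed: int = 0) -> np.ndarray:
    """Assign each sample to one of ``k`` stratified folds.

    Folds are size-balanced within one sample and preserve class
    proportions; the assignment is deterministic per seed.  Returns an
    integer array of fold indices aligned with ``labels``.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValidationError("k must be >= 2")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValidationError(
            f"smallest class has {counts.min()} members; cannot stratify into {k} folds"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(labels.shape[0], dtype=np.int64)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros_like(labels), labels)):
        assignment[test_idx] = fold
    return assignment
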
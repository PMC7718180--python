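"""Diagnostic test measures: accuracy, F1, ROC-AUC, posterior binarization.

Accuracy is (TP + TN)/N and F1 the harmonic mean of precision TP/(TP + FP)
and recall TP/(TP + FN), with the convention F1 = 0 when TP = 0.  Posterior
probabilities of stroke are binarized at a strict 0.5 threshold, i.e.
p(stroke | features) > 0.5 decides stroke.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve


class UndefinedAUCError(ValueError):
    """AUC is undefined when only one class is present."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion-matrix cell counts for a binary stroke/no-stroke decision."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, int)
        y_pred = np.asarray(y_pred, int)
        if y_true.shape != y_pred.shape:
            raise ValueError("label/prediction length mismatch")
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / N."""
    if c.n == 0:
        raise ValueError("accuracy undefined for N = 0")
    return (c.tp + c.tn) / c.n


def f1_score(c: ConfusionCounts) -> float:
    """2·precision·recall / (precision + recall); 0 when TP = 0."""
    if c.n == 0:
        raise ValueError("F1 undefined for N = 0")
    if c.tp == 0:
        return 0.0
    precision = c.tp / (c.tp + c.fp)
    recall = c.tp / (c.tp + c.fn)
    return 2 * precision * recall / (precision + recall)


def roc_auc(posteriors, labels) -> float:
    """Trapezoidal ROC-AUC over all distinct thresholds; ties count ½.

    Equals the probability that a random stroke patient scores above a random
    non-stroke patient, plus half the tie probability.
    """
    labels = np.asarray(labels, int)
    posteriors = np.asarray(posteriors, float)
    if len(set(labels.tolist())) < 2:
        raise UndefinedAUCError("both classes are required to compute an AUC")
    return float(roc_auc_score(labels, posteriors))


def roc_points(scores, labels):
    """(fpr, tpr, thresholds) of the ROC curve over all distinct cutoffs."""
    labels = np.asarray(labels, int)
    if len(set(labels.tolist())) < 2:
        raise UndefinedAUCError("both classes are required to compute a ROC curve")
    fpr, tpr, thr = roc_curve(labels, np.asarray(scores, float))
    return fpr, tpr, thr


def binarize(posterior: float) -> int:
    """1 (stroke) iff posterior > 0.5, strictly; 0 otherwise."""
    p = np.asarray(posterior, float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("posterior probabilities must lie in [0, 1]")
    out = (p > 0.5).astype(int)
    return int(out) if out.ndim == 0 else out
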
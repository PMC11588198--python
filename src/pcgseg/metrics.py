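"""Evaluation measures for the murmur and outcome tasks.

The murmur task is a three-class problem (present / unknown / absent)
scored with a weighted accuracy that counts each murmur-present patient
five times and each unknown three times, reflecting the clinical cost of a
missed murmur.  Binary murmur detection is scored with ROC analysis of the
continuous murmur likelihood C(M-N), and screening operating points with
Youden's index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

MURMUR_CLASSES = ("present", "unknown", "absent")
#: per-true-class weights for the weighted accuracy
CLASS_WEIGHTS = {"present": 5.0, "unknown": 3.0, "absent": 1.0}


@dataclass
class MurmurConfusion:
    """3x3 counts: rows = predicted class, columns = true class."""

    counts: np.ndarray  # (3, 3), order MURMUR_CLASSES

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3) or (self.counts < 0).any():
            raise ValueError("confusion matrix must be 3x3 with non-negative counts")

    @classmethod
    def from_labels(cls, predicted, true) -> "MurmurConfusion":
        idx = {c: i for i, c in enumerate(MURMUR_CLASSES)}
        counts = np.zeros((3, 3), dtype=np.int64)
        for p, t in zip(predicted, true, strict=True):
            counts[idx[p], idx[t]] += 1
        return cls(counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def weighted_accuracy(cm: MurmurConfusion,
                      weights: dict = CLASS_WEIGHTS) -> float:
    """Challenge-style weighted accuracy: correct counts weighted per true class."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    w = np.array([weights[c] for c in MURMUR_CLASSES])
    correct = np.diag(cm.counts)
    per_true = cm.counts.sum(axis=0)
    return float((w * correct).sum() / (w * per_true).sum())


def per_class_stats(cm: MurmurConfusion) -> dict:
    """Sensitivity, PPV and F1 per class, plus macro F1 and micro accuracy.

    A class with no true (or no predicted) examples has undefined
    sensitivity (or PPV); undefined F1 values are excluded from the macro
    average with a warning rather than treated as zero.
    """
    correct = np.diag(cm.counts).astype(float)
    n_true = cm.counts.sum(axis=0).astype(float)
    n_pred = cm.counts.sum(axis=1).astype(float)
    out: dict = {}
    f1s = []
    for i, c in enumerate(MURMUR_CLASSES):
        sens = correct[i] / n_true[i] if n_true[i] > 0 else None
        ppv = correct[i] / n_pred[i] if n_pred[i] > 0 else None
        if sens is not None and ppv is not None and (sens + ppv) > 0:
            f1 = 2 * sens * ppv / (sens + ppv)
        else:
            f1 = None
            warnings.warn(f"F1 undefined for class {c!r}; excluded from macro average")
        out[c] = {"sensitivity": sens, "ppv": ppv, "f1": f1, "n": int(n_true[i])}
        if f1 is not None:
            f1s.append(f1)
    out["macro_f1"] = float(np.mean(f1s)) if f1s else None
    out["micro_accuracy"] = float(correct.sum() / cm.total)
    return out


def roc_curve(scores, labels, n_bootstrap: int = 0, seed: int = 0):
    """ROC over the unique score thresholds (positive call when score >= thr).

    Returns ``(sens, spec, auc)`` and, when ``n_bootstrap`` > 0, a percentile
    95% CI on the AUC from seeded bootstrap resampling.  Patients without a
    definite murmur label should be removed before calling.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if labels.min() == labels.max():
        raise ValueError("need both classes for a ROC curve")
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    pos, neg = labels == 1, labels == 0
    sens = np.array([(scores[pos] >= t).mean() for t in thresholds])
    spec = np.array([(scores[neg] < t).mean() for t in thresholds])
    fpr = 1 - spec
    auc = float(np.trapezoid(sens, fpr))
    if n_bootstrap <= 0:
        return sens, spec, auc
    rng = np.random.default_rng(seed)
    n = len(scores)
    boot = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        if labels[idx].min() == labels[idx].max():
            continue
        boot.append(roc_curve(scores[idx], labels[idx])[2])
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    return sens, spec, auc, ci


def auroc(scores, labels) -> float:
    """Area under the ROC curve (threshold-sweep + trapezoid)."""
    return roc_curve(scores, labels)[2]


def youden(sensitivity: float, specificity: float) -> float:
    """Youden's J: sensitivity + specificity - 1."""
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity and specificity must be fractions")
    return sensitivity + specificity - 1.0


def reliability_bins(scores, labels, n_bins: int = 10):
    """Equal-width calibration bins: (mean score, murmur frequency) per bin.

    Empty bins are omitted.  A well-calibrated murmur likelihood gives an
    approximately monotone, linear relationship.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    edges = np.linspace(scores.min(), scores.max(), n_bins + 1)
    edges[-1] += 1e-12
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (scores >= lo) & (scores < hi)
        if mask.any():
            out.append((float(scores[mask].mean()), float(labels[mask].mean())))
    return out
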
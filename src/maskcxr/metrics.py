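"""Evaluation metrics: per-class AUROC and ROC curves, operating-threshold
selection, macro and count-weighted averaging, relative improvement.

AUROC follows the rank (Mann-Whitney) formulation — the probability that a
random positive outranks a random negative, ties counted one half — which
equals the trapezoidal area under the ROC curve.  Two aggregators are
provided because benchmark reports use both: the unweighted *macro* mean of a
per-class metric, and the count-weighted mean (e.g. box-count-weighted mean
IoU over the annotated classes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auroc: float
    operating_threshold: float


def auroc(scores, labels):
    """Rank-based AUROC; returns ``None`` (with a warning) when only one class
    is present, so callers can exclude undefined classes from averages."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if len(np.unique(labels)) < 2:
        warnings.warn("AUROC undefined: only one class present")
        return None
    return float(roc_auc_score(labels, scores))


def macro_auroc(y_true: np.ndarray, y_score: np.ndarray):
    """Unweighted mean AUROC over classes, skipping undefined ones."""
    vals = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(y_true.shape[1]):
            a = auroc(y_score[:, k], y_true[:, k])
            if a is not None:
                vals.append(a)
    return float(np.mean(vals)) if vals else None


def roc_result(scores, labels) -> ROCResult:
    """ROC points (monotone from (0,0) to (1,1)), AUROC, and the Youden-J
    operating threshold."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    a = auroc(scores, labels)
    if a is None:
        warnings.warn("degenerate ROC; falling back to threshold 0.5")
        return ROCResult(np.array([0.0, 1.0]), np.array([0.0, 1.0]),
                         np.array([np.inf, -np.inf]), 0.5, 0.5)
    fpr, tpr, thr = roc_curve(labels, scores)
    return ROCResult(fpr, tpr, thr, a, choose_threshold(fpr, tpr, thr))


def choose_threshold(fpr: np.ndarray, tpr: np.ndarray, thresholds: np.ndarray) -> float:
    """Threshold maximising Youden's J = tpr - fpr; ties broken toward higher
    specificity (lower false-positive rate, i.e. the higher threshold)."""
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())
    # roc_curve orders thresholds descending, so the first maximiser has the
    # lowest fpr / highest threshold
    idx = best[0]
    t = float(thresholds[idx])
    if not np.isfinite(t):
        t = float(thresholds[best[-1]]) if np.isfinite(thresholds[best[-1]]) else 0.5
    return t


def macro_average(per_class) -> float:
    """Unweighted arithmetic mean, reported to 4 decimals."""
    per_class = np.asarray(per_class, dtype=np.float64)
    if per_class.size == 0:
        raise ValueError("cannot average an empty vector")
    return round(float(per_class.mean()), 4)


def weighted_average(values, weights) -> float:
    """Weight-normalised mean ``sum(w v) / sum(w)``, reported to 4 decimals."""
    values = np.asarray(values, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if values.shape != weights.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("weight sum must be positive")
    return round(float((values * weights).sum() / total), 4)


def relative_improvement(new: float, base: float) -> float:
    """Percent improvement ``100 (new - base) / base``, 2 decimals."""
    if base <= 0:
        raise ValueError("baseline must be positive")
    return round(100.0 * (new - base) / base, 2)


def evaluate_classifier(y_true: np.ndarray, y_score: np.ndarray,
                        class_names) -> pd.DataFrame:
    """Per-class AUROC and operating threshold plus a macro-average row."""
    rows = []
    defined = []
    for k, name in enumerate(class_names):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = auroc(y_score[:, k], y_true[:, k])
        if a is None:
            rows.append({"class": name, "auroc": np.nan, "threshold": np.nan})
            continue
        r = roc_result(y_score[:, k], y_true[:, k])
        rows.append({"class": name, "auroc": round(a, 4), "threshold": r.operating_threshold})
        defined.append(a)
    rows.append({"class": "Average", "auroc": macro_average(defined) if defined else np.nan,
                 "threshold": np.nan})
    return pd.DataFrame(rows, columns=["class", "auroc", "threshold"])
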
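"""Classifier evaluation: confusion-matrix metrics, ROC/AUC, DeLong's test.

The positive class is *malignant* throughout, so sensitivity is the malignant
detection rate. AUC is the trapezoidal area under the threshold-sweep ROC
curve, which equals the tie-corrected Mann–Whitney pair-counting statistic.
DeLong's test compares two correlated AUCs computed on the same samples using
the fast placement-value covariance estimate and a two-sided normal
approximation for the AUC difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_curve

__all__ = [
    "EvaluationReport",
    "DeLongResult",
    "confusion_and_metrics",
    "roc_auc",
    "delong_test",
    "evaluate_scores",
]

POSITIVE_LABEL = "malignant"


@dataclass
class EvaluationReport:
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    f_score: float
    undefined: list[str] = field(default_factory=list)
    roc_points: np.ndarray | None = None  # (FPR, TPR) rows
    auc: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        d = {
            "confusion": {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn},
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "f_score": self.f_score,
            "undefined": self.undefined,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d


@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    variance: float  # variance of the AUC difference
    z: float
    p_value: float


def _as_binary(labels, positive) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        return (y == positive).astype(int)
    return (y == 1).astype(int) if positive == POSITIVE_LABEL else (y == positive).astype(int)


def confusion_and_metrics(labels, predicted, positive=POSITIVE_LABEL) -> EvaluationReport:
    """Confusion matrix and the five scalar metrics.

    Undefined ratios (e.g. precision with no positive predictions) are
    reported as NaN and flagged, never silently zeroed.
    """
    y = _as_binary(labels, positive)
    p = _as_binary(predicted, positive)
    if y.shape[0] != p.shape[0]:
        raise ValueError("labels and predictions differ in length")
    tp = int(((y == 1) & (p == 1)).sum())
    fp = int(((y == 0) & (p == 1)).sum())
    fn = int(((y == 1) & (p == 0)).sum())
    tn = int(((y == 0) & (p == 0)).sum())

    undefined: list[str] = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return math.nan
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    acc = (tp + tn) / (tp + fp + fn + tn)
    prec = ratio(tp, tp + fp, "precision")
    if math.isnan(prec) or math.isnan(sens) or (prec + sens) == 0:
        undefined.append("f_score")
        f = math.nan
    else:
        f = 2 * prec * sens / (prec + sens)
    return EvaluationReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=sens, specificity=spec, accuracy=acc, precision=prec, f_score=f,
        undefined=undefined,
    )


def roc_auc(scores, labels, positive=POSITIVE_LABEL) -> tuple[np.ndarray, float]:
    """ROC points from a threshold sweep and the trapezoidal AUC.

    Tied scores step diagonally (simultaneous FPR/TPR increments), which makes
    the trapezoidal area equal to the tie-corrected pair-counting statistic.
    """
    y = _as_binary(labels, positive)
    s = np.asarray(scores, dtype=np.float64)
    if y.sum() == 0 or y.sum() == y.shape[0]:
        raise ValueError("AUC undefined: both classes must be present")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Placement values V10 (per positive) and V01 (per negative), plus AUC."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = pos.size, neg.size
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    return v10, v01, auc


def delong_test(scores_a, scores_b, labels, positive=POSITIVE_LABEL) -> DeLongResult:
    """Paired comparison of two models' AUCs on the same samples."""
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    y = _as_binary(labels, positive)
    if a.shape[0] != b.shape[0] or a.shape[0] != y.shape[0]:
        raise ValueError("paired design requires equal-length score vectors and labels")
    if y.sum() == 0 or y.sum() == y.shape[0]:
        raise ValueError("both classes must be present")

    v10a, v01a, auc_a = _placements(a, y)
    v10b, v01b, auc_b = _placements(b, y)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    var = max(float(var), 0.0)
    diff = auc_a - auc_b
    if var == 0.0:
        z = 0.0
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / math.sqrt(var)
        p = float(2.0 * norm.sf(abs(z)))
    return DeLongResult(auc_a=auc_a, auc_b=auc_b, variance=var, z=z, p_value=p)


def evaluate_scores(scores, labels, threshold: float = 0.0, positive=POSITIVE_LABEL) -> EvaluationReport:
    """Full report from decision scores: thresholded metrics plus ROC/AUC.

    The default threshold 0 is the linear SVM's native decision boundary.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = _as_binary(labels, positive)
    pred = (s > threshold).astype(int)
    rep = confusion_and_metrics(y, pred, positive=1)
    rep.roc_points, rep.auc = roc_auc(s, y, positive=1)
    return rep
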
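"""ROC analysis, cutoff selection and confusion-matrix metrics.

The AUC is the Mann–Whitney probability that a randomly chosen positive
outscores a randomly chosen negative (ties count 1/2); its 95% confidence
interval uses the DeLong placement-variance estimator. The operating cutoff
maximizes the Youden index J = sensitivity + specificity - 1, with ties
broken toward higher specificity and then the lower threshold; samples are
called positive when score >= cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .scoring import ScoreTable


@dataclass
class ROCCurve:
    """Sensitivity/specificity over candidate thresholds plus AUC and its CI.

    Thresholds are midpoints between consecutive distinct scores, with -inf
    and +inf sentinels; a sample is predicted positive when score >= threshold,
    so sensitivity is non-increasing and specificity non-decreasing in the
    threshold.
    """

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    auc_ci_low: float
    auc_ci_high: float


@dataclass
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class ClassificationReport:
    """Predicted labels, confusion counts and the accuracy/sensitivity/
    specificity triple; an undefined metric (single-class truth) is None."""

    cutoff: float | None
    predictions: pd.Series
    confusion: ConfusionMatrix
    accuracy: float
    sensitivity: float | None
    specificity: float | None

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "confusion": {"TP": self.confusion.tp, "TN": self.confusion.tn,
                          "FP": self.confusion.fp, "FN": self.confusion.fn},
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "predictions": {str(k): bool(v) for k, v in self.predictions.items()},
        }


def _scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and aligned")
    if not y.any() or y.all():
        raise ValueError("both classes must be present")
    return s, y


def auc(scores, labels) -> float:
    """Mann–Whitney AUC: P(random positive > random negative) + 0.5 P(tie)."""
    s, y = _scores_labels(scores, labels)
    m = int(y.sum())
    n = s.size - m
    ranks = rankdata(s, method="average")
    return float((ranks[y].sum() - m * (m + 1) / 2.0) / (m * n))


def _placements(s: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placements: per-positive fraction of negatives beaten, and vice versa."""
    pos, neg = s[y], s[~y]
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), 1.0 - cmp.mean(axis=0)


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float, float]:
    """AUC with a DeLong-variance normal-approximation confidence interval."""
    s, y = _scores_labels(scores, labels)
    v10, v01 = _placements(s, y)
    a = float(v10.mean())
    m, n = v10.size, v01.size
    var = 0.0
    if m > 1:
        var += v10.var(ddof=1) / m
    if n > 1:
        var += v01.var(ddof=1) / n
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return a, float(max(0.0, a - half)), float(min(1.0, a + half))


def roc_curve(scores, labels) -> ROCCurve:
    """Full ROC over midpoint thresholds with AUC and DeLong 95% CI."""
    s, y = _scores_labels(scores, labels)
    distinct = np.unique(s)
    if distinct.size == 1:
        mids = distinct  # degenerate: keep the lone score as a finite threshold
    else:
        mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    pred = s[None, :] >= thresholds[:, None]
    sens = (pred & y).sum(axis=1) / y.sum()
    spec = (~pred & ~y).sum(axis=1) / (~y).sum()
    a, lo, hi = delong_ci(s, y)
    return ROCCurve(thresholds, sens, spec, a, lo, hi)


def choose_cutoff(roc: ROCCurve) -> float:
    """Youden-optimal threshold (max J = sens + spec - 1).

    Ties are broken toward higher specificity, then the lower threshold;
    only finite thresholds are eligible. A degenerate curve (max J == 0)
    still returns the tie-break threshold, with a warning.
    """
    finite = np.isfinite(roc.thresholds)
    j = roc.sens + roc.spec - 1.0
    jf, specf, tf = j[finite], roc.spec[finite], roc.thresholds[finite]
    if tf.size == 0:
        raise ValueError("no finite thresholds available")
    best_j = jf.max()
    if best_j <= 0:
        warnings.warn("degenerate ROC: Youden J <= 0 at every threshold", stacklevel=2)
    tied = jf == best_j
    best_spec = specf[tied].max()
    tied &= specf == best_spec
    return float(tf[tied].min())


def classify(scores, cutoff: float) -> pd.Series | np.ndarray:
    """Predicted active ⇔ score >= cutoff. Accepts a ScoreTable or array."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    if isinstance(scores, ScoreTable):
        s = scores.scores
        return s >= cutoff
    return np.asarray(scores, dtype=float) >= cutoff


def confusion_metrics(pred, truth, cutoff: float | None = None) -> ClassificationReport:
    """Accuracy/sensitivity/specificity from predicted vs true labels.

    accuracy = (TP+TN)/(TP+TN+FP+FN); sensitivity = TP/(TP+FN);
    specificity = TN/(TN+FP). A metric whose denominator is empty (truth has
    only one class) is reported as None, never 0.
    """
    if isinstance(pred, pd.Series):
        index = pred.index
        p = pred.to_numpy(dtype=bool)
    else:
        p = np.asarray(pred, dtype=bool)
        index = pd.RangeIndex(p.size)
    t = np.asarray(truth, dtype=bool)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.size} predictions vs {t.size} truth labels")
    if p.size == 0:
        raise ValueError("empty input")

    cm = ConfusionMatrix(
        tp=int((p & t).sum()),
        tn=int((~p & ~t).sum()),
        fp=int((p & ~t).sum()),
        fn=int((~p & t).sum()),
    )
    accuracy = (cm.tp + cm.tn) / cm.total
    sensitivity = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else None
    specificity = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) else None
    return ClassificationReport(cutoff, pd.Series(p, index=index), cm, accuracy, sensitivity, specificity)


def roc_points_frame(roc: ROCCurve) -> pd.DataFrame:
    return pd.DataFrame({"threshold": roc.thresholds, "sens": roc.sens, "spec": roc.spec})
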
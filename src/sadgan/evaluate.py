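"""Pixel-level segmentation metrics: ACC/SE/SP at a threshold, plus ROC and
precision-recall curves and their areas.

All metrics are computed over pixels inside the field-of-view mask only (the
standard protocol for fundus benchmarks); a flag widens them to the full
frame.  Definitions:

    ACC = (TP+TN)/(TP+FP+FN+TN),  SE = TP/(TP+FN),  SP = TN/(TN+FP).

ROC area uses trapezoidal integration over all distinct score thresholds;
PR area uses the stepwise rule sum_n (R_n - R_{n-1}) P_n.  Undefined ratios
(empty denominators, single-class inputs) are flagged as NaN rather than
raised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm

__all__ = ["ConfusionCounts", "MetricsReport", "confusion", "point_metrics",
           "roc_pr_areas", "roc_pr_curves", "dice_coefficient",
           "evaluate_samples", "pooled_scores"]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    acc: float
    se: float
    sp: float
    roc_auc: float
    pr_auc: float
    threshold: float = 0.5


def confusion(pred: np.ndarray, truth: np.ndarray, fov: np.ndarray | None = None,
              threshold: float = 0.5) -> ConfusionCounts:
    """Pixel tallies at a threshold; prediction positive iff prob >= threshold.

    ``pred`` is the positive-class probability plane (H×W).  Only pixels with
    fov = 1 are counted; fov=None evaluates the full frame.
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"pred shape {pred.shape} != truth shape {truth.shape}")
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0,1]")
    if fov is None:
        sel = np.ones(pred.shape, dtype=bool)
    else:
        fov = np.asarray(fov)
        if fov.shape != pred.shape:
            raise ValueError(f"fov shape {fov.shape} != pred shape {pred.shape}")
        sel = fov.astype(bool)
    p = pred[sel] >= threshold
    t = truth[sel].astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(p & t)), fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)), fn=int(np.sum(~p & t)),
    )


def point_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(ACC, SE, SP); NaN flags an empty denominator."""
    if c.total == 0:
        raise ValueError("no evaluated pixels")
    acc = (c.tp + c.tn) / c.total
    se = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else float("nan")
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else float("nan")
    return acc, se, sp


def roc_pr_areas(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(ROC_AUC, PR_AUC) over flat score/label arrays; NaN if single-class."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        return float("nan"), float("nan")
    roc = float(_skm.roc_auc_score(labels, scores))
    pr = float(_skm.average_precision_score(labels, scores))
    return roc, pr


def roc_pr_curves(scores: np.ndarray, labels: np.ndarray
                  ) -> dict[str, np.ndarray]:
    """Curve point tables for replotting: fpr/tpr and precision/recall."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    fpr, tpr, roc_thr = _skm.roc_curve(labels, scores)
    prec, rec, pr_thr = _skm.precision_recall_curve(labels, scores)
    return {"fpr": fpr, "tpr": tpr, "roc_thresholds": roc_thr,
            "precision": prec, "recall": rec, "pr_thresholds": pr_thr}


def dice_coefficient(pred_mask: np.ndarray, truth: np.ndarray,
                     fov: np.ndarray | None = None) -> float:
    """2|A∩B| / (|A|+|B|) between binary masks (1.0 when both are empty)."""
    a = np.asarray(pred_mask).astype(bool)
    b = np.asarray(truth).astype(bool)
    if fov is not None:
        sel = np.asarray(fov).astype(bool)
        a, b = a[sel], b[sel]
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.sum(a & b) / denom)


def pooled_scores(prob_maps: list[np.ndarray], truths: list[np.ndarray],
                  fovs: list[np.ndarray] | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Flatten FOV pixels of many images into one (scores, labels) pair."""
    ss, ll = [], []
    for i, (p, t) in enumerate(zip(prob_maps, truths)):
        sel = np.ones(p.shape, dtype=bool) if fovs is None else fovs[i].astype(bool)
        ss.append(np.asarray(p, dtype=np.float64)[sel])
        ll.append(np.asarray(t)[sel])
    return np.concatenate(ss), np.concatenate(ll)


def evaluate_samples(prob_maps: list[np.ndarray], truths: list[np.ndarray],
                     fovs: list[np.ndarray] | None = None,
                     threshold: float = 0.5) -> MetricsReport:
    """Pooled metrics across images (all FOV pixels pooled before computing)."""
    counts = ConfusionCounts(0, 0, 0, 0)
    for i, (p, t) in enumerate(zip(prob_maps, truths)):
        c = confusion(p, t, None if fovs is None else fovs[i], threshold)
        counts = ConfusionCounts(counts.tp + c.tp, counts.fp + c.fp,
                                 counts.tn + c.tn, counts.fn + c.fn)
    acc, se, sp = point_metrics(counts)
    scores, labels = pooled_scores(prob_maps, truths, fovs)
    roc, pr = roc_pr_areas(scores, labels)
    return MetricsReport(acc=acc, se=se, sp=sp, roc_auc=roc, pr_auc=pr,
                         threshold=threshold)
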
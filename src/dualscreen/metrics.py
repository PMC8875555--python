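"""Binary-classification metrics for screening models.

Accuracy and the Matthews correlation coefficient are computed directly from
the confusion counts:

    ACC = (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with MCC defined as 0 when any denominator factor vanishes.  AUC is the
probability that a uniformly random positive outscores a uniformly random
negative (ties counted 1/2), computed from ranks.  LogAUC is the area under
TPR versus log10(FPR) over [fpr_floor, 1], normalised by the log range and
expressed as a percentage — it up-weights early enrichment, the regime that
matters when only the top of a ranked screen is ever tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class MetricSet:
    """Confusion counts plus derived metrics for one evaluation."""

    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    mcc: float
    auc: float | None = None
    logauc: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return tp, tn, fp, fn


def accuracy_from_counts(tp: int, tn: int, fp: int, fn: int) -> float:
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion matrix")
    return (tp + tn) / total


def mcc_from_counts(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    denom_factors = [(tp + fp), (tp + fn), (tn + fp), (tn + fn)]
    if any(f == 0 for f in denom_factors):
        return 0.0
    num = tp * tn - fp * fn
    return num / math.sqrt(math.prod(float(f) for f in denom_factors))


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUC: P(score_pos > score_neg) with ties counted 1/2."""
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    rank_sum_pos = ranks[y_true == 1].sum()
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray | None = None,
    with_logauc: bool = False,
) -> MetricSet:
    """ACC/MCC from hard predictions and, when scores are given and both
    classes are present, AUC (and optionally LogAUC).

    With a single-class truth vector AUC is undefined and reported absent;
    ACC and MCC still apply (MCC uses the zero-denominator convention).
    """
    tp, tn, fp, fn = confusion_counts(y_true, y_pred)
    auc = logauc = None
    y_true = np.asarray(y_true).astype(int)
    both_classes = 0 < y_true.sum() < len(y_true)
    if scores is not None and both_classes:
        auc = roc_auc(y_true, scores)
        if with_logauc:
            logauc = log_auc(y_true, scores)
    return MetricSet(
        tp=tp, tn=tn, fp=fp, fn=fn,
        acc=accuracy_from_counts(tp, tn, fp, fn),
        mcc=mcc_from_counts(tp, tn, fp, fn),
        auc=auc, logauc=logauc,
    )


def _roc_points(y_true: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ROC curve (FPR, TPR) by descending score threshold, tie groups merged."""
    order = np.argsort(-scores, kind="mergesort")
    y = y_true[order]
    s = scores[order]
    # threshold boundaries where the score changes
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tps = np.cumsum(y)[distinct]
    fps = (distinct + 1) - tps
    tpr = np.r_[0.0, tps / y_true.sum()]
    fpr = np.r_[0.0, fps / (len(y_true) - y_true.sum())]
    return fpr, tpr


def log_auc(
    y_true: np.ndarray, scores: np.ndarray, fpr_floor: float = 0.001
) -> float:
    """Semilog-ROC area: TPR integrated over log10(FPR) from fpr_floor to 1.

    Normalised by the log range (3 decades at the default floor) and returned
    as a percentage.  A perfect classifier scores 100; a random one about
    (1 - fpr_floor) / (3 ln 10) x 100 ~ 14.5.
    """
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    if not 0 < y_true.sum() < len(y_true):
        raise ValueError("log_auc requires both classes present")
    if not 0.0 < fpr_floor < 1.0:
        raise ValueError("fpr_floor must be in (0, 1)")
    fpr, tpr = _roc_points(y_true, scores)
    # linear interpolation of the ROC at the floor, then restrict to >= floor
    tpr_floor = float(np.interp(fpr_floor, fpr, tpr))
    keep = fpr > fpr_floor
    fpr_c = np.r_[fpr_floor, fpr[keep]]
    tpr_c = np.r_[tpr_floor, tpr[keep]]
    if fpr_c[-1] < 1.0:
        fpr_c = np.r_[fpr_c, 1.0]
        tpr_c = np.r_[tpr_c, tpr_c[-1]]
    log_fpr = np.log10(fpr_c)
    area = np.trapezoid(tpr_c, log_fpr)
    return float(area / -np.log10(fpr_floor) * 100.0)
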
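"""Statistical toolkit for quality-classification experiments.

Conventions follow the quality-assessment setting: the positive class is
"sufficient quality", higher FD scores indicate the positive class, and
the decision rule is ``score >= threshold``.  TP/FN count sufficient-
quality images classified correctly/wrongly; TN/FP count insufficient-
quality images classified correctly/wrongly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn import metrics as _skm


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one count")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class RateSet:
    """TPR = TP/(TP+FN), FPR = FP/(FP+TN), precision = TP/(TP+FP);
    recall is identically TPR.  Undefined rates (zero denominator) are NaN.
    """

    tpr: float
    fpr: float
    precision: float

    @property
    def recall(self) -> float:
        return self.tpr

    @property
    def fnr(self) -> float:
        return 1.0 - self.tpr


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def rates(cm: ConfusionMatrix) -> RateSet:
    """Confusion-matrix rates."""
    return RateSet(tpr=_ratio(cm.tp, cm.tp + cm.fn),
                   fpr=_ratio(cm.fp, cm.fp + cm.tn),
                   precision=_ratio(cm.tp, cm.tp + cm.fp))


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP + TN) / total."""
    return (cm.tp + cm.tn) / cm.total


def _check_scored(scores, labels):
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-D sequences")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return s, y


def roc_curve(scores, labels):
    """ROC curve over all distinct score thresholds plus its trapezoid AUC.

    Returns ``(fpr, tpr, thresholds, auc)``; the rule is score >= t ->
    positive, the curve runs from (0, 0) to (1, 1).
    """
    s, y = _check_scored(scores, labels)
    fpr, tpr, thr = _skm.roc_curve(y, s, drop_intermediate=False)
    return fpr, tpr, thr, float(_skm.auc(fpr, tpr))


def pr_curve(scores, labels):
    """Precision-recall curve and its trapezoid AUC (in recall order)."""
    s, y = _check_scored(scores, labels)
    precision, recall, thr = _skm.precision_recall_curve(y, s)
    # trapezoid over the attainable envelope: at tied recalls only the
    # best precision is an operating point worth integrating
    uniq = {}
    for r, p in zip(recall, precision):
        uniq[float(r)] = max(uniq.get(float(r), 0.0), float(p))
    xs = np.array(sorted(uniq))
    ys = np.array([uniq[x] for x in xs])
    auc_pr = float(np.trapezoid(ys, xs))
    return recall, precision, thr, auc_pr


def optimal_cutoff(scores, labels, kind: str = "roc") -> float:
    """Operating threshold maximizing Youden's J (ROC) or F1 (PR).

    Candidates are the distinct scores (rule score >= t); ties break
    toward the larger threshold.
    """
    s, y = _check_scored(scores, labels)
    if kind not in ("roc", "pr"):
        raise ValueError("kind must be 'roc' or 'pr'")
    pos = int(y.sum())
    neg = int(len(y) - pos)
    best_t, best_val = None, -np.inf
    for t in np.unique(s):
        pred = s >= t
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        if kind == "roc":
            val = tp / pos - fp / neg
        else:
            denom = 2 * tp + fp + (pos - tp)
            val = 2 * tp / denom if denom > 0 else 0.0
        if val >= best_val:  # >= so ties go to the larger threshold
            best_val, best_t = val, float(t)
    return best_t


def group_stats(values, confidence: float = 0.95):
    """Mean and t-based confidence interval of one FD group.

    Returns ``(mean, (low, high))`` with the interval
    mean +/- t(1 - alpha/2, n - 1) * SE.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("group must contain at least two values")
    mean = float(v.mean())
    se = float(v.std(ddof=1) / np.sqrt(v.size))
    tmult = float(stats.t.ppf(0.5 + confidence / 2.0, v.size - 1))
    return mean, (mean - tmult * se, mean + tmult * se)


def compare_groups(a, b, alpha: float = 0.001):
    """Welch two-sample t-test between two independent FD groups.

    Returns ``(t_statistic, p_value, significant)`` with significance at
    p < alpha (default 0.001).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group must contain at least two values")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), bool(p < alpha)
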
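"""Diagnostic performance metrics.

Sensitivity is the true-positive rate TP/(TP+FN)·100%. Two "specificity"
conventions coexist in the literature this package follows: the literal
false-positive-rate form FP/(FP+TN)·100% (exposed as :func:`paper_fpr`) and
the standard complement TN/(TN+FP)·100% (:func:`specificity_std`); the two
always sum to 100. AUC is the rank (Mann–Whitney) statistic: the probability
that a random positive instance outscores a random negative one, ties
counted half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_matrix(truth, predicted) -> ConfusionMatrix:
    """Tally the four cells; labels must be in {-1, +1} with +1 = positive."""
    t = np.asarray(truth).ravel()
    p = np.asarray(predicted).ravel()
    if t.shape != p.shape:
        raise ValueError("truth and predicted must have equal length")
    if not (np.all(np.isin(t, [-1, 1])) and np.all(np.isin(p, [-1, 1]))):
        raise ValueError("labels must be in {-1, +1}")
    return ConfusionMatrix(
        tp=int(np.sum((t == 1) & (p == 1))),
        fp=int(np.sum((t == -1) & (p == 1))),
        tn=int(np.sum((t == -1) & (p == -1))),
        fn=int(np.sum((t == 1) & (p == -1))),
    )


def sensitivity(cm: ConfusionMatrix) -> float:
    """TPR = 100·TP/(TP+FN)."""
    if cm.tp + cm.fn == 0:
        raise ValueError("no positive instances")
    return 100.0 * cm.tp / (cm.tp + cm.fn)


def paper_fpr(cm: ConfusionMatrix) -> float:
    """The false-positive rate 100·FP/(FP+TN)."""
    if cm.fp + cm.tn == 0:
        raise ValueError("no negative instances")
    return 100.0 * cm.fp / (cm.fp + cm.tn)


def specificity_std(cm: ConfusionMatrix) -> float:
    """Standard specificity 100·TN/(TN+FP) = 100 − FPR."""
    return 100.0 - paper_fpr(cm)


def accuracy(cm: ConfusionMatrix) -> float:
    """100·(TP+TN)/total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * (cm.tp + cm.tn) / cm.total


def auc(scores, truth) -> float:
    """Mann–Whitney AUC of continuous scores against {-1,+1} truth."""
    s = np.asarray(scores, dtype=np.float64).ravel()
    t = np.asarray(truth).ravel()
    if s.shape != t.shape:
        raise ValueError("scores and truth must have equal length")
    pos = t == 1
    neg = t == -1
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)  # average ranks handle ties as half-wins
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def metrics_report(truth, predicted, scores=None) -> dict:
    """All metrics as a dict (percent values rounded to 2 decimals for
    presentation; 'auc' on [0, 1])."""
    cm = confusion_matrix(truth, predicted)
    report = {
        "TP": cm.tp, "FP": cm.fp, "TN": cm.tn, "FN": cm.fn,
        "sensitivity_TPR": round(sensitivity(cm), 2),
        "paper_FPR": round(paper_fpr(cm), 2),
        "specificity_std": round(specificity_std(cm), 2),
        "accuracy": round(accuracy(cm), 2),
    }
    if scores is not None:
        report["auc"] = auc(scores, truth)
    return report
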
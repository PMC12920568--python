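"""Binary-classification metrics: Acc, Sn, Sp, HM, Precision, F1, MCC, AUC.

HM is the harmonic mean of sensitivity and specificity, the usual aggregate
in gene-finding evaluations.  AUC uses the rank (Mann-Whitney) formulation,
which is exact under ties.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy.stats import rankdata


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ValueError("empty confusion table")
    return (c.tp + c.tn) / c.total


def sensitivity(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        raise ValueError("no positive instances (tp + fn == 0)")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    if c.tn + c.fp == 0:
        raise ValueError("no negative instances (tn + fp == 0)")
    return c.tn / (c.tn + c.fp)


def precision(c: ConfusionCounts) -> float:
    if c.tp + c.fp == 0:
        raise ValueError("no predicted positives (tp + fp == 0)")
    return c.tp / (c.tp + c.fp)


def f1_score(c: ConfusionCounts) -> float:
    p, s = precision(c), sensitivity(c)
    if p + s == 0:
        warnings.warn("precision + sensitivity is zero; F1 set to 0")
        return 0.0
    return 2 * p * s / (p + s)


def mcc(c: ConfusionCounts) -> float:
    denom = math.sqrt(float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    if denom == 0:
        warnings.warn("degenerate confusion table; MCC set to 0")
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / denom


def harmonic_mean_sn_sp(c: ConfusionCounts) -> float:
    sn, sp = sensitivity(c), specificity(c)
    if sn + sp == 0:
        warnings.warn("Sn + Sp is zero; HM set to 0")
        return 0.0
    return 2 * sn * sp / (sn + sp)


def auc(scores, labels) -> float:
    """Area under the ROC curve via the rank statistic; ties contribute 1/2."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes to be present")
    ranks = rankdata(scores)
    pos_rank_sum = ranks[labels == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def report(c: ConfusionCounts) -> dict:
    """All table metrics as a flat dict (fractions, not percentages)."""
    return {
        "accuracy": accuracy(c),
        "sensitivity": sensitivity(c),
        "specificity": specificity(c),
        "harmonic_mean": harmonic_mean_sn_sp(c),
        "precision": precision(c) if c.tp + c.fp > 0 else float("nan"),
        "f1": f1_score(c) if c.tp + c.fp > 0 else float("nan"),
        "mcc": mcc(c),
    }
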
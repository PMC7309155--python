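"""Diagnostic-test statistics and group/classifier comparison tests.

Implements the standard binary-diagnostic toolkit: confusion matrix,
sensitivity, specificity, predictive values, accuracy and likelihood
ratios, plus the Mann–Whitney test used for faller/nonfaller group
differences and McNemar's test for comparing two classifiers evaluated on
the same participants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

__all__ = [
    "ConfusionMatrix",
    "DiagnosticMetrics",
    "confusion",
    "diagnostic_metrics",
    "likelihood_ratios",
    "evaluate_classifier",
    "mann_whitney",
    "mcnemar",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """True/false positive/negative counts of one binary classifier."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer")
        if self.total < 1:
            raise ValueError("confusion matrix must count at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Se/Sp/PPV/NPV/Acc and likelihood ratios of a confusion matrix.

    Ratios with an empty margin are NaN (or +inf for LR+ at Sp = 1) and the
    affected statistic is named in ``undefined``.
    """

    se: float
    sp: float
    ppv: float
    npv: float
    acc: float
    lr_pos: float
    lr_neg: float
    undefined: tuple = ()


def confusion(pred, truth) -> ConfusionMatrix:
    """Tally predictions against true labels (both binary 0/1)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have the same length")
    if pred.size < 1:
        raise ValueError("empty input")
    for arr, name in ((pred, "pred"), (truth, "truth")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must contain only 0/1")
    return ConfusionMatrix(
        tp=int(np.sum((pred == 1) & (truth == 1))),
        fp=int(np.sum((pred == 1) & (truth == 0))),
        fn=int(np.sum((pred == 0) & (truth == 1))),
        tn=int(np.sum((pred == 0) & (truth == 0))),
    )


def likelihood_ratios(se: float, sp: float) -> tuple[float, float]:
    """LR+ = Se/(1-Sp) and LR- = (1-Se)/Sp.

    LR+ is +inf at Sp = 1 (a positive test is then conclusive); LR- is NaN
    at Sp = 0.
    """
    lr_pos = se / (1.0 - sp) if sp < 1.0 else math.inf
    lr_neg = (1.0 - se) / sp if sp > 0.0 else math.nan
    return lr_pos, lr_neg


def diagnostic_metrics(cm: ConfusionMatrix) -> DiagnosticMetrics:
    """All seven statistics of a confusion matrix.

    Margins with zero count yield NaN for the statistics that depend on
    them, flagged by name rather than propagated silently.
    """
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return math.nan
        return num / den

    se = ratio(cm.tp, cm.tp + cm.fn, "se")
    sp = ratio(cm.tn, cm.tn + cm.fp, "sp")
    ppv = ratio(cm.tp, cm.tp + cm.fp, "ppv")
    npv = ratio(cm.tn, cm.tn + cm.fn, "npv")
    acc = (cm.tp + cm.tn) / cm.total
    if math.isnan(se) or math.isnan(sp):
        lr_pos = math.nan
        lr_neg = math.nan
        undefined.extend(["lr_pos", "lr_neg"])
    else:
        lr_pos, lr_neg = likelihood_ratios(se, sp)
        if math.isinf(lr_pos):
            undefined.append("lr_pos")
        if math.isnan(lr_neg):
            undefined.append("lr_neg")
    return DiagnosticMetrics(
        se=se, sp=sp, ppv=ppv, npv=npv, acc=acc,
        lr_pos=lr_pos, lr_neg=lr_neg, undefined=tuple(undefined),
    )


def evaluate_classifier(pred, truth) -> tuple[ConfusionMatrix, DiagnosticMetrics]:
    """Confusion matrix and diagnostic statistics in one call."""
    cm = confusion(pred, truth)
    return cm, diagnostic_metrics(cm)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test between two samples.

    Uses the exact null distribution for small tie-free samples
    (min(n) <= 8) and the normal approximation with tie correction
    otherwise, following common statistical-software behaviour.

    Returns
    -------
    (U, p) : U statistic of the first sample and two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if min(x.size, y.size) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def mcnemar(pred_a, pred_b, truth, variant: str = "auto") -> tuple[float, float]:
    """McNemar's test for two classifiers scored on the same participants.

    The discordant counts are b (A correct, B wrong) and c (A wrong, B
    correct). With ``variant='auto'`` the continuity-corrected chi-square
    statistic ``(|b-c|-1)^2/(b+c)`` (1 df) is used when b + c >= 25 and the
    exact two-sided binomial test otherwise; ``'exact'`` and ``'chi2'``
    force one branch. b + c = 0 returns (0, 1).
    """
    pred_a = np.asarray(pred_a)
    pred_b = np.asarray(pred_b)
    truth = np.asarray(truth)
    if not (pred_a.shape == pred_b.shape == truth.shape):
        raise ValueError("all three label vectors must have the same length")
    correct_a = pred_a == truth
    correct_b = pred_b == truth
    b = int(np.sum(correct_a & ~correct_b))
    c = int(np.sum(~correct_a & correct_b))
    if b + c == 0:
        return 0.0, 1.0
    if variant == "auto":
        variant = "chi2" if b + c >= 25 else "exact"
    table = [[0, b], [c, 0]]  # only the off-diagonal matters
    if variant == "chi2":
        res = _sm_mcnemar(table, exact=False, correction=True)
    elif variant == "exact":
        res = _sm_mcnemar(table, exact=True)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return float(res.statistic), float(res.pvalue)
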
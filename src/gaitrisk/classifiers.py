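"""Fall-risk classifiers: thresholded TUG, the TUG+ rule, logistic fusion.

Three progressively richer ways of labelling a participant as at risk:

* ``TugThresholdClassifier`` — the clinical Timed Up and Go test alone: an
  ROC analysis of TUG times picks the threshold maximizing Youden's index
  Se + Sp - 1; longer times mean higher risk.
* ``TugPlusClassifier`` — the TUG threshold augmented with two walk-derived
  variability indices (anteroposterior acceleration SD, higher = riskier;
  vertical acceleration fractal dimension, lower = riskier), with the two
  index thresholds fitted by exhaustive in-sample accuracy search.
* ``LogisticFusionClassifier`` — the same three features fused by a
  maximum-likelihood logistic regression instead of a checklist rule.

All estimators follow the scikit-learn fit/predict protocol and accept
either a pandas DataFrame (columns ``tug_s``, ``SDa_ap``, ``Da_v``) or a
plain (n, 3) array in that column order.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "RocCurve",
    "TugPlusRule",
    "roc_curve",
    "youden_threshold",
    "tug_classify",
    "tugplus_classify",
    "fit_tugplus_thresholds",
    "logistic_fusion_fit",
    "logistic_fusion_predict",
    "TugThresholdClassifier",
    "TugPlusClassifier",
    "LogisticFusionClassifier",
]

_FEATURES = ("tug_s", "SDa_ap", "Da_v")


def _feature_matrix(X) -> np.ndarray:
    """Coerce input to an (n, 3) float array in (tug, SDa_ap, Da_v) order."""
    if hasattr(X, "columns"):
        missing = [c for c in _FEATURES if c not in X.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        return X[list(_FEATURES)].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("expected an (n, 3) array of (tug_s, SDa_ap, Da_v)")
    return X


@dataclass
class RocCurve:
    """Operating points of a 'higher score = riskier' classifier family.

    ``thresholds[i]`` is a cut; predicting risk as ``score > thresholds[i]``
    yields sensitivity ``se[i]`` and specificity ``sp[i]``. The first
    threshold is -inf (everything positive). ``auc`` is the trapezoidal
    area under (1 - sp, se), identical to the tie-corrected concordance
    probability.
    """

    thresholds: np.ndarray
    se: np.ndarray
    sp: np.ndarray
    auc: float


def roc_curve(scores, labels) -> RocCurve:
    """ROC analysis of a continuous risk score against binary labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    distinct = np.unique(scores)
    cuts = np.concatenate([[-np.inf], distinct])
    se = np.empty(cuts.size)
    sp = np.empty(cuts.size)
    for i, c in enumerate(cuts):
        pred = scores > c
        se[i] = np.sum(pred & (labels == 1)) / n_pos
        sp[i] = np.sum(~pred & (labels == 0)) / n_neg
    # se decreases along cuts; integrate over (1 - sp, se). Points sharing
    # an fpr must be ordered by se so vertical steps carry no spurious area.
    fpr = 1.0 - sp
    order = np.lexsort((se, fpr))
    auc = float(np.trapezoid(se[order], fpr[order]))
    return RocCurve(thresholds=cuts, se=se, sp=sp, auc=auc)


def youden_threshold(roc: RocCurve) -> tuple[float, float]:
    """Cutpoint maximizing Youden's index J = Se + Sp - 1.

    Ties are broken toward the lower (more sensitive) cut. The reported
    threshold is the midpoint between the two adjacent distinct scores, so
    the implied classification is invariant to infinitesimal score
    perturbations; at the extremes it is -inf / +inf.
    """
    j = roc.se + roc.sp - 1.0
    best = int(np.argmax(j))  # argmax takes the first, i.e. lowest, cut
    cuts = roc.thresholds
    if best == 0:
        threshold = -np.inf
    elif best == cuts.size - 1:
        threshold = np.inf
    else:
        threshold = 0.5 * (cuts[best] + cuts[best + 1])
    return float(threshold), float(j[best])


def tug_classify(tug_time, t_star: float):
    """Risk from the TUG time alone: strictly slower than t* is at risk."""
    return (np.asarray(tug_time, dtype=float) > t_star).astype(int)


@dataclass
class TugPlusRule:
    """Fitted thresholds and combination logic of the augmented TUG test.

    The three binary answers are ``TUG > t_star``, ``SDa_ap > sd_aap_star``
    and ``Da_v < d_av_star``. ``combine`` selects how they merge:

    * ``"or"`` (default): at risk if any answer is positive — the
      three-question checklist reading.
    * ``"sequential"``: the TUG-positives are re-tested, at risk only if
      additionally an index answer is positive.
    * ``"tug_only"``: first question alone (reduces to the plain TUG test).
    """

    t_star: float
    sd_aap_star: float
    d_av_star: float
    combine: str = "or"

    def answers(self, tug_time, sd_aap, d_av) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        q1 = np.asarray(tug_time, dtype=float) > self.t_star
        q2 = np.asarray(sd_aap, dtype=float) > self.sd_aap_star
        q3 = np.asarray(d_av, dtype=float) < self.d_av_star
        return q1, q2, q3

    def evaluate(self, tug_time, sd_aap, d_av) -> np.ndarray:
        q1, q2, q3 = self.answers(tug_time, sd_aap, d_av)
        if self.combine == "or":
            risk = q1 | q2 | q3
        elif self.combine == "sequential":
            risk = q1 & (q2 | q3)
        elif self.combine == "tug_only":
            risk = q1
        else:
            raise ValueError(f"unknown combine rule {self.combine!r}")
        return risk.astype(int)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TugPlusRule":
        return cls(**d)


def tugplus_classify(tug_time, sd_aap, d_av, rule: TugPlusRule):
    """Apply a fitted TUG+ rule to one or more participants."""
    return rule.evaluate(tug_time, sd_aap, d_av)


def _candidate_cuts(values: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct observed values, plus sentinels.

    The sentinels make 'answer never positive' and 'answer always positive'
    part of the search space, so a fitted rule can switch an index question
    off entirely.
    """
    v = np.unique(values)
    mids = 0.5 * (v[:-1] + v[1:])
    return np.concatenate([[-np.inf], mids, [np.inf]])


def fit_tugplus_thresholds(
    X, y, t_star: float, combine: str = "or"
) -> TugPlusRule:
    """Exhaustive in-sample accuracy search for the two index thresholds.

    The TUG threshold ``t_star`` is held fixed (it comes from the Youden
    analysis of the TUG test); the SDa_ap and Da_v cuts range over all
    observed-value midpoints including on/off sentinels. Ties are broken
    toward higher sensitivity, then lower ``sd_aap_star``, then higher
    ``d_av_star``. The search is in-sample by design, reproducing how such
    checklist tests are tuned on a full cohort.
    """
    F = _feature_matrix(X)
    y = np.asarray(y)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    tug, sd_aap, d_av = F[:, 0], F[:, 1], F[:, 2]
    a_cuts = _candidate_cuts(sd_aap)
    d_cuts = _candidate_cuts(d_av)

    q1 = tug > t_star  # (n,)
    q2 = sd_aap[:, None] > a_cuts[None, :]  # (n, A)
    q3 = d_av[:, None] < d_cuts[None, :]  # (n, D)
    if combine == "or":
        risk = q1[:, None, None] | q2[:, :, None] | q3[:, None, :]
    elif combine == "sequential":
        risk = q1[:, None, None] & (q2[:, :, None] | q3[:, None, :])
    else:
        raise ValueError(f"unknown combine rule {combine!r}")

    pos = y == 1
    acc = np.mean(risk == pos[:, None, None], axis=0)
    se = np.mean(risk[pos], axis=0)

    best_acc = acc.max()
    cand = np.argwhere(acc == best_acc)
    best_se = se[tuple(cand.T)].max()
    cand = cand[se[tuple(cand.T)] == best_se]
    # lower sd_aap_star, then higher d_av_star
    order = np.lexsort((-d_cuts[cand[:, 1]], a_cuts[cand[:, 0]]))
    ia, id_ = cand[order[0]]
    return TugPlusRule(
        t_star=float(t_star),
        sd_aap_star=float(a_cuts[ia]),
        d_av_star=float(d_cuts[id_]),
        combine=combine,
    )


class TugThresholdClassifier(BaseEstimator, ClassifierMixin):
    """Youden-thresholded TUG test as a scikit-learn classifier.

    ``fit`` expects TUG times (1-d, or column 0 of an (n, 3) feature
    matrix / ``tug_s`` of a DataFrame) and binary faller labels; it stores
    the fitted cut in ``threshold_`` together with the full ``roc_`` and
    ``youden_j_``.
    """

    def fit(self, X, y):
        tug = self._tug_times(X)
        y = np.asarray(y)
        self.roc_ = roc_curve(tug, y)
        self.threshold_, self.youden_j_ = youden_threshold(self.roc_)
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X):
        return tug_classify(self._tug_times(X), self.threshold_)

    @staticmethod
    def _tug_times(X) -> np.ndarray:
        if hasattr(X, "columns"):
            return X["tug_s"].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            return X
        return X[:, 0]


class TugPlusClassifier(BaseEstimator, ClassifierMixin):
    """The augmented TUG test (TUG+) as a scikit-learn classifier.

    Parameters
    ----------
    t_star : float or None
        Fixed TUG threshold in seconds. None (default) refits it on the
        training cohort by Youden's index, as the plain TUG test does.
    combine : {"or", "sequential"}
        Combination logic of the three checklist answers.
    """

    def __init__(self, t_star: float | None = None, combine: str = "or"):
        self.t_star = t_star
        self.combine = combine

    def fit(self, X, y):
        F = _feature_matrix(X)
        y = np.asarray(y)
        if self.t_star is None:
            t_star, _ = youden_threshold(roc_curve(F[:, 0], y))
        else:
            t_star = self.t_star
        self.rule_ = fit_tugplus_thresholds(F, y, t_star=t_star, combine=self.combine)
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X):
        F = _feature_matrix(X)
        return self.rule_.evaluate(F[:, 0], F[:, 1], F[:, 2])


class LogisticFusionClassifier(BaseEstimator, ClassifierMixin):
    """Maximum-likelihood logistic fusion of (TUG, SDa_ap, Da_v).

    On perfectly separable cohorts the unpenalized likelihood has no
    maximum; a warning is issued and a ridge-penalized fit (alpha =
    ``ridge``) is used instead.
    """

    def __init__(self, cut: float = 0.5, ridge: float = 1e-4):
        self.cut = cut
        self.ridge = ridge

    def fit(self, X, y):
        import statsmodels.api as sm

        F = _feature_matrix(X)
        y = np.asarray(y, dtype=float)
        design = sm.add_constant(F, has_constant="add")
        self.separable_ = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error")
                res = sm.Logit(y, design).fit(disp=0, maxiter=200)
            params = res.params
            if not np.all(np.isfinite(params)) or np.max(np.abs(params[1:])) > 1e6:
                raise RuntimeError("diverging coefficients")
        except Exception:
            self.separable_ = True
            warnings.warn(
                "perfect separation detected; falling back to a ridge-penalized fit",
                stacklevel=2,
            )
            from sklearn.linear_model import LogisticRegression

            lr = LogisticRegression(C=1.0 / self.ridge, max_iter=2000)
            lr.fit(F, y.astype(int))
            params = np.concatenate([lr.intercept_, lr.coef_.ravel()])
        self.intercept_ = float(params[0])
        self.coef_ = np.asarray(params[1:], dtype=float)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        F = _feature_matrix(X)
        z = self.intercept_ + F @ self.coef_
        p = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] > self.cut).astype(int)


def logistic_fusion_fit(X, y, ridge: float = 1e-4) -> LogisticFusionClassifier:
    """Fit the logistic fusion model; returns the fitted estimator."""
    return LogisticFusionClassifier(ridge=ridge).fit(X, y)


def logistic_fusion_predict(X, model: LogisticFusionClassifier, cut: float = 0.5):
    """Risk labels from a fitted fusion model at probability cut ``cut``."""
    return (model.predict_proba(X)[:, 1] > cut).astype(int)
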
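"""ROC/Youden analysis, TUG and TUG+ rules, logistic fusion."""

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.metrics import roc_auc_score

import gaitrisk as gr
from gaitrisk.classifiers import TugPlusRule, _candidate_cuts


def brute_force_auc(scores, labels):
    """Concordance probability by pair counting: (wins + ties/2) / (n1*n0)."""
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    wins = sum(np.sum(p > neg) + 0.5 * np.sum(p == neg) for p in pos)
    return wins / (pos.size * neg.size)


class TestRocCurve:
    def test_perfect_separation(self):
        roc = gr.roc_curve([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert roc.auc == pytest.approx(1.0)

    def test_uninformative_constant_scores(self):
        roc = gr.roc_curve([5.0] * 6, [0, 1, 0, 1, 0, 1])
        assert roc.auc == pytest.approx(0.5)

    def test_six_point_hand_example(self):
        scores = [25, 30, 21, 15, 18, 22]
        labels = [1, 1, 1, 0, 0, 0]
        roc = gr.roc_curve(scores, labels)
        assert roc.auc == pytest.approx(brute_force_auc(scores, labels))

    @pytest.mark.parametrize("seed", range(6))
    def test_auc_equals_concordance_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 8, size=30).astype(float)  # many ties
        labels = rng.integers(0, 2, size=30)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        roc = gr.roc_curve(scores, labels)
        assert roc.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
        assert roc.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            gr.roc_curve([1.0, 2.0], [1, 1])


def brute_force_youden(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    best = (-np.inf, None)
    for cut in _candidate_cuts(scores):
        pred = scores > cut
        se = np.mean(pred[labels == 1])
        sp = np.mean(~pred[labels == 0])
        j = se + sp - 1
        if j > best[0] + 1e-12:
            best = (j, cut)
    return best


class TestYoudenThreshold:
    def test_midpoint_convention_on_gap(self):
        roc = gr.roc_curve([15, 17, 19, 23, 27, 30], [0, 0, 0, 1, 1, 1])
        threshold, j = gr.youden_threshold(roc)
        assert threshold == pytest.approx(21.0)
        assert j == pytest.approx(1.0)

    def test_degenerate_scores_zero_j(self):
        roc = gr.roc_curve([5.0] * 6, [0, 1, 0, 1, 0, 1])
        _, j = gr.youden_threshold(roc)
        assert j == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(100 + seed)
        scores = np.round(rng.normal(20, 4, size=20), 1)
        labels = (scores + rng.normal(0, 4, size=20) > 20).astype(int)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        threshold, j = gr.youden_threshold(gr.roc_curve(scores, labels))
        j_brute, _ = brute_force_youden(scores, labels)
        assert j == pytest.approx(j_brute, abs=1e-12)


class TestTugClassify:
    def test_above_threshold_is_risk(self):
        assert gr.tug_classify(23.0, 22.5) == 1

    def test_below_threshold_is_no_risk(self):
        assert gr.tug_classify(19.0, 22.5) == 0

    def test_exact_threshold_is_no_risk(self):
        assert gr.tug_classify(22.5, 22.5) == 0


class TestTugPlusRule:
    rule = TugPlusRule(t_star=22.5, sd_aap_star=0.105, d_av_star=1.795)

    def test_all_negative_answers(self):
        assert gr.tugplus_classify(20.0, 0.09, 1.82, self.rule) == 0

    def test_all_positive_answers(self):
        assert gr.tugplus_classify(25.0, 0.15, 1.75, self.rule) == 1

    def test_index_positive_alone_fires_or_rule(self):
        # fast TUG but elevated SDa_ap: at risk under the checklist reading
        assert gr.tugplus_classify(20.0, 0.15, 1.82, self.rule) == 1

    def test_sequential_variant_requires_tug_positive(self):
        seq = TugPlusRule(22.5, 0.105, 1.795, combine="sequential")
        assert gr.tugplus_classify(20.0, 0.15, 1.82, seq) == 0
        assert gr.tugplus_classify(25.0, 0.15, 1.82, seq) == 1

    def test_tug_only_reduces_to_tug_classify(self):
        rng = np.random.default_rng(0)
        tug = rng.uniform(10, 35, 50)
        rule = TugPlusRule(22.5, 0.1, 1.8, combine="tug_only")
        np.testing.assert_array_equal(
            rule.evaluate(tug, rng.uniform(0, 1, 50), rng.uniform(1, 2, 50)),
            gr.tug_classify(tug, 22.5),
        )

    def test_round_trips_through_dict(self):
        d = self.rule.to_dict()
        assert TugPlusRule.from_dict(d) == self.rule


def brute_force_tugplus(X, y, t_star, combine="or"):
    tug, sd_aap, d_av = X[:, 0], X[:, 1], X[:, 2]
    best = None
    for a in _candidate_cuts(sd_aap):
        for d in _candidate_cuts(d_av):
            rule = TugPlusRule(t_star, a, d, combine=combine)
            acc = np.mean(rule.evaluate(tug, sd_aap, d_av) == y)
            if best is None or acc > best[0] + 1e-12:
                best = (acc, rule)
    return best


class TestFitTugPlus:
    def test_perfectly_separating_index_reaches_full_accuracy(self):
        rng = np.random.default_rng(1)
        n = 20
        y = np.repeat([0, 1], n // 2)
        X = np.column_stack([
            rng.uniform(15, 30, n),  # uninformative TUG
            np.where(y == 1, 0.2, 0.05) + rng.uniform(0, 0.01, n),
            rng.uniform(1.7, 1.9, n),
        ])
        rule = gr.fit_tugplus_thresholds(X, y, t_star=np.inf)
        acc = np.mean(rule.evaluate(X[:, 0], X[:, 1], X[:, 2]) == y)
        assert acc == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_grid(self, seed):
        rng = np.random.default_rng(200 + seed)
        n = 20
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        X = np.column_stack([
            rng.normal(21, 4, n),
            rng.lognormal(-2.3, 0.4, n),
            rng.normal(1.8, 0.05, n),
        ])
        rule = gr.fit_tugplus_thresholds(X, y, t_star=22.5)
        acc = np.mean(rule.evaluate(X[:, 0], X[:, 1], X[:, 2]) == y)
        best_acc, _ = brute_force_tugplus(X, y, 22.5)
        assert acc == pytest.approx(best_acc, abs=1e-12)

    def test_never_worse_than_tug_alone(self, index_table):
        y = index_table["faller"].to_numpy()
        tug = gr.TugThresholdClassifier().fit(index_table, y)
        acc_tug = np.mean(tug.predict(index_table) == y)
        plus = gr.TugPlusClassifier().fit(index_table, y)
        acc_plus = np.mean(plus.predict(index_table) == y)
        assert acc_plus >= acc_tug  # TUG lies in TUG+'s hypothesis space


class TestEstimatorProtocol:
    def test_clone_and_params(self):
        est = gr.TugPlusClassifier(t_star=22.5, combine="sequential")
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_tug_estimator_matches_functions(self, index_table):
        y = index_table["faller"].to_numpy()
        est = gr.TugThresholdClassifier().fit(index_table, y)
        roc = gr.roc_curve(index_table["tug_s"].to_numpy(), y)
        threshold, j = gr.youden_threshold(roc)
        assert est.threshold_ == threshold
        assert est.youden_j_ == j
        assert est.roc_.auc == pytest.approx(roc.auc)


class TestLogisticFusion:
    def test_null_features_give_prevalence_intercept(self):
        rng = np.random.default_rng(3)
        n = 400
        X = np.column_stack([
            rng.normal(20, 3, n), rng.lognormal(-2.3, 0.3, n), rng.normal(1.8, 0.05, n)
        ])
        y = rng.random(n) < 0.3
        model = gr.logistic_fusion_fit(X, y.astype(int))
        prev = y.mean()
        z = model.intercept_ + X.mean(axis=0) @ model.coef_
        assert z == pytest.approx(np.log(prev / (1 - prev)), abs=0.25)

    def test_predictive_feature_coefficient_sign(self):
        rng = np.random.default_rng(4)
        n = 200
        sd_aap = rng.lognormal(-2.3, 0.4, n)
        y = (np.log(sd_aap) + rng.normal(0, 0.3, n) > -2.3).astype(int)
        X = np.column_stack([rng.normal(20, 3, n), sd_aap, rng.normal(1.8, 0.05, n)])
        model = gr.logistic_fusion_fit(X, y)
        assert model.coef_[1] > 0

    def test_perfect_separation_falls_back_with_warning(self):
        X = np.column_stack([
            np.r_[np.full(10, 15.0), np.full(10, 30.0)],
            np.full(20, 0.1),
            np.full(20, 1.8),
        ])
        y = np.repeat([0, 1], 10)
        with pytest.warns(UserWarning, match="separation"):
            model = gr.logistic_fusion_fit(X, y)
        assert model.separable_
        assert np.all(np.isfinite(model.coef_))
        np.testing.assert_array_equal(model.predict(X), y)

    def test_both_fusions_improve_on_tug_alone(self, index_table):
        """Either fusion of the three features beats the bare TUG in-sample.

        The checklist and logistic fusions need not coincide on synthetic
        cohorts (the disjunctive rule can only add positives to the TUG
        answer, while the logistic reweights features freely), but both
        must recover at least the TUG-only operating accuracy.
        """
        y = index_table["faller"].to_numpy()
        tug = gr.TugThresholdClassifier().fit(index_table, y)
        acc_tug = np.mean(tug.predict(index_table) == y)
        plus = gr.TugPlusClassifier().fit(index_table, y)
        acc_tree = np.mean(plus.predict(index_table) == y)
        logit = gr.LogisticFusionClassifier().fit(index_table, y)
        acc_logit = np.mean(logit.predict(index_table) == y)
        assert acc_tree >= acc_tug
        assert acc_logit >= acc_tug
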
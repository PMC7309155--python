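"""Frame CNN: splitting, datasets, training sanity, risk aggregation."""

import hashlib

import numpy as np
import pytest

import gaitrisk as gr
from gaitrisk.cnn import CnnConfig, FrameCnnClassifier, make_frame_dataset, split_cohort
from gaitrisk.nn import Conv2D, Dense, GlobalAvgPool, MaxPool2D, Sequential, bce_loss


def tiny_records(n_per_class=4, duration=60.0):
    """Hand-built cohort: class-1 signals carry a high-frequency tone."""
    records = []
    rate = 100.0
    t = np.arange(int(duration * rate)) / rate
    for label in (0, 1):
        for i in range(n_per_class):
            rng = np.random.default_rng(10 * label + i)
            channels = {}
            for c in gr.CHANNELS:
                x = np.sin(2 * np.pi * 1.0 * t + rng.uniform(0, 6)) + 0.3 * rng.standard_normal(t.size)
                if label == 1:
                    x = x + 1.5 * np.sin(2 * np.pi * 12.0 * t + rng.uniform(0, 6))
                channels[c] = x
            records.append(
                gr.ParticipantRecord(
                    f"{'F' if label else 'N'}{i}", 20.0,
                    gr.ImuTimeSeries(t=t, sampling_rate=rate, **channels), label,
                )
            )
    return records


class TestSplitCohort:
    def test_study_layout(self, default_cohort):
        sp = split_cohort(default_cohort, seed=0)
        assert sp.n_test_fallers == 8 and sp.n_test_nonfallers == 8
        assert sp.n_train_fallers == 15 and sp.n_train_nonfallers == 42
        assert len(sp.train_ids) == 57 and len(sp.test_ids) == 16
        assert not set(sp.train_ids) & set(sp.test_ids)

    def test_deterministic_in_seed(self, default_cohort):
        a = split_cohort(default_cohort, seed=5)
        b = split_cohort(default_cohort, seed=5)
        assert a == b

    def test_zero_test_fallers(self, default_cohort):
        sp = split_cohort(default_cohort, n_test_fallers=0, seed=1)
        assert sp.n_train_fallers == 23

    def test_insufficient_class(self):
        records = tiny_records(n_per_class=2)
        with pytest.raises(ValueError):
            split_cohort(records, n_test_fallers=3, n_test_nonfallers=1)


class TestMakeFrameDataset:
    def test_counts_and_standardization(self):
        records = tiny_records(duration=60.0)
        X, y, pids, stats = make_frame_dataset(records, 20.0, 10.0)
        assert X.shape == (8 * 5, 6, 2000)  # 5 overlapping frames each
        np.testing.assert_allclose(X.mean(axis=(0, 2)), 0.0, atol=1e-4)
        np.testing.assert_allclose(X.std(axis=(0, 2)), 1.0, atol=1e-4)

    def test_frozen_stats_are_reused(self):
        records = tiny_records(duration=60.0)
        _, _, _, stats = make_frame_dataset(records[:4], 20.0, 10.0)
        X2, _, _, stats2 = make_frame_dataset(records[4:], 20.0, 20.0, stats=stats)
        assert stats2 is stats
        # standardized with foreign stats: mean need not vanish
        assert abs(X2.mean()) > 1e-6

    def test_no_participant_leakage(self, default_cohort):
        sp = split_cohort(default_cohort, seed=2)
        by_id = {r.participant_id: r for r in default_cohort}
        _, _, train_pids, _ = make_frame_dataset(
            [by_id[i] for i in sp.train_ids], 20.0, 10.0
        )
        assert set(train_pids) == set(sp.train_ids)
        assert not set(train_pids) & set(sp.test_ids)


def small_config(**over):
    base = dict(
        window_s=10.0, train_step_s=5.0,
        conv_stages=((8, 3, 7, 4, 1), (16, 3, 5, 1, 4)),
        dense_widths=(16,), epochs=12, min_epochs=4, patience=3, seed=0,
    )
    base.update(over)
    return CnnConfig(**base)


class TestTraining:
    def test_separable_tones_are_learned(self):
        records = tiny_records(duration=60.0)
        X, y, pids, _ = make_frame_dataset(records, 10.0, 5.0)
        model = FrameCnnClassifier(small_config()).fit(X, y, groups=pids)
        acc = np.mean(model.predict(X) == y)
        assert acc >= 0.95

    def test_shuffled_labels_stay_at_chance_held_out(self):
        records = tiny_records(n_per_class=6, duration=60.0)
        rng = np.random.default_rng(0)
        # shuffle labels participant-wise, keeping the classes balanced
        labels = dict(zip([r.participant_id for r in records],
                          rng.permutation([0, 1] * 6)))
        shuffled = [
            gr.ParticipantRecord(r.participant_id, r.tug_time, r.series,
                                 int(labels[r.participant_id]))
            for r in records
        ]
        held = [r for r in shuffled if r.participant_id in ("N0", "F0", "N1", "F1")]
        train = [r for r in shuffled if r not in held]
        X, y, pids, stats = make_frame_dataset(train, 10.0, 5.0)
        model = FrameCnnClassifier(small_config()).fit(X, y, groups=pids)
        Xh, yh, _, _ = make_frame_dataset(held, 10.0, 10.0, stats=stats)
        acc = np.mean(model.predict(Xh) == yh)
        assert 0.2 <= acc <= 0.8  # labels carry no signal to generalize

    def test_same_seed_identical_weights(self):
        records = tiny_records(duration=60.0)
        X, y, pids, _ = make_frame_dataset(records, 10.0, 5.0)
        def checksum():
            m = FrameCnnClassifier(small_config()).fit(X, y, groups=pids)
            h = hashlib.sha256()
            for arr in m.model_.state():
                h.update(arr.tobytes())
            return h.hexdigest()
        assert checksum() == checksum()

    def test_single_class_rejected(self):
        X = np.zeros((10, 6, 1000), dtype=np.float32)
        with pytest.raises(ValueError):
            FrameCnnClassifier(small_config()).fit(X, np.zeros(10, dtype=int))


class TestGradients:
    def test_numeric_gradient_of_small_network(self):
        """Backprop agrees with central finite differences."""
        rng = np.random.default_rng(0)
        model = Sequential([
            Conv2D(1, 2, 2, 3, rng), MaxPool2D(1, 2), GlobalAvgPool(),
            Dense(2, 1, rng),
        ])
        x = rng.standard_normal((3, 1, 3, 8)).astype(np.float32)
        y = np.array([0, 1, 1])

        def loss_value():
            from scipy.special import expit
            p = expit(model.forward(x, train=True).ravel().astype(np.float64))
            l, _ = bce_loss(p.astype(np.float32), y)
            return l

        from scipy.special import expit
        z = model.forward(x, train=True).ravel()
        p = expit(z.astype(np.float64)).astype(np.float32)
        l0, grad = bce_loss(p, y)
        dz = (grad.astype(np.float64) * p * (1 - p)).astype(np.float32)
        model.backward(dz.reshape(-1, 1))

        layer = model.layers[0]
        eps = 1e-3
        for idx in [(0, 0, 0, 0), (1, 0, 1, 2)]:
            w0 = layer.w[idx]
            layer.w[idx] = w0 + eps
            lp = loss_value()
            layer.w[idx] = w0 - eps
            lm = loss_value()
            layer.w[idx] = w0
            numeric = (lp - lm) / (2 * eps)
            assert layer.dw[idx] == pytest.approx(numeric, abs=5e-3)


class TestParticipantRisk:
    class StubModel:
        def __init__(self, scores):
            self._scores = np.asarray(scores, dtype=float)

        def predict_proba(self, frames):
            return self._scores[: len(frames)]

    def test_mean_and_strict_threshold(self):
        model = self.StubModel([0.2, 0.4, 0.9])
        score, risk = gr.participant_risk(model, np.zeros((3, 6, 10)))
        assert score == pytest.approx(0.5)
        assert risk == 0  # exactly 0.5 is not risk

    def test_high_scores_flag_risk(self):
        model = self.StubModel([0.9, 0.9, 0.9, 0.9])
        score, risk = gr.participant_risk(model, np.zeros((4, 6, 10)))
        assert score == pytest.approx(0.9)
        assert risk == 1

    def test_frame_order_invariance(self):
        rng = np.random.default_rng(1)
        scores = rng.random(10)
        model = self.StubModel(scores)
        s1, _ = gr.participant_risk(model, np.zeros((10, 6, 10)))
        model2 = self.StubModel(scores[::-1])
        s2, _ = gr.participant_risk(model2, np.zeros((10, 6, 10)))
        assert s1 == pytest.approx(s2)

    def test_no_frames_rejected(self):
        with pytest.raises(ValueError):
            gr.participant_risk(self.StubModel([1.0]), np.zeros((0, 6, 10)))

    def test_constant_positive_model_plumbing(self):
        """A model pinned at score 1 must evaluate to Se = 1, Sp = 0."""
        model = self.StubModel(np.ones(100))
        truth, preds = [], []
        for label in (1, 1, 0, 0, 0):
            _, risk = gr.participant_risk(model, np.zeros((5, 6, 10)))
            preds.append(risk)
            truth.append(label)
        _, metrics = gr.evaluate_classifier(preds, truth)
        assert metrics.se == 1.0
        assert metrics.sp == 0.0


class TestModelPersistence:
    def test_save_load_round_trip(self, tmp_path):
        records = tiny_records(duration=60.0)
        X, y, pids, stats = make_frame_dataset(records, 10.0, 5.0)
        model = FrameCnnClassifier(small_config(epochs=4, min_epochs=2)).fit(X, y, groups=pids)
        model.save(tmp_path / "model", stats=stats)
        loaded, stats2 = FrameCnnClassifier.load(tmp_path / "model")
        np.testing.assert_allclose(loaded.predict_proba(X), model.predict_proba(X), atol=1e-6)
        np.testing.assert_allclose(stats2[0], stats[0])
        assert loaded.config.window_s == model.config.window_s


class TestSklearnInterop:
    def test_cross_validation_of_threshold_classifiers(self, index_table):
        """The estimators drop into sklearn model selection unchanged."""
        from sklearn.model_selection import StratifiedKFold, cross_val_score

        y = index_table["faller"].to_numpy()
        X = index_table[["tug_s", "SDa_ap", "Da_v"]].to_numpy()
        cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=0)
        for est in (gr.TugThresholdClassifier(), gr.TugPlusClassifier()):
            scores = cross_val_score(est, X, y, cv=cv)
            assert scores.shape == (3,)
            assert np.all((scores >= 0.0) & (scores <= 1.0))
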
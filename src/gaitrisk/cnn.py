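"""Frame-level CNN risk classifier and the end-to-end AI experiment.

The raw six-channel signal is cut into fixed-duration frames (default 20 s,
overlapping by half during training only), standardized per channel with
statistics frozen on the training participants, and fed to a small 2-D
convolutional network (channels x time, one input map) ending in a
sigmoid. A participant's risk of fall is the arithmetic mean of the scores
of all their frames; a mean strictly greater than 0.5 labels the
participant at risk.

Splits are participant-wise — every frame of a participant falls on one
side of the train/test divide — so frame-level training cannot leak
test-participant signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import ParticipantRecord
from .io import split_frames
from .metrics import ConfusionMatrix, DiagnosticMetrics, evaluate_classifier
from .nn import Adam, Conv2D, Dense, Flatten, GlobalAvgPool, MaxPool2D, ReLU, Sequential, Sigmoid, bce_loss

__all__ = [
    "CnnConfig",
    "CohortSplit",
    "split_cohort",
    "make_frame_dataset",
    "FrameCnnClassifier",
    "train_cnn",
    "participant_risk",
    "run_ai_experiment",
    "AiExperimentResult",
]


@dataclass(frozen=True)
class CnnConfig:
    """Architecture and training settings of the frame classifier.

    ``conv_stages`` is a tuple of (n_filters, kernel_height, kernel_width,
    time_stride, time_pool) stages; kernel heights shrink as pooling is
    only applied along time and the channel axis is consumed by the
    convolutions. The first stage strides by 4 samples (40 ms at 100 Hz,
    with a kernel wide enough to overlap) so deeper stages work at a
    manageable resolution. The defaults are the smallest topology honouring
    "a few conv stages into a three-layer dense head" that trains in
    minutes on one CPU core.
    """

    window_s: float = 20.0
    train_step_s: float = 10.0
    conv_stages: tuple = ((8, 3, 7, 4, 1), (16, 3, 5, 1, 4), (32, 2, 5, 1, 4))
    dense_widths: tuple = (64, 16)
    learning_rate: float = 3e-3
    epochs: int = 40
    batch_size: int = 32
    patience: int = 5
    min_epochs: int = 15
    val_fraction: float = 0.15
    class_weighting: bool = True
    global_pool: bool = True
    weight_decay: float = 1e-4
    calibrate_bias: bool = True
    seed: int = 0


@dataclass(frozen=True)
class CohortSplit:
    """Participant-wise train/test partition."""

    train_ids: tuple
    test_ids: tuple
    n_train_fallers: int
    n_train_nonfallers: int
    n_test_fallers: int
    n_test_nonfallers: int


def split_cohort(
    cohort: list[ParticipantRecord],
    n_test_fallers: int = 8,
    n_test_nonfallers: int = 8,
    seed=0,
) -> CohortSplit:
    """Randomly reserve a balanced test set; the remainder trains.

    Sampling is without replacement and deterministic in ``seed``.
    """
    fallers = [r.participant_id for r in cohort if r.faller == 1]
    nonfallers = [r.participant_id for r in cohort if r.faller == 0]
    if len(fallers) < n_test_fallers or len(nonfallers) < n_test_nonfallers:
        raise ValueError("not enough participants in a class for the requested test set")
    rng = np.random.default_rng(seed)
    test_f = set(rng.choice(fallers, size=n_test_fallers, replace=False))
    test_n = set(rng.choice(nonfallers, size=n_test_nonfallers, replace=False))
    test = test_f | test_n
    train_ids = tuple(r.participant_id for r in cohort if r.participant_id not in test)
    test_ids = tuple(r.participant_id for r in cohort if r.participant_id in test)
    return CohortSplit(
        train_ids=train_ids,
        test_ids=test_ids,
        n_train_fallers=len(fallers) - n_test_fallers,
        n_train_nonfallers=len(nonfallers) - n_test_nonfallers,
        n_test_fallers=n_test_fallers,
        n_test_nonfallers=n_test_nonfallers,
    )


def make_frame_dataset(
    participants: list[ParticipantRecord],
    window_s: float,
    step_s: float,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, list, tuple[np.ndarray, np.ndarray]]:
    """Frames, labels and participant ids, standardized per channel.

    ``stats`` is a (mean, sd) pair per channel. Pass None on the training
    set (statistics are computed and returned) and the returned training
    stats on validation/test data, so no test information enters the
    standardization.
    """
    frames, labels, pids = [], [], []
    for rec in participants:
        for fr in split_frames(rec.series, window_s, step_s, rec.participant_id, rec.faller):
            frames.append(fr.data)
            labels.append(fr.label)
            pids.append(fr.participant_id)
    if not frames:
        raise ValueError("no frames produced; recordings shorter than the window?")
    X = np.asarray(frames, dtype=np.float32)
    y = np.asarray(labels, dtype=np.int64)
    if stats is None:
        mean = X.mean(axis=(0, 2))
        sd = X.std(axis=(0, 2))
        sd[sd == 0] = 1.0
        stats = (mean, sd)
    mean, sd = stats
    X = (X - mean[None, :, None]) / sd[None, :, None]
    return X, y, pids, stats


def _build_model(config: CnnConfig, n_channels: int, n_samples: int, rng) -> Sequential:
    layers: list = []
    c_in, h, w = 1, n_channels, n_samples
    for n_filters, kh, kw, stride_w, pool_w in config.conv_stages:
        kh = min(kh, h)
        layers.append(Conv2D(c_in, n_filters, kh, kw, rng, stride_w=stride_w))
        h, w = h - kh + 1, (w - kw) // stride_w + 1
        layers.append(ReLU())
        if pool_w > 1:
            layers.append(MaxPool2D(1, pool_w))
            w = w // pool_w
        c_in = n_filters
        if w < 1 or h < 1:
            raise ValueError("frame too short for the configured conv stages")
    if config.global_pool:
        layers.append(GlobalAvgPool())
        n_feat = c_in
    else:
        layers.append(Flatten())
        n_feat = c_in * h * w
    for width in config.dense_widths:
        layers.append(Dense(n_feat, width, rng))
        layers.append(ReLU())
        n_feat = width
    layers.append(Dense(n_feat, 1, rng))
    layers.append(Sigmoid())
    return Sequential(layers)


class FrameCnnClassifier:
    """Small CNN scoring 20-s frames of standardized 6-channel signal.

    scikit-learn style: ``fit(X, y)`` with X of shape (n_frames, 6,
    window samples), then ``predict_proba`` / ``predict``. Training is
    deterministic given ``config.seed``. Early stopping monitors
    cross-entropy on a participant-wise validation fold carved from the
    training frames when ``groups`` are supplied (frame-wise otherwise),
    restoring the best weights.
    """

    def __init__(self, config: CnnConfig | None = None):
        self.config = config if config is not None else CnnConfig()

    def get_params(self, deep=True):
        return {"config": self.config}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y, groups=None):
        cfg = self.config
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.int64)
        if X.ndim != 3:
            raise ValueError("X must be (n_frames, n_channels, n_samples)")
        if len(np.unique(y)) < 2:
            raise ValueError("training frames must contain both classes")
        rng = np.random.default_rng(cfg.seed)
        n, c, w = X.shape
        self.input_shape_ = (c, w)
        self.model_ = _build_model(cfg, c, w, rng)

        train_idx, val_idx = self._validation_split(y, groups, rng)
        if cfg.class_weighting:
            n_pos = max(1, int(np.sum(y[train_idx] == 1)))
            n_neg = max(1, int(np.sum(y[train_idx] == 0)))
            self.pos_weight_ = n_neg / n_pos
        else:
            self.pos_weight_ = 1.0
        Xin = X[:, None, :, :]  # one input map
        best_state, best_val, wait = None, np.inf, 0
        self.history_ = []
        opt = Adam(self.model_, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
        for epoch in range(cfg.epochs):
            order = rng.permutation(train_idx)
            for start in range(0, order.size, cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                p = self.model_.forward(Xin[batch], train=True).ravel()
                if not np.all(np.isfinite(p)):
                    raise FloatingPointError("non-finite activations during training")
                loss, grad = bce_loss(p, y[batch], pos_weight=self.pos_weight_)
                if not np.isfinite(loss):
                    raise FloatingPointError("non-finite training loss")
                self.model_.backward(grad.reshape(-1, 1))
                opt.step()
            val_loss = self._dataset_loss(Xin[val_idx], y[val_idx])
            self.history_.append(val_loss)
            if val_loss < best_val - 1e-4:
                best_val, best_state, wait = val_loss, self.model_.state(), 0
            elif epoch + 1 >= cfg.min_epochs:
                wait += 1
                if wait >= cfg.patience:
                    break
        if best_state is not None:
            self.model_.load_state(best_state)
        self.n_epochs_ = len(self.history_)
        if cfg.calibrate_bias and groups is not None:
            self._calibrate_output_bias(X, y, np.asarray(groups), val_idx)
        return self

    def _calibrate_output_bias(self, X, y, groups, val_idx) -> None:
        """Center frame scores so 0.5 is the balanced participant cut.

        Mean frame scores drift with class imbalance and random
        initialization; the published decision rule (participant mean
        score strictly above 0.5) assumes centered scores. The midpoint
        between the two classes' mean participant scores on the
        early-stopping validation fold — training-side data only — is
        mapped to 0.5 by shifting the final pre-sigmoid bias.
        """
        scores = self.predict_proba(X[val_idx])
        yv, gv = y[val_idx], groups[val_idx]
        per_pid = {}
        for pid in np.unique(gv):
            sel = gv == pid
            per_pid[pid] = (float(scores[sel].mean()), int(yv[sel][0]))
        m1 = np.mean([s for s, lab in per_pid.values() if lab == 1])
        m0 = np.mean([s for s, lab in per_pid.values() if lab == 0])
        center = float(np.clip(0.5 * (m0 + m1), 0.05, 0.95))
        delta = -np.log(center / (1.0 - center))
        final_dense = [l for l in self.model_.layers if hasattr(l, "b")][-1]
        final_dense.b = final_dense.b + np.float32(delta)
        self.bias_shift_ = float(delta)

    def _validation_split(self, y, groups, rng):
        idx = np.arange(y.size)
        if groups is None:
            perm = rng.permutation(idx)
            n_val = max(1, int(round(self.config.val_fraction * y.size)))
            return perm[n_val:], perm[:n_val]
        groups = np.asarray(groups)
        val_groups = []
        for label in (0, 1):
            g = np.unique(groups[y == label])
            n_val = max(1, int(round(self.config.val_fraction * g.size)))
            val_groups.extend(rng.choice(g, size=n_val, replace=False))
        val_mask = np.isin(groups, val_groups)
        if val_mask.all() or not val_mask.any():
            raise ValueError("validation fold degenerate; too few participants")
        return idx[~val_mask], idx[val_mask]

    def _dataset_loss(self, Xin, y, batch: int = 256) -> float:
        losses, weights = [], []
        for start in range(0, y.size, batch):
            p = self.model_.forward(Xin[start : start + batch]).ravel()
            loss, _ = bce_loss(p, y[start : start + batch], pos_weight=self.pos_weight_)
            losses.append(loss)
            weights.append(p.size)
        return float(np.average(losses, weights=weights))

    def predict_proba(self, X, batch: int = 256) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        out = []
        for start in range(0, X.shape[0], batch):
            out.append(self.model_.forward(X[start : start + batch, None, :, :]).ravel())
        return np.concatenate(out).astype(float)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) > 0.5).astype(int)

    def save(self, model_dir, stats=None) -> None:
        """Persist config, weights and (optionally) standardization stats.

        Writes ``config.json``, ``weights.npz`` and ``stats.npz`` into
        ``model_dir`` so a trained model can score new recordings later.
        """
        import json
        from pathlib import Path

        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": self.config.__dict__,
            "n_channels": int(self.input_shape_[0]),
            "n_samples": int(self.input_shape_[1]),
        }
        (model_dir / "config.json").write_text(json.dumps(meta, indent=2))
        np.savez(model_dir / "weights.npz",
                 **{f"p{i}": arr for i, arr in enumerate(self.model_.state())})
        if stats is not None:
            np.savez(model_dir / "stats.npz", mean=stats[0], sd=stats[1])

    @classmethod
    def load(cls, model_dir):
        """Rebuild a saved model; returns (classifier, stats-or-None)."""
        import json
        from pathlib import Path

        model_dir = Path(model_dir)
        meta = json.loads((model_dir / "config.json").read_text())
        cfg_dict = dict(meta["config"])
        cfg_dict["conv_stages"] = tuple(tuple(s) for s in cfg_dict["conv_stages"])
        cfg_dict["dense_widths"] = tuple(cfg_dict["dense_widths"])
        clf = cls(CnnConfig(**cfg_dict))
        rng = np.random.default_rng(0)  # weights are overwritten below
        clf.model_ = _build_model(clf.config, meta["n_channels"], meta["n_samples"], rng)
        clf.input_shape_ = (meta["n_channels"], meta["n_samples"])
        with np.load(model_dir / "weights.npz") as z:
            clf.model_.load_state([z[f"p{i}"] for i in range(len(z.files))])
        stats = None
        stats_path = model_dir / "stats.npz"
        if stats_path.exists():
            with np.load(stats_path) as z:
                stats = (z["mean"], z["sd"])
        return clf, stats


def train_cnn(X, y, config: CnnConfig | None = None, groups=None) -> FrameCnnClassifier:
    """Train the frame classifier; thin functional wrapper."""
    return FrameCnnClassifier(config).fit(X, y, groups=groups)


def participant_risk(model: FrameCnnClassifier, frames: np.ndarray) -> tuple[float, int]:
    """Mean frame score and the resulting binary risk (strictly > 0.5)."""
    frames = np.asarray(frames, dtype=np.float32)
    if frames.shape[0] < 1:
        raise ValueError("participant has no frames")
    mean_score = float(np.mean(model.predict_proba(frames)))
    return mean_score, int(mean_score > 0.5)


@dataclass
class AiExperimentResult:
    split: CohortSplit
    scores: dict  # participant id -> mean frame score (test set)
    predictions: dict  # participant id -> 0/1 risk
    confusion: ConfusionMatrix
    metrics: DiagnosticMetrics
    model: FrameCnnClassifier
    stats: tuple = field(repr=False, default=())


def run_ai_experiment(
    cohort: list[ParticipantRecord],
    config: CnnConfig | None = None,
    seed: int = 0,
    n_test_fallers: int = 8,
    n_test_nonfallers: int = 8,
) -> AiExperimentResult:
    """Full pipeline: split, frame, train, aggregate, evaluate.

    Training frames overlap (``train_step_s``); test frames are
    non-overlapping (step = window). ``seed`` drives the split and, offset
    by it, the network initialization and batching.
    """
    config = config if config is not None else CnnConfig()
    split = split_cohort(cohort, n_test_fallers, n_test_nonfallers, seed=seed)
    by_id = {r.participant_id: r for r in cohort}
    train = [by_id[i] for i in split.train_ids]
    test = [by_id[i] for i in split.test_ids]

    Xtr, ytr, gtr, stats = make_frame_dataset(train, config.window_s, config.train_step_s)
    cfg = CnnConfig(**{**config.__dict__, "seed": config.seed + seed})
    model = FrameCnnClassifier(cfg).fit(Xtr, ytr, groups=gtr)

    scores, predictions, truth = {}, {}, []
    for rec in test:
        Xp, _, _, _ = make_frame_dataset([rec], config.window_s, config.window_s, stats=stats)
        s, r = participant_risk(model, Xp)
        scores[rec.participant_id] = s
        predictions[rec.participant_id] = r
        truth.append(rec.faller)
    cm, metrics = evaluate_classifier([predictions[r.participant_id] for r in test], truth)
    return AiExperimentResult(
        split=split, scores=scores, predictions=predictions,
        confusion=cm, metrics=metrics, model=model, stats=stats,
    )
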
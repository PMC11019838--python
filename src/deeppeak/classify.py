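"""Peak classification: a small 1-D CNN and the cascade-of-ten ensemble.

The classifier maps a 297-point scatter feature vector to a cluster
probability.  The network is six (convolution + max-pool) blocks, one
additional max-pool, and a fully connected sigmoid head.  Class
imbalance (clusters are rare) is handled in the loss: a weighted binary
cross-entropy mixed with the focal Tversky loss, not by resampling.

The cascade trains up to ten networks where each successive network
sees only the previous stage's hard examples — its training-set
FP + FN + TP events, with the confidently rejected true negatives
dropped — so later stages learn new boundaries between hard-to-discern
NC and cluster peaks.  At prediction time every example enters stage 1
and only predicted positives advance, so the predicted-positive set
shrinks weakly with depth: purity rises while sensitivity falls.

Estimators follow scikit-learn conventions (``fit`` / ``predict`` /
``get_params``) and compose with sklearn model selection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.utils.validation import check_is_fitted

from ._nn import Adam, ConvNet1D, combined_loss_with_logits, sigmoid
from .featurize import N_FEATURES


@dataclass
class TrainConfig:
    """Training schedule and loss hyperparameters.

    ``positive_class_weight=None`` recomputes N_neg / N_pos per training
    set.  Tversky ``alpha`` penalizes false negatives, ``beta`` false
    positives (alpha + beta = 1); ``gamma`` is the focal exponent;
    ``loss_mix`` interpolates weighted BCE (1.0) and focal Tversky (0.0).
    """

    learning_rate: float = 1e-3
    max_epochs: int = 15
    early_stop_patience: int = 7
    positive_class_weight: float | None = None
    tversky_alpha: float = 0.7
    tversky_beta: float = 0.3
    tversky_gamma: float = 0.75
    loss_mix: float = 0.5
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(self.tversky_alpha + self.tversky_beta, 1.0):
            raise ValueError("tversky_alpha + tversky_beta must equal 1")
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("early_stop_patience must be below max_epochs")
        if self.positive_class_weight is not None and self.positive_class_weight <= 0:
            raise ValueError("positive_class_weight must be positive")


def combined_loss(
    scores: np.ndarray,
    labels: np.ndarray,
    pos_weight: float = 1.0,
    alpha: float = 0.7,
    beta: float = 0.3,
    gamma: float = 0.75,
    loss_mix: float = 0.5,
) -> float:
    """Weighted BCE + focal Tversky loss on probability scores.

    ``loss = loss_mix * weighted_BCE + (1 - loss_mix) * (1 - TI)^gamma``
    with the Tversky index TI computed on soft scores over the batch.
    """
    p = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.size == 0:
        raise ValueError("empty batch")
    if np.any((p <= 0) | (p >= 1)):
        p = np.clip(p, 1e-12, 1 - 1e-12)
    logits = np.log(p / (1 - p))
    loss, _ = combined_loss_with_logits(
        logits, y, pos_weight, alpha, beta, gamma, loss_mix
    )
    return loss


class EarlyStopper:
    """Early stopping on validation F1, ties broken by lower validation loss."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best_f1 = -np.inf
        self.best_loss = np.inf
        self.stale = 0
        self.best_epoch = 0

    def update(self, f1: float, loss: float, epoch: int) -> bool:
        improved = f1 > self.best_f1 or (f1 == self.best_f1 and loss < self.best_loss)
        if improved:
            self.best_f1, self.best_loss, self.best_epoch = f1, loss, epoch
            self.stale = 0
        else:
            self.stale += 1
        return improved

    @property
    def should_stop(self) -> bool:
        return self.stale >= self.patience


def _binary_f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


class PeakCNNClassifier(BaseEstimator, ClassifierMixin):
    """1-D CNN scoring 297-point scatter windows as cluster / non-cluster.

    Parameters mirror :class:`TrainConfig`; ``channels`` are the feature
    maps of the six convolutional blocks and ``kernel_size`` their
    shared kernel width.  Training runs at most ``max_epochs`` epochs of
    Adam at ``learning_rate`` and stops early when validation F1 fails
    to improve for ``early_stop_patience`` epochs, restoring the
    best-validation weights.  Fully deterministic given ``random_state``.
    """

    def __init__(
        self,
        channels: tuple[int, ...] = (8, 16, 32, 32, 32, 32),
        kernel_size: int = 3,
        learning_rate: float = 1e-3,
        max_epochs: int = 15,
        early_stop_patience: int = 7,
        positive_class_weight: float | None = None,
        tversky_alpha: float = 0.7,
        tversky_beta: float = 0.3,
        tversky_gamma: float = 0.75,
        loss_mix: float = 0.5,
        batch_size: int = 64,
        threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.channels = channels
        self.kernel_size = kernel_size
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.positive_class_weight = positive_class_weight
        self.tversky_alpha = tversky_alpha
        self.tversky_beta = tversky_beta
        self.tversky_gamma = tversky_gamma
        self.loss_mix = loss_mix
        self.batch_size = batch_size
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X, y, validation_data: tuple[np.ndarray, np.ndarray] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[1] != N_FEATURES:
            raise ValueError(f"expected (n, {N_FEATURES}) feature matrix, got {X.shape}")
        present = set(np.unique(y))
        for cls, name in ((1, "CTCC"), (0, "NC")):
            if cls not in present:
                raise ValueError(f"training set contains no {name} examples")
        if validation_data is None:
            X_val, y_val = X, y
        else:
            X_val = np.asarray(validation_data[0], dtype=float)
            y_val = np.asarray(validation_data[1], dtype=int)

        pos_weight = self.positive_class_weight
        if pos_weight is None:
            pos_weight = float(np.sum(y == 0)) / float(np.sum(y == 1))

        rng = np.random.default_rng(self.random_state)
        net = ConvNet1D(N_FEATURES, tuple(self.channels), self.kernel_size, rng)
        opt = Adam(net.params, lr=self.learning_rate)
        stopper = EarlyStopper(self.early_stop_patience)
        best_state = net.get_state()
        history = {"epoch": [], "train_loss": [], "val_loss": [], "val_f1": []}

        n = len(X)
        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                logits = net.forward(X[idx])
                loss, dz = combined_loss_with_logits(
                    logits, y[idx], pos_weight, self.tversky_alpha,
                    self.tversky_beta, self.tversky_gamma, self.loss_mix,
                )
                net.backward(dz)
                opt.step(net.grads)
                epoch_loss += loss * len(idx)
            epoch_loss /= n

            val_logits = self._forward_batched(net, X_val)
            val_loss, _ = combined_loss_with_logits(
                val_logits, y_val, pos_weight, self.tversky_alpha,
                self.tversky_beta, self.tversky_gamma, self.loss_mix,
            )
            val_pred = (sigmoid(val_logits) >= self.threshold).astype(int)
            val_f1 = _binary_f1(y_val, val_pred)
            history["epoch"].append(epoch)
            history["train_loss"].append(epoch_loss)
            history["val_loss"].append(float(val_loss))
            history["val_f1"].append(val_f1)
            if stopper.update(val_f1, float(val_loss), epoch):
                best_state = net.get_state()
            if stopper.should_stop:
                break

        net.set_state(best_state)
        self.network_ = net
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = N_FEATURES
        self.pos_weight_ = pos_weight
        self.history_ = history
        self.best_epoch_ = stopper.best_epoch
        self.n_epochs_ = len(history["epoch"])
        return self

    @staticmethod
    def _forward_batched(net: ConvNet1D, X: np.ndarray, chunk: int = 1024) -> np.ndarray:
        outs = [net.forward(X[i : i + chunk]) for i in range(0, len(X), chunk)]
        return np.concatenate(outs) if outs else np.empty(0)

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != N_FEATURES:
            raise ValueError(f"expected (n, {N_FEATURES}) feature matrix, got {X.shape}")
        return self._forward_batched(self.network_, X)

    def predict_proba(self, X) -> np.ndarray:
        p = sigmoid(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(int)


class CascadeClassifier(BaseEstimator, ClassifierMixin):
    """Predicted-positive-pass-through cascade of up to ten networks.

    Stage k+1 trains on stage k's training-set TP u FP u FN (true
    negatives dropped); the positive class weight is recomputed per
    stage.  The cascade truncates with a warning if a stage's surviving
    training set becomes single-class.  Prediction is positive only if
    every stage votes positive; :meth:`predict_audit` also reports the
    stage at which each rejected example was dropped.
    """

    def __init__(self, estimator=None, n_stages: int = 10, random_state: int = 0):
        self.estimator = estimator
        self.n_stages = n_stages
        self.random_state = random_state

    def fit(self, X, y, validation_data=None):
        if not 1 <= self.n_stages <= 10:
            raise ValueError("n_stages must be in [1, 10]")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        proto = self.estimator if self.estimator is not None else PeakCNNClassifier()
        self.stages_ = []
        self.stage_train_sizes_ = []
        self.stage_positive_fraction_ = []
        idx = np.arange(len(y))
        for k in range(self.n_stages):
            yk = y[idx]
            if len(np.unique(yk)) < 2:
                warnings.warn(
                    f"stage {k + 1} training set is single-class; "
                    f"cascade truncated at {k} stage(s)"
                )
                break
            stage = clone(proto)
            if hasattr(stage, "random_state"):
                stage.set_params(random_state=self.random_state + k)
            if _accepts_validation(stage):
                stage.fit(X[idx], yk, validation_data=validation_data)
            else:
                stage.fit(X[idx], yk)
            self.stages_.append(stage)
            self.stage_train_sizes_.append(len(idx))
            self.stage_positive_fraction_.append(float(np.mean(yk)))
            pred = stage.predict(X[idx])
            keep = ~((pred == 0) & (yk == 0))  # drop the true negatives only
            idx = idx[keep]
        if not self.stages_:
            raise ValueError("cascade has no trainable stage (single-class data)")
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def predict_audit(
        self, X, max_stages: int | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Predictions plus the 1-based stage at which each example was
        rejected (0 = survived every stage)."""
        check_is_fitted(self, "stages_")
        X = np.asarray(X, dtype=float)
        stages = self.stages_[: max_stages or len(self.stages_)]
        active = np.ones(len(X), dtype=bool)
        dropped_at = np.zeros(len(X), dtype=int)
        for k, stage in enumerate(stages, start=1):
            if not active.any():
                break
            pred = stage.predict(X[active])
            rejected = np.flatnonzero(active)[pred == 0]
            dropped_at[rejected] = k
            active[rejected] = False
        return active.astype(int), dropped_at

    def predict(self, X, max_stages: int | None = None) -> np.ndarray:
        return self.predict_audit(X, max_stages=max_stages)[0]


def _accepts_validation(estimator) -> bool:
    import inspect

    try:
        return "validation_data" in inspect.signature(estimator.fit).parameters
    except (TypeError, ValueError):
        return False


def _classifier_from_config(config: TrainConfig, random_state: int) -> PeakCNNClassifier:
    return PeakCNNClassifier(
        learning_rate=config.learning_rate,
        max_epochs=config.max_epochs,
        early_stop_patience=config.early_stop_patience,
        positive_class_weight=config.positive_class_weight,
        tversky_alpha=config.tversky_alpha,
        tversky_beta=config.tversky_beta,
        tversky_gamma=config.tversky_gamma,
        loss_mix=config.loss_mix,
        batch_size=config.batch_size,
        random_state=random_state,
    )


def train_one(
    train_examples: tuple[np.ndarray, np.ndarray],
    val_examples: tuple[np.ndarray, np.ndarray],
    config: TrainConfig | None = None,
) -> PeakCNNClassifier:
    """Train a single network on (X, y) pairs with validation monitoring."""
    config = config or TrainConfig()
    clf = _classifier_from_config(config, config.seed)
    return clf.fit(*train_examples, validation_data=val_examples)


def train_cascade(
    train_examples: tuple[np.ndarray, np.ndarray],
    val_examples: tuple[np.ndarray, np.ndarray] | None = None,
    config: TrainConfig | None = None,
    n_models: int = 10,
) -> CascadeClassifier:
    """Train the pass-through cascade (up to ten networks)."""
    config = config or TrainConfig()
    cascade = CascadeClassifier(
        estimator=_classifier_from_config(config, config.seed),
        n_stages=n_models,
        random_state=config.seed,
    )
    return cascade.fit(*train_examples, validation_data=val_examples)


def predict_cascade(
    ensemble: CascadeClassifier, X: np.ndarray, max_stages: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Final labels and the per-stage rejection audit."""
    return ensemble.predict_audit(X, max_stages=max_stages)


def save_cascade(cascade: CascadeClassifier, directory: str | Path) -> None:
    """Serialize stage weights (npz) with a JSON sidecar of the settings."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {"n_stages": len(cascade.stages_), "stages": []}
    for k, stage in enumerate(cascade.stages_):
        arrays = {f"p{i}": p for i, p in enumerate(stage.network_.params)}
        np.savez(directory / f"stage{k}.npz", **arrays)
        meta["stages"].append(
            {"params": stage.get_params(), "pos_weight": stage.pos_weight_}
        )
    (directory / "cascade.json").write_text(json.dumps(meta, indent=2, default=str))


def load_cascade(directory: str | Path) -> CascadeClassifier:
    directory = Path(directory)
    meta = json.loads((directory / "cascade.json").read_text())
    cascade = CascadeClassifier(n_stages=max(1, meta["n_stages"]))
    cascade.stages_ = []
    for k, stage_meta in enumerate(meta["stages"]):
        params = stage_meta["params"]
        # tuple-valued params round-trip through JSON as strings/lists
        chan = params.get("channels", (8, 16, 32, 32, 32, 32))
        if isinstance(chan, str):
            chan = tuple(int(c) for c in chan.strip("()").split(",") if c.strip())
        elif isinstance(chan, list):
            chan = tuple(chan)
        clf = PeakCNNClassifier(
            channels=chan,
            kernel_size=int(params.get("kernel_size", 3)),
            threshold=float(params.get("threshold", 0.5)),
        )
        rng = np.random.default_rng(0)
        clf.network_ = ConvNet1D(N_FEATURES, chan, clf.kernel_size, rng)
        data = np.load(directory / f"stage{k}.npz")
        clf.network_.set_state([data[f"p{i}"] for i in range(len(data.files))])
        clf.classes_ = np.array([0, 1])
        clf.n_features_in_ = N_FEATURES
        clf.pos_weight_ = float(stage_meta["pos_weight"])
        cascade.stages_.append(clf)
    cascade.classes_ = np.array([0, 1])
    cascade.n_features_in_ = N_FEATURES
    return cascade
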
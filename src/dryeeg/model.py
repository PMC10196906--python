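"""1-D CNN clean-vs-artifact classifier with transfer learning.

``CNNClassifier`` is a scikit-learn-style estimator over the NumPy engine in
:mod:`dryeeg.nn`. It maps a 200-sample single-channel window to a clean
probability, trains with AdamW under a cosine-annealed learning rate by
minimizing binary cross-entropy against soft targets, and stops early when
the validation loss has not improved for a fixed number of epochs.

Transfer learning follows the usual recipe: train on a source domain, then
re-initialize the final dense layer from scratch and continue training every
layer on the target domain (``fit(..., init_from=..., reinit_head=True)``).
The module-level ``build_cnn`` / ``pretrain`` / ``fine_tune`` /
``predict_scores`` functions are thin wrappers over the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn


@dataclass
class ModelSpec:
    """Architecture of the 1-D CNN.

    Three convolution blocks (convolution, ReLU, batch normalization,
    max-pool 2), global average pooling, one hidden dense layer, and a single
    logistic output score.
    """

    channels: tuple[int, ...] = (16, 32, 64)
    kernel_size: int = 7
    pool: int = 2
    head_units: int = 64
    input_len: int = 200


@dataclass
class TrainConfig:
    """Optimization hyperparameters for pretraining and fine-tuning."""

    lr: float = 1e-3
    weight_decay: float = 0.01
    batch_size: int = 256
    max_epochs: int = 100
    patience: int = 10
    soft_targets: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr < 0 or self.weight_decay < 0:
            raise ValueError("lr and weight_decay must be non-negative")
        if min(self.batch_size, self.max_epochs) <= 0:
            raise ValueError("batch_size and max_epochs must be positive")
        if not self.patience < self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


class CNNClassifier(ClassifierMixin, BaseEstimator):
    """Clean-vs-artifact 1-D CNN, scikit-learn estimator interface.

    Parameters mirror :class:`ModelSpec` and :class:`TrainConfig`. ``X`` is
    an (n_segments, input_len) array of microvolt samples; ``y`` holds soft
    labels in [0,1] (fraction of reviewers voting clean). ``predict`` applies
    a 0.5 cutoff; calibrated operating thresholds live in
    :mod:`dryeeg.calibrate`.

    Amplitude carries the main artifact signal, so inputs are scaled by a
    fixed constant (``input_scale`` uV) rather than standardized per segment.
    """

    def __init__(
        self,
        channels: tuple[int, ...] = (16, 32, 64),
        kernel_size: int = 7,
        pool: int = 2,
        head_units: int = 64,
        input_len: int = 200,
        lr: float = 1e-3,
        weight_decay: float = 0.01,
        batch_size: int = 256,
        max_epochs: int = 100,
        patience: int = 10,
        soft_targets: bool = True,
        input_scale: float = 100.0,
        val_fraction: float = 0.1,
        random_state: int | None = None,
    ):
        self.channels = channels
        self.kernel_size = kernel_size
        self.pool = pool
        self.head_units = head_units
        self.input_len = input_len
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.soft_targets = soft_targets
        self.input_scale = input_scale
        self.val_fraction = val_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------ net
    def _build_net(self, rng: np.random.Generator) -> nn.Sequential:
        layers: list = []
        c_in = 1
        length = self.input_len
        for c_out in self.channels:
            layers += [
                nn.Conv1D(c_in, c_out, self.kernel_size, rng),
                nn.ReLU(),
                nn.BatchNorm1D(c_out),
                nn.MaxPool1D(self.pool),
            ]
            if length % self.pool:
                raise ValueError("input_len must be divisible by pool at every block")
            length //= self.pool
            c_in = c_out
        layers += [
            nn.GlobalAvgPool1D(),
            nn.Dense(self.channels[-1], self.head_units, rng),
            nn.ReLU(),
            nn.Dense(self.head_units, 1, rng),
        ]
        return nn.Sequential(layers)

    def initialize(self) -> "CNNClassifier":
        """Build the (untrained) network so the forward pass is usable."""
        rng = np.random.default_rng(self.random_state)
        self.net_ = self._build_net(rng)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = self.input_len
        self.history_ = {"train_loss": [], "val_loss": [], "lr": []}
        self.best_epoch_ = 0
        return self

    @property
    def n_parameters_(self) -> int:
        return int(sum(p.value.size for p in self.net_.params()))

    def _validate_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2 or X.shape[1] != self.input_len:
            raise ValueError(
                f"X must be (n_segments, {self.input_len}); got {X.shape}"
            )
        return X[:, None, :] / np.float32(self.input_scale)

    # ------------------------------------------------------------------ fit
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        init_from: "CNNClassifier | None" = None,
        reinit_head: bool = False,
    ) -> "CNNClassifier":
        """Train against soft targets with AdamW + cosine annealing.

        ``init_from`` warm-starts from another fitted/initialized estimator
        (its state is copied; the donor is never mutated). ``reinit_head``
        re-draws the final dense layer from scratch, the transfer-learning
        recipe. When no validation set is given, a seeded ``val_fraction``
        tail of a shuffled copy of the data is held out for early stopping.
        """
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        if np.any((y < 0) | (y > 1)):
            raise ValueError("targets must be soft labels in [0,1]")
        hard = (y >= 2.0 / 3.0).astype(np.float64)
        if np.unique(hard).size < 2:
            raise ValueError("training data must contain both classes")
        if not self.soft_targets:
            y = hard

        rng = np.random.default_rng(self.random_state)
        self.net_ = self._build_net(rng)
        if init_from is not None:
            donor = getattr(init_from, "net_", None)
            if donor is None:
                raise ValueError("init_from estimator has no built network")
            self.net_.load_state(donor.state())
            if reinit_head:
                head = self.net_.layers[-1]
                fresh = nn.Dense(head.w.value.shape[1], head.w.value.shape[0], rng)
                head.w.value = fresh.w.value
                head.b.value = fresh.b.value

        if X_val is None:
            n_val = max(1, int(round(self.val_fraction * X.shape[0])))
            perm = rng.permutation(X.shape[0])
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            X_val, y_val = X[val_idx], y[val_idx]
            X, y = X[tr_idx], y[tr_idx]
        else:
            X_val = np.asarray(X_val, dtype=np.float64)
            y_val = np.asarray(y_val, dtype=np.float64)
            if not self.soft_targets:
                y_val = (y_val >= 2.0 / 3.0).astype(np.float64)

        Xb = self._validate_X(X)
        Xv = self._validate_X(X_val)
        opt = nn.AdamW(
            self.net_.params(), lr=self.lr, weight_decay=self.weight_decay
        )
        history = {"train_loss": [], "val_loss": [], "lr": []}
        best_loss = np.inf
        best_state = None
        best_epoch = 0
        n = Xb.shape[0]
        order = np.arange(n)
        for epoch in range(1, self.max_epochs + 1):
            opt.lr = nn.cosine_lr(self.lr, epoch - 1, self.max_epochs)
            rng.shuffle(order)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                z = self.net_.forward(Xb[idx], train=True)[:, 0]
                loss, dz = nn.bce_with_logits(z, y[idx])
                self.net_.zero_grad()
                self.net_.backward(np.ascontiguousarray(dz[:, None]))
                opt.step()
                losses.append(loss * idx.size)
            val_loss = self._val_loss(Xv, y_val)
            history["train_loss"].append(float(np.sum(losses) / n))
            history["val_loss"].append(val_loss)
            history["lr"].append(float(opt.lr))
            if val_loss < best_loss:
                best_loss = val_loss
                best_state = self.net_.state()
                best_epoch = epoch
            elif epoch - best_epoch >= self.patience:
                break
        if best_state is not None:
            self.net_.load_state(best_state)
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.best_val_loss_ = float(best_loss)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = self.input_len
        return self

    def _val_loss(self, Xv_scaled: np.ndarray, yv: np.ndarray) -> float:
        zs = []
        for start in range(0, Xv_scaled.shape[0], 4096):
            zs.append(self.net_.forward(Xv_scaled[start : start + 4096])[:, 0])
        loss, _ = nn.bce_with_logits(np.concatenate(zs), yv)
        return loss

    # ------------------------------------------------------------- predict
    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Clean probability per segment, deterministic (evaluation mode)."""
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is neither fitted nor initialized")
        Xs = self._validate_X(np.asarray(X, dtype=np.float64))
        zs = []
        for start in range(0, Xs.shape[0], 4096):
            zs.append(self.net_.forward(Xs[start : start + 4096])[:, 0])
        z = np.concatenate(zs).astype(np.float64)
        return 1.0 / (1.0 + np.exp(-z))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p = self.predict_scores(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_scores(X) >= 0.5).astype(np.int64)

    def evaluate_loss(self, X: np.ndarray, y: np.ndarray) -> float:
        """Soft-target BCE of this model on (X, y), evaluation mode."""
        Xs = self._validate_X(np.asarray(X, dtype=np.float64))
        return self._val_loss(Xs, np.asarray(y, dtype=np.float64))


# ------------------------------------------------------- functional wrappers

def build_cnn(spec: ModelSpec | None = None, seed: int = 0) -> CNNClassifier:
    """Construct an initialized (untrained) classifier from an architecture spec."""
    spec = spec if spec is not None else ModelSpec()
    clf = CNNClassifier(
        channels=tuple(spec.channels),
        kernel_size=spec.kernel_size,
        pool=spec.pool,
        head_units=spec.head_units,
        input_len=spec.input_len,
        random_state=seed,
    )
    return clf.initialize()


def _configured_clone(model: CNNClassifier, cfg: TrainConfig) -> CNNClassifier:
    clone = CNNClassifier(**model.get_params())
    clone.set_params(
        lr=cfg.lr,
        weight_decay=cfg.weight_decay,
        batch_size=cfg.batch_size,
        max_epochs=cfg.max_epochs,
        patience=cfg.patience,
        soft_targets=cfg.soft_targets,
        random_state=cfg.seed,
    )
    return clone


def pretrain(
    model: CNNClassifier,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig | None = None,
) -> CNNClassifier:
    """Train a fresh copy of ``model`` on the source domain. Input unchanged."""
    cfg = cfg if cfg is not None else TrainConfig()
    clone = _configured_clone(model, cfg)
    return clone.fit(X, y)


def fine_tune(
    model: CNNClassifier,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    cfg: TrainConfig | None = None,
) -> CNNClassifier:
    """Transfer to the target domain: fresh head, all layers trained further.

    Returns a new estimator; the pretrained model is never mutated.
    """
    cfg = cfg if cfg is not None else TrainConfig()
    clone = _configured_clone(model, cfg)
    return clone.fit(
        X_train, y_train, X_val=X_val, y_val=y_val,
        init_from=model, reinit_head=True,
    )


def predict_scores(model: CNNClassifier, X: np.ndarray) -> np.ndarray:
    return model.predict_scores(X)
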
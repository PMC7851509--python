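"""Trajectory-image classification: two-branch MLP and a convolutional baseline.

Each trajectory is represented by two binarized flattened images (path
geometry and speed); the model consumes both through separate dense branches,
concatenates them, and emits a probability over the three cognitive-status
classes {cognitively healthy, MCI, PwD} through a 3-neuron softmax head.
Training follows a fixed recipe: categorical cross-entropy, Adam with a low
learning rate (1e-5), mini-batches of 64, at most 100 epochs with early
stopping on validation loss (best weights restored).

The estimators follow scikit-learn conventions (``fit``/``predict``/
``predict_proba``, ``get_params``, trailing-underscore fitted attributes) and
compose with sklearn model selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .nn import Adam, DcnnNet, Network, TwoBranchMLPNet, softmax

__all__ = [
    "CLASS_ORDER",
    "ModelSpec",
    "TrainConfig",
    "Prediction",
    "build_two_input_mlp",
    "build_dcnn_baseline",
    "stratified_validation_split",
    "train_model",
    "predict_trajectory",
    "TwoBranchMLPClassifier",
    "DcnnClassifier",
]

#: Clinical class order; also the tie-break order for argmax predictions.
CLASS_ORDER = ("healthy", "MCI", "PwD")


def ordered_classes(labels) -> np.ndarray:
    """Unique labels in clinical order when applicable, else sorted."""
    uniq = set(np.asarray(labels).tolist())
    if uniq <= set(CLASS_ORDER):
        return np.array([c for c in CLASS_ORDER if c in uniq])
    return np.array(sorted(uniq))


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description; ``instantiate`` builds the numpy network."""

    kind: str  # "two_branch_mlp" | "dcnn"
    input_dim: int | None = None  # per-branch features (MLP)
    input_shape: tuple[int, int, int] | None = None  # H, W, C (DCNN)
    hidden: int = 32
    n_classes: int = 3
    dropout: float = 0.5
    head_batchnorm: bool = True
    layers: tuple = ()

    @property
    def n_params(self) -> int:
        return sum(n for _, n in self.layers)

    def instantiate(self, rng: np.random.Generator) -> Network:
        if self.kind == "two_branch_mlp":
            return TwoBranchMLPNet(
                self.input_dim,
                hidden=self.hidden,
                n_classes=self.n_classes,
                dropout=self.dropout,
                head_batchnorm=self.head_batchnorm,
                rng=rng,
            )
        if self.kind == "dcnn":
            return DcnnNet(self.input_shape, n_classes=self.n_classes, rng=rng)
        raise ValueError(f"unknown model kind {self.kind!r}")


def build_two_input_mlp(
    input_dim: int = 39_000,
    hidden: int = 32,
    n_classes: int = 3,
    dropout: float = 0.5,
    head_batchnorm: bool = True,
) -> ModelSpec:
    """Spec of the two-branch MLP over TRAJ/SPEED feature-vector pairs."""
    if input_dim <= 0:
        raise ValueError("input_dim must be positive")
    layers = []
    for b in ("traj", "speed"):
        layers += [
            (f"{b}/dense1", input_dim * hidden + hidden),
            (f"{b}/batchnorm1", 2 * hidden),
            (f"{b}/dense2", hidden * hidden + hidden),
            (f"{b}/batchnorm2", 2 * hidden),
            (f"{b}/dropout", 0),
        ]
    layers.append(("head/dense", 2 * hidden * n_classes + n_classes))
    if head_batchnorm:
        layers += [("head/batchnorm", 2 * n_classes), ("head/dropout", 0)]
    return ModelSpec(
        kind="two_branch_mlp",
        input_dim=input_dim,
        hidden=hidden,
        n_classes=n_classes,
        dropout=dropout,
        head_batchnorm=head_batchnorm,
        layers=tuple(layers),
    )


def build_dcnn_baseline(
    input_shape: tuple[int, int] | tuple[int, int, int],
    n_classes: int = 3,
) -> ModelSpec:
    """Spec of the convolutional baseline (3 conv blocks + 3 dense layers)."""
    if len(input_shape) == 2:
        input_shape = (*input_shape, 1)
    H, W, C = input_shape
    if H // 8 < 1 or W // 8 < 1:
        raise ValueError(f"input {H}x{W} too small for three 2x2 poolings")
    layers = []
    c_in = C
    for i, f in enumerate(DcnnNet.FILTERS, start=1):
        layers += [(f"conv{i}", 5 * 5 * c_in * f + f), (f"pool{i}", 0)]
        c_in = f
    n_in = (H // 8) * (W // 8) * DcnnNet.FILTERS[-1]
    for i, n in enumerate(DcnnNet.DENSE, start=1):
        layers.append((f"dense{i}", n_in * n + n))
        n_in = n
    layers.append(("head/dense", n_in * n_classes + n_classes))
    return ModelSpec(
        kind="dcnn", input_shape=(H, W, C), n_classes=n_classes, layers=tuple(layers)
    )


@dataclass(frozen=True)
class TrainConfig:
    """The training recipe (Adam + cross-entropy + early stopping)."""

    learning_rate: float = 1e-5
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 15
    min_epochs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


@dataclass(frozen=True)
class Prediction:
    """Class probabilities for one trajectory plus the argmax class."""

    probabilities: dict[str, float]
    label: str

    def __post_init__(self) -> None:
        total = sum(self.probabilities.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"probabilities sum to {total}, not 1")


def stratified_validation_split(
    y, fraction: float = 0.1, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Hold out ``fraction`` of each category (at least one sample) for validation.

    Returns (train_idx, val_idx); deterministic given the seed.
    """
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    val_idx: list[int] = []
    for cls in ordered_classes(y):
        idx = np.flatnonzero(y == cls)
        n_val = max(1, int(len(idx) * fraction)) if len(idx) > 1 else 0
        chosen = rng.choice(idx, size=n_val, replace=False)
        val_idx.extend(chosen.tolist())
    val = np.array(sorted(val_idx), dtype=int)
    train = np.setdiff1d(np.arange(len(y)), val)
    return train, val


def _one_hot(y_codes: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(y_codes), n_classes), dtype=np.float32)
    out[np.arange(len(y_codes)), y_codes] = 1.0
    return out


def _xent(probs: np.ndarray, onehot: np.ndarray) -> float:
    p = np.clip(probs, 1e-12, 1.0)
    return float(-(onehot * np.log(p)).sum(axis=1).mean())


def train_model(
    spec_or_net,
    train_data: tuple,
    val_data: tuple,
    cfg: TrainConfig = TrainConfig(),
) -> tuple[Network, dict]:
    """Train a network with Adam, mini-batches, and validation early stopping.

    ``train_data``/``val_data`` are ``(inputs, y_onehot)`` where ``inputs`` is
    a tuple of input arrays (two for the MLP, one for the DCNN).  Training
    stops when validation loss has not improved for ``patience`` epochs and
    the best-validation weights are restored.  Fully deterministic given
    ``cfg.seed``.  Raises if a class has no training sample.
    """
    rng = np.random.default_rng(cfg.seed)
    if isinstance(spec_or_net, ModelSpec):
        net = spec_or_net.instantiate(rng)
    else:
        net = spec_or_net
    inputs, y = train_data
    inputs = tuple(np.asarray(a, dtype=np.float32) for a in inputs)
    y = np.asarray(y, dtype=np.float32)
    if (y.sum(axis=0) == 0).any():
        missing = int(np.flatnonzero(y.sum(axis=0) == 0)[0])
        raise ValueError(f"class index {missing} absent from training data")
    val_inputs, val_y = val_data
    val_inputs = tuple(np.asarray(a, dtype=np.float32) for a in val_inputs)
    val_y = np.asarray(val_y, dtype=np.float32)

    opt = Adam(lr=cfg.learning_rate)
    n = len(y)
    history = {"train_loss": [], "val_loss": []}
    best_loss = np.inf
    best_weights = net.get_weights()
    best_epoch = -1
    wait = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch_in = tuple(a[idx] for a in inputs)
            batch_y = y[idx]
            logits = net.forward_logits(batch_in, training=True, rng=rng)
            probs = softmax(logits)
            losses.append(_xent(probs, batch_y))
            net.backward((probs - batch_y) / len(idx))
            opt.step(net)
        history["train_loss"].append(float(np.mean(losses)))
        val_probs = softmax(net.forward_logits(val_inputs, training=False))
        val_loss = _xent(val_probs, val_y)
        history["val_loss"].append(val_loss)
        if val_loss < best_loss - 1e-9:
            best_loss = val_loss
            best_weights = net.get_weights()
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= cfg.patience and epoch + 1 >= cfg.min_epochs:
                break
    net.set_weights(best_weights)
    history["best_epoch"] = best_epoch
    history["stopped_epoch"] = epoch
    return net, history


def predict_trajectory(model, traj_vec, speed_vec) -> Prediction:
    """Classify one trajectory from its TRAJ/SPEED feature vectors.

    ``model`` is a fitted :class:`TwoBranchMLPClassifier` or a raw network
    with attached ``classes_``.  Ties in the argmax resolve toward the first
    class in clinical order (healthy < MCI < PwD).
    """
    if isinstance(model, TwoBranchMLPClassifier):
        net, classes = model.net_, model.classes_
    else:
        net, classes = model, np.asarray(CLASS_ORDER)
    traj_vec = np.asarray(traj_vec, dtype=np.float32).reshape(1, -1)
    speed_vec = np.asarray(speed_vec, dtype=np.float32).reshape(1, -1)
    if traj_vec.shape[1] != net.input_dim or speed_vec.shape[1] != net.input_dim:
        raise ValueError(
            f"expected feature vectors of length {net.input_dim}, got "
            f"{traj_vec.shape[1]} and {speed_vec.shape[1]}"
        )
    probs = softmax(net.forward_logits((traj_vec, speed_vec), training=False))[0]
    label = str(classes[int(np.argmax(probs))])
    return Prediction(
        probabilities={str(c): float(p) for c, p in zip(classes, probs)}, label=label
    )


class TwoBranchMLPClassifier(ClassifierMixin, BaseEstimator):
    """Two-branch MLP over concatenated TRAJ+SPEED feature-vector pairs.

    ``X`` has shape (n_samples, 2*input_dim): the first ``input_dim`` columns
    are the binarized TRAJ vector, the rest the SPEED vector.  A fraction of
    each category is held out for validation-based early stopping.
    """

    def __init__(
        self,
        input_dim: int = 39_000,
        hidden: int = 32,
        dropout: float = 0.5,
        head_batchnorm: bool = True,
        learning_rate: float = 1e-5,
        batch_size: int = 64,
        max_epochs: int = 100,
        patience: int = 15,
        min_epochs: int = 20,
        validation_fraction: float = 0.1,
        random_state: int = 0,
    ) -> None:
        self.input_dim = input_dim
        self.hidden = hidden
        self.dropout = dropout
        self.head_batchnorm = head_batchnorm
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.min_epochs = min_epochs
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _split_branches(self, X) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2 or X.shape[1] != 2 * self.input_dim:
            raise ValueError(
                f"X must have shape (n, {2 * self.input_dim}); got {X.shape}"
            )
        return X[:, : self.input_dim], X[:, self.input_dim :]

    def fit(self, X, y):
        Xt, Xs = self._split_branches(X)
        y = np.asarray(y)
        if len(y) != len(Xt):
            raise ValueError("X and y length mismatch")
        self.classes_ = ordered_classes(y)
        code = {cls: i for i, cls in enumerate(self.classes_)}
        codes = np.array([code[v] for v in y])
        onehot = _one_hot(codes, len(self.classes_))
        tr, va = stratified_validation_split(
            y, self.validation_fraction, seed=self.random_state
        )
        spec = build_two_input_mlp(
            input_dim=self.input_dim,
            hidden=self.hidden,
            n_classes=len(self.classes_),
            dropout=self.dropout,
            head_batchnorm=self.head_batchnorm,
        )
        cfg = TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            min_epochs=self.min_epochs,
            seed=self.random_state,
        )
        self.net_, self.history_ = train_model(
            spec,
            ((Xt[tr], Xs[tr]), onehot[tr]),
            ((Xt[va], Xs[va]), onehot[va]),
            cfg,
        )
        self.n_features_in_ = 2 * self.input_dim
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        Xt, Xs = self._split_branches(X)
        return softmax(self.net_.forward_logits((Xt, Xs), training=False))

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        return self.classes_[np.argmax(probs, axis=1)]

    def save(self, path) -> None:
        """Persist the fitted model (weights + hyper-parameters + classes)."""
        check_is_fitted(self, "net_")
        import json

        meta = {"params": self.get_params(), "classes": self.classes_.tolist()}
        weights = self.net_.get_weights()
        np.savez(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            n_weights=np.array(len(weights)),
            **{f"w{i}": w for i, w in enumerate(weights)},
        )

    @classmethod
    def load(cls, path) -> "TwoBranchMLPClassifier":
        import json

        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            weights = [data[f"w{i}"] for i in range(int(data["n_weights"]))]
        clf = cls(**meta["params"])
        clf.classes_ = np.array(meta["classes"])
        spec = build_two_input_mlp(
            input_dim=clf.input_dim,
            hidden=clf.hidden,
            n_classes=len(clf.classes_),
            dropout=clf.dropout,
            head_batchnorm=clf.head_batchnorm,
        )
        clf.net_ = spec.instantiate(np.random.default_rng(0))
        clf.net_.set_weights(weights)
        clf.n_features_in_ = 2 * clf.input_dim
        clf.history_ = {}
        return clf


class DcnnClassifier(ClassifierMixin, BaseEstimator):
    """Convolutional baseline over single trajectory images (NHWC)."""

    def __init__(
        self,
        input_shape: tuple[int, int, int] = (130, 100, 3),
        learning_rate: float = 1e-5,
        batch_size: int = 64,
        max_epochs: int = 100,
        patience: int = 15,
        min_epochs: int = 20,
        validation_fraction: float = 0.1,
        random_state: int = 0,
    ) -> None:
        self.input_shape = input_shape
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.min_epochs = min_epochs
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[..., None]
        if X.shape[1:] != tuple(self.input_shape):
            raise ValueError(
                f"X must have shape (n, {self.input_shape}); got {X.shape}"
            )
        return X

    def fit(self, X, y):
        X = self._check_X(X)
        y = np.asarray(y)
        self.classes_ = ordered_classes(y)
        code = {cls: i for i, cls in enumerate(self.classes_)}
        codes = np.array([code[v] for v in y])
        onehot = _one_hot(codes, len(self.classes_))
        tr, va = stratified_validation_split(
            y, self.validation_fraction, seed=self.random_state
        )
        spec = build_dcnn_baseline(self.input_shape, n_classes=len(self.classes_))
        cfg = TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            min_epochs=self.min_epochs,
            seed=self.random_state,
        )
        self.net_, self.history_ = train_model(
            spec, ((X[tr],), onehot[tr]), ((X[va],), onehot[va]), cfg
        )
        self.n_features_in_ = int(np.prod(self.input_shape))
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        X = self._check_X(X)
        return softmax(self.net_.forward_logits((X,), training=False))

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        return self.classes_[np.argmax(probs, axis=1)]
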
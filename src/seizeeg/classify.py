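"""Compact 1-D CNN for the selected feature vector, in pure NumPy.

Architecture (no padding, all strides 1), with the exact length
walk-through for the default 10-feature input:

    input 10 -> conv(16 filters, kernel 2) 9 -> batchnorm -> ReLU
             -> maxpool(2) 8
             -> conv(32 filters, kernel 2) 7 -> batchnorm -> ReLU
             -> maxpool(2) 6
             -> flatten 6*32 = 192 -> fc 32 (ReLU) -> fc n_classes -> softmax

Training is mini-batch Adam on the softmax cross-entropy.  Everything is
seeded, so (data, config, seed) fully determines the trained parameters.
Overlapping stride-1 pooling is unusual but implemented exactly as sized;
average pooling is provided alongside max pooling but unused by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .io import FeatureMatrix

SERIALIZATION_VERSION = 1


def max_pool(x, size: int = 2, stride: int = 1) -> np.ndarray:
    """Sliding-window maximum over the last axis; length -> L - size + 1 (stride 1)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < size:
        raise ValueError(f"pool window {size} larger than input {x.shape[-1]}")
    return sliding_window_view(x, size, axis=-1)[..., ::stride, :].max(axis=-1)


def avg_pool(x, size: int = 2, stride: int = 1) -> np.ndarray:
    """Sliding-window mean over the last axis."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < size:
        raise ValueError(f"pool window {size} larger than input {x.shape[-1]}")
    return sliding_window_view(x, size, axis=-1)[..., ::stride, :].mean(axis=-1)


@dataclass(frozen=True)
class CNNSpec:
    """Layer shape specification; raises at construction if lengths collapse."""

    input_len: int = 10
    conv1_filters: int = 16
    conv2_filters: int = 32
    kernel_size: int = 2
    pool_size: int = 2
    fc_hidden: int = 32
    n_classes: int = 2

    def __post_init__(self) -> None:
        self.shape_walkthrough()  # validates

    def shape_walkthrough(self) -> List[int]:
        """Sequence lengths after each conv/pool stage (all strides 1, no padding)."""
        L = self.input_len
        lengths = [L]
        for _ in range(2):  # two conv+pool blocks
            L = L - self.kernel_size + 1
            lengths.append(L)
            L = L - self.pool_size + 1
            lengths.append(L)
            if L < 1:
                raise ValueError(
                    f"spec collapses: length walk-through {lengths} reaches < 1"
                )
        return lengths

    @property
    def flat_dim(self) -> int:
        return self.shape_walkthrough()[-1] * self.conv2_filters


@dataclass
class TrainConfig:
    """Optimisation settings: Adam on softmax cross-entropy, stratified 3:1 split."""

    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    test_fraction: float = 0.25  # the 3:1 split
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")


# ---------------------------------------------------------------------------
# layers


class _Conv1d:
    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_ch * k))  # He initialisation
        self.W = rng.standard_normal((out_ch, in_ch, k)) * scale
        self.b = np.zeros(out_ch)
        self.params = ["W", "b"]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        # x: (batch, in_ch, L) -> (batch, out_ch, L-k+1), cross-correlation + bias
        self._windows = sliding_window_view(x, self.W.shape[2], axis=2)
        return np.einsum("bciw,fcw->bfi", self._windows, self.W) + self.b[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW = np.einsum("bfi,bciw->fcw", grad, self._windows)
        self.db = grad.sum(axis=(0, 2))
        batch, in_ch = self._windows.shape[0], self.W.shape[1]
        L = self._windows.shape[2] + self.W.shape[2] - 1
        dx = np.zeros((batch, in_ch, L))
        for t in range(self.W.shape[2]):
            dx[:, :, t : t + grad.shape[2]] += np.einsum("bfi,fc->bci", grad, self.W[:, :, t])
        return dx


class _BatchNorm1d:
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.params = ["gamma", "beta"]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)[None, :, None]
        self._xhat = (x - mean[None, :, None]) / self._std
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        m = grad.shape[0] * grad.shape[2]  # reduction size per channel
        self.dgamma = (grad * self._xhat).sum(axis=(0, 2))
        self.dbeta = grad.sum(axis=(0, 2))
        g = grad * self.gamma[None, :, None]
        return (
            g - g.mean(axis=(0, 2), keepdims=True)
            - self._xhat * (g * self._xhat).mean(axis=(0, 2), keepdims=True)
        ) / self._std


class _ReLU:
    params: List[str] = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class _MaxPool1d:
    params: List[str] = []

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._in_shape = x.shape
        windows = sliding_window_view(x, self.size, axis=2)
        self._argmax = windows.argmax(axis=-1)  # first max on ties
        return windows.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._in_shape)
        b, c, L_out = grad.shape
        bi, ci, ii = np.indices(grad.shape)
        np.add.at(dx, (bi, ci, ii + self._argmax), grad)
        return dx


class _Flatten:
    params: List[str] = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._in_shape)


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)
        self.b = np.zeros(d_out)
        self.params = ["W", "b"]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, layers, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers, self.lr, self.b1, self.b2, self.eps = layers, lr, beta1, beta2, eps
        self.t = 0
        self.m = [
            {p: np.zeros_like(getattr(l, p)) for p in l.params} for l in layers
        ]
        self.v = [
            {p: np.zeros_like(getattr(l, p)) for p in l.params} for l in layers
        ]

    def step(self) -> None:
        self.t += 1
        for li, layer in enumerate(self.layers):
            for p in layer.params:
                g = getattr(layer, "d" + p)
                self.m[li][p] = self.b1 * self.m[li][p] + (1 - self.b1) * g
                self.v[li][p] = self.b2 * self.v[li][p] + (1 - self.b2) * g * g
                mhat = self.m[li][p] / (1 - self.b1**self.t)
                vhat = self.v[li][p] / (1 - self.b2**self.t)
                getattr(layer, p)[...] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# estimator


class CNNClassifier(BaseEstimator, ClassifierMixin):
    """Seeded NumPy 1-D CNN over short tabular feature vectors.

    Follows the sklearn estimator contract: ``fit(X, y)`` trains on all
    rows it is given (callers own the train/test split), ``predict_proba``
    returns softmax class probabilities, and fitted state lives in
    trailing-underscore attributes.  Inputs are standardised per feature
    using statistics of the training rows.
    """

    def __init__(
        self,
        spec: Optional[CNNSpec] = None,
        learning_rate: float = 1e-3,
        epochs: int = 100,
        batch_size: int = 32,
        seed: int = 0,
    ):
        self.spec = spec
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed

    # -- internal ----------------------------------------------------------
    def _build(self, spec: CNNSpec, rng: np.random.Generator) -> list:
        k, pool = spec.kernel_size, spec.pool_size
        return [
            _Conv1d(1, spec.conv1_filters, k, rng),
            _BatchNorm1d(spec.conv1_filters),
            _ReLU(),
            _MaxPool1d(pool),
            _Conv1d(spec.conv1_filters, spec.conv2_filters, k, rng),
            _BatchNorm1d(spec.conv2_filters),
            _ReLU(),
            _MaxPool1d(pool),
            _Flatten(),
            _Dense(spec.flat_dim, spec.fc_hidden, rng),
            _ReLU(),
            _Dense(spec.fc_hidden, spec.n_classes, rng),
        ]

    def _forward(self, X: np.ndarray, training: bool) -> np.ndarray:
        out = X[:, None, :]  # (batch, 1, input_len)
        for layer in self.layers_:
            out = layer.forward(out, training)
        return out

    # -- sklearn surface ---------------------------------------------------
    def fit(self, X, y) -> "CNNClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (rows x features)")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("training data contains a single class")
        spec = self.spec or CNNSpec(input_len=X.shape[1], n_classes=self.classes_.size)
        if X.shape[1] != spec.input_len:
            raise ValueError(f"expected {spec.input_len} features, got {X.shape[1]}")
        self.spec_ = spec
        self.x_mean_ = X.mean(axis=0)
        self.x_std_ = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        Xs = (X - self.x_mean_) / self.x_std_

        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0xC44]))
        self.layers_ = self._build(spec, rng)
        opt = _Adam(self.layers_, self.learning_rate)
        n = Xs.shape[0]
        self.loss_curve_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                if idx.size < 2:
                    continue  # batch-norm needs >= 2 rows
                logits = self._forward(Xs[idx], training=True)
                probs = _softmax(logits)
                eps = 1e-12
                loss = -np.mean(np.log(probs[np.arange(idx.size), y_idx[idx]] + eps))
                if not np.isfinite(loss):
                    raise FloatingPointError(f"non-finite loss at epoch {epoch}")
                epoch_loss += loss * idx.size
                grad = probs.copy()
                grad[np.arange(idx.size), y_idx[idx]] -= 1.0
                grad /= idx.size
                for layer in reversed(self.layers_):
                    grad = layer.backward(grad)
                opt.step()
            self.loss_curve_.append(epoch_loss / n)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "layers_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.spec_.input_len:
            raise ValueError(f"expected (n, {self.spec_.input_len}) input")
        Xs = (X - self.x_mean_) / self.x_std_
        return _softmax(self._forward(Xs, training=False))

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def make_svm_baseline(seed: int = 0) -> SVC:
    """RBF-kernel SVM behind the same fit/predict contract, for comparison only."""
    return SVC(kernel="rbf", probability=False, random_state=seed)


# ---------------------------------------------------------------------------
# functional surface


def build_cnn(spec: Optional[CNNSpec] = None, seed: int = 0, **train_kw) -> CNNClassifier:
    """Untrained seeded classifier for the given architecture spec."""
    return CNNClassifier(spec=spec, seed=seed, **train_kw)


def train(
    model: CNNClassifier, fm: FeatureMatrix, cfg: TrainConfig = TrainConfig()
) -> Tuple[CNNClassifier, np.ndarray, np.ndarray]:
    """Stratified 3:1 split, fit on the training fold, return held-out indices.

    Returns (fitted model, train_idx, test_idx); the model never sees the
    test-fold rows.
    """
    idx = np.arange(fm.n_segments)
    train_idx, test_idx = train_test_split(
        idx,
        test_size=cfg.test_fraction,
        stratify=fm.labels,
        random_state=cfg.seed % (2**32 - 1),
    )
    model.set_params(
        learning_rate=cfg.learning_rate, epochs=cfg.epochs, batch_size=cfg.batch_size
    )
    model.fit(fm.values[train_idx], np.asarray(fm.labels)[train_idx])
    return model, train_idx, test_idx


def predict(model: CNNClassifier, X) -> Tuple[np.ndarray, np.ndarray]:
    """(probabilities, argmax labels) for a fitted model."""
    probs = model.predict_proba(X)
    return probs, model.classes_[np.argmax(probs, axis=1)]


# -- serialization ----------------------------------------------------------


def model_to_dict(model: CNNClassifier) -> Dict:
    """JSON-serialisable snapshot of a fitted model (versioned)."""
    check_is_fitted(model, "layers_")
    layers_state = []
    for layer in model.layers_:
        state = {p: getattr(layer, p).tolist() for p in layer.params}
        if isinstance(layer, _BatchNorm1d):
            state["running_mean"] = layer.running_mean.tolist()
            state["running_var"] = layer.running_var.tolist()
        layers_state.append(state)
    return {
        "version": SERIALIZATION_VERSION,
        "spec": vars(model.spec_).copy() if hasattr(model.spec_, "__dict__") else {
            f: getattr(model.spec_, f) for f in model.spec_.__dataclass_fields__
        },
        "classes": model.classes_.tolist(),
        "x_mean": model.x_mean_.tolist(),
        "x_std": model.x_std_.tolist(),
        "layers": layers_state,
        "loss_curve": list(model.loss_curve_),
    }


def model_from_dict(state: Dict) -> CNNClassifier:
    if state.get("version") != SERIALIZATION_VERSION:
        raise ValueError(f"unsupported model version {state.get('version')}")
    spec = CNNSpec(**state["spec"])
    model = CNNClassifier(spec=spec)
    rng = np.random.default_rng(0)
    model.spec_ = spec
    model.layers_ = model._build(spec, rng)
    model.classes_ = np.asarray(state["classes"])
    model.x_mean_ = np.asarray(state["x_mean"], dtype=float)
    model.x_std_ = np.asarray(state["x_std"], dtype=float)
    model.loss_curve_ = list(state["loss_curve"])
    for layer, lstate in zip(model.layers_, state["layers"]):
        for p in layer.params:
            getattr(layer, p)[...] = np.asarray(lstate[p], dtype=float)
        if isinstance(layer, _BatchNorm1d):
            layer.running_mean[...] = np.asarray(lstate["running_mean"], dtype=float)
            layer.running_var[...] = np.asarray(lstate["running_var"], dtype=float)
    model.n_features_in_ = spec.input_len
    return model
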
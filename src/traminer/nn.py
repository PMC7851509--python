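"""Minimal seeded neural-network engine (dense, batch-norm, dropout, conv, Adam).

The networks used here are small enough that a plain numpy implementation is
the most transparent and dependency-light choice: a two-branch multilayer
perceptron over flattened image pairs, and a deep convolutional baseline.
Everything is float32, fully deterministic given a seed, and batch-norm uses
running statistics in inference mode, so a frozen model's forward pass is
batch-size invariant.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "softmax",
    "Dense",
    "ReLU",
    "BatchNorm",
    "Dropout",
    "Sequential",
    "TwoBranchMLPNet",
    "DcnnNet",
    "Adam",
]

F32 = np.float32


def softmax(logits: np.ndarray) -> np.ndarray:
    """Exponential normalization over the last axis, stabilized by max-subtraction."""
    z = np.asarray(logits, dtype=np.float64)
    if not np.isfinite(z).all():
        raise ValueError("softmax requires finite logits")
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _he_uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class Layer:
    """A differentiable layer; parameters live in ``params``/``grads`` dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, training=False, rng=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError


class Dense(Layer):
    def __init__(
        self, n_in: int, n_out: int, rng: np.random.Generator, input_layer: bool = False
    ) -> None:
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        self.input_layer = input_layer  # skip the (unused) input gradient
        self.params["W"] = _he_uniform(rng, n_in, (n_in, n_out))
        self.params["b"] = np.zeros(n_out, dtype=F32)

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        if self.input_layer:
            return None
        return dy @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class BatchNorm(Layer):
    """Per-feature batch normalization (keras-style defaults)."""

    def __init__(self, n: int, momentum: float = 0.99, eps: float = 1e-3) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(n, dtype=F32)
        self.params["beta"] = np.zeros(n, dtype=F32)
        self.running_mean = np.zeros(n, dtype=F32)
        self.running_var = np.ones(n, dtype=F32)

    def forward(self, x, training=False, rng=None):
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mu
            ).astype(F32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(F32)
        else:
            mu, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xc = x - mu
        self._xhat = self._xc / self._std
        self._training = training
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy):
        self.grads["gamma"] = (dy * self._xhat).sum(axis=0)
        self.grads["beta"] = dy.sum(axis=0)
        dxhat = dy * self.params["gamma"]
        if not self._training:
            return dxhat / self._std
        B = dy.shape[0]
        dvar = (dxhat * self._xc * -0.5 / self._std**3).sum(axis=0)
        dmu = (-dxhat / self._std).sum(axis=0) + dvar * (-2.0 * self._xc).mean(axis=0)
        return dxhat / self._std + dvar * 2.0 * self._xc / B + dmu / B


class Dropout(Layer):
    def __init__(self, rate: float = 0.5) -> None:
        super().__init__()
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask.astype(F32)

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask.astype(F32)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    def forward(self, x, training=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def iter_layers(self):
        for layer in self.layers:
            yield layer


class Conv2D(Layer):
    """5×5 zero-padded ('same') convolution, stride 1, NHWC layout."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 5) -> None:
        super().__init__()
        self.k, self.c_in, self.c_out = k, c_in, c_out
        fan_in = k * k * c_in
        self.params["W"] = _he_uniform(rng, fan_in, (fan_in, c_out))
        self.params["b"] = np.zeros(c_out, dtype=F32)

    def _im2col(self, xp, H, W):
        k = self.k
        cols = [
            xp[:, i : i + H, j : j + W, :] for i in range(k) for j in range(k)
        ]
        return np.concatenate(cols, axis=-1)  # (B,H,W,k*k*C)

    def forward(self, x, training=False, rng=None):
        B, H, W, C = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        col = self._im2col(xp, H, W).reshape(B * H * W, -1)
        self._col, self._shape = col, (B, H, W, C)
        out = col @ self.params["W"] + self.params["b"]
        return out.reshape(B, H, W, self.c_out)

    def backward(self, dy):
        B, H, W, C = self._shape
        k, p = self.k, self.k // 2
        dmat = dy.reshape(B * H * W, self.c_out)
        self.grads["W"] = self._col.T @ dmat
        self.grads["b"] = dmat.sum(axis=0)
        dcol = (dmat @ self.params["W"].T).reshape(B, H, W, k * k * C)
        dxp = np.zeros((B, H + 2 * p, W + 2 * p, C), dtype=F32)
        idx = 0
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + H, j : j + W, :] += dcol[..., idx * C : (idx + 1) * C]
                idx += 1
        return dxp[:, p : p + H, p : p + W, :]


class MaxPool2(Layer):
    """2×2 max pooling, stride 2; an odd trailing row/column is dropped."""

    def forward(self, x, training=False, rng=None):
        B, H, W, C = x.shape
        Ho, Wo = H // 2, W // 2
        xt = x[:, : Ho * 2, : Wo * 2, :].reshape(B, Ho, 2, Wo, 2, C)
        self._x_shape = x.shape
        out = xt.max(axis=(2, 4))
        self._mask = xt == out[:, :, None, :, None, :]
        return out

    def backward(self, dy):
        B, H, W, C = self._x_shape
        Ho, Wo = H // 2, W // 2
        d = self._mask * dy[:, :, None, :, None, :]
        dx = np.zeros(self._x_shape, dtype=F32)
        dx[:, : Ho * 2, : Wo * 2, :] = d.reshape(B, Ho * 2, Wo * 2, C)
        return dx


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


def _iter_param_layers(root):
    stack = [root]
    while stack:
        layer = stack.pop()
        if isinstance(layer, Sequential):
            stack.extend(reversed(layer.layers))
        elif layer.params:
            yield layer


class Network:
    """Base class: a forward pass to logits plus parameter bookkeeping."""

    def param_layers(self):
        raise NotImplementedError

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self.param_layers():
            for name in sorted(layer.params):
                out.append(layer.params[name].copy())
            if isinstance(layer, BatchNorm):
                out.append(layer.running_mean.copy())
                out.append(layer.running_var.copy())
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self.param_layers():
            for name in sorted(layer.params):
                layer.params[name] = next(it).copy()
            if isinstance(layer, BatchNorm):
                layer.running_mean = next(it).copy()
                layer.running_var = next(it).copy()

    @property
    def n_params(self) -> int:
        return sum(
            p.size for layer in self.param_layers() for p in layer.params.values()
        )


class TwoBranchMLPNet(Network):
    """Two identical dense branches over the TRAJ and SPEED feature vectors.

    Branch: dense 32 → ReLU → batch-norm → dense 32 → ReLU → batch-norm →
    dropout 0.5.  The branch outputs are concatenated and a 3-neuron head
    (followed, as configured, by batch-norm and dropout) produces the logits
    that softmax turns into class probabilities.
    """

    def __init__(
        self,
        input_dim: int,
        hidden: int = 32,
        n_classes: int = 3,
        dropout: float = 0.5,
        head_batchnorm: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.input_dim = input_dim
        self.n_classes = n_classes

        def branch():
            return Sequential(
                [
                    Dense(input_dim, hidden, rng, input_layer=True),
                    ReLU(),
                    BatchNorm(hidden),
                    Dense(hidden, hidden, rng),
                    ReLU(),
                    BatchNorm(hidden),
                    Dropout(dropout),
                ]
            )

        self.branch_traj = branch()
        self.branch_speed = branch()
        head_layers: list[Layer] = [Dense(2 * hidden, n_classes, rng)]
        if head_batchnorm:
            head_layers += [BatchNorm(n_classes), Dropout(dropout)]
        self.head = Sequential(head_layers)
        self._hidden = hidden

    def param_layers(self):
        for root in (self.branch_traj, self.branch_speed, self.head):
            yield from _iter_param_layers(root)

    def forward_logits(self, inputs, training=False, rng=None):
        xt, xs = inputs
        ht = self.branch_traj.forward(xt, training=training, rng=rng)
        hs = self.branch_speed.forward(xs, training=training, rng=rng)
        return self.head.forward(np.concatenate([ht, hs], axis=1), training=training, rng=rng)

    def backward(self, dlogits):
        dh = self.head.backward(dlogits.astype(F32))
        self.branch_traj.backward(dh[:, : self._hidden])
        self.branch_speed.backward(dh[:, self._hidden :])


class DcnnNet(Network):
    """Deep convolutional baseline: three 'same' 5×5 conv blocks (32, 128, 256
    filters) each followed by 2×2 max pooling, then dense 512/128/64 and a
    3-way softmax head."""

    FILTERS = (32, 128, 256)
    DENSE = (512, 128, 64)

    def __init__(
        self,
        input_shape: tuple[int, int, int],
        n_classes: int = 3,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        H, W, C = input_shape
        if H // 8 < 1 or W // 8 < 1:
            raise ValueError(f"input {H}x{W} too small for three 2x2 poolings")
        self.input_shape = (H, W, C)
        layers: list[Layer] = []
        c_in = C
        for f in self.FILTERS:
            layers += [Conv2D(c_in, f, rng), ReLU(), MaxPool2()]
            c_in = f
        layers.append(Flatten())
        self.post_conv_hw = (H // 2 // 2 // 2, W // 2 // 2 // 2)
        n_in = self.post_conv_hw[0] * self.post_conv_hw[1] * self.FILTERS[-1]
        for n in self.DENSE:
            layers += [Dense(n_in, n, rng), ReLU()]
            n_in = n
        layers.append(Dense(n_in, n_classes, rng))
        self.net = Sequential(layers)

    def param_layers(self):
        yield from _iter_param_layers(self.net)

    def forward_logits(self, inputs, training=False, rng=None):
        (x,) = inputs if isinstance(inputs, (tuple, list)) else (inputs,)
        return self.net.forward(x.astype(F32), training=training, rng=rng)

    def backward(self, dlogits):
        self.net.backward(dlogits.astype(F32))


class Adam:
    """Adaptive-moment gradient descent."""

    def __init__(self, lr=1e-5, beta1=0.9, beta2=0.999, eps=1e-7) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[int, dict[str, np.ndarray]] = {}
        self._v: dict[int, dict[str, np.ndarray]] = {}

    def step(self, net: Network) -> None:
        self.t += 1
        b1, b2 = F32(self.beta1), F32(self.beta2)
        lr_t = F32(
            self.lr * np.sqrt(1 - self.beta2**self.t) / (1 - self.beta1**self.t)
        )
        eps = F32(self.eps)
        for i, layer in enumerate(net.param_layers()):
            m = self._m.setdefault(i, {})
            v = self._v.setdefault(i, {})
            for name, p in layer.params.items():
                g = layer.grads[name]
                if g.dtype != F32:
                    g = g.astype(F32)
                if name not in m:
                    m[name] = np.zeros_like(p)
                    v[name] = np.zeros_like(p)
                m[name] *= b1
                m[name] += (1 - b1) * g
                v[name] *= b2
                v[name] += (1 - b2) * g * g
                p -= lr_t * m[name] / (np.sqrt(v[name]) + eps)
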
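"""Minimal numpy layer framework backing the fusion classifier.

Implements exactly the pieces the dual-backbone harness needs: 2-D
convolution (stride 1, same padding), batch normalization, ReLU, 2x2 max
pooling, global average pooling, dense layers, inverted dropout, a softmax
cross-entropy head and an Adam optimizer. Layers carry a ``trainable``
flag; the optimizer only touches trainable layers, and a frozen batch-norm
layer runs in inference mode (running statistics, no updates), so freezing
a backbone leaves every one of its arrays bit-identical through training.

All randomness (initialization, dropout masks) flows from a single
``numpy.random.Generator``, so a seeded build + training run is exactly
reproducible.
"""

from __future__ import annotations


from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "BatchNorm2D",
    "ReLU",
    "MaxPool2D",
    "GlobalAvgPool",
    "Dense",
    "Dropout",
    "Adam",
    "softmax",
    "cross_entropy",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    """Mean negative log-likelihood of integer labels under ``probs``."""
    n = len(y)
    return float(-np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean())


class Layer:
    """Base layer: forward/backward plus named parameter and state access."""

    trainable: bool = True

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> dict[str, np.ndarray]:
        """Learnable arrays, updated by the optimizer when trainable."""
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def state(self) -> dict[str, np.ndarray]:
        """All persistent arrays (parameters + buffers), for checkpoints."""
        return dict(self.params())

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        own = self.state()
        for k, v in state.items():
            own[k][...] = v

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params().values())


class Conv2D(Layer):
    """3x3-style convolution, stride 1, same (zero) padding, NCHW layout."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd (same padding)")
        scale = np.sqrt(2.0 / (c_in * kernel * kernel))  # He init
        self.w = rng.normal(0.0, scale, (c_out, c_in, kernel, kernel))
        self.b = np.zeros(c_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.kernel = kernel
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.kernel
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * k * k)
        out = cols @ self.w.reshape(self.w.shape[0], -1).T + self.b
        if train:
            self._cols, self._shape = cols, x.shape
        return out.transpose(0, 2, 1).reshape(n, -1, h, w)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        k, p = self.kernel, self.kernel // 2
        f = self.w.shape[0]
        g = grad.reshape(n, f, h * w).transpose(0, 2, 1)  # (n, hw, f)
        self.dw[...] = np.tensordot(g, self._cols, axes=([0, 1], [0, 1])).reshape(
            self.w.shape
        )
        self.db[...] = g.sum(axis=(0, 1))
        dcols = g @ self.w.reshape(f, -1)  # (n, hw, ckk)
        d = dcols.reshape(n, h, w, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += d[:, :, :, :, i, j]
        return dxp[:, :, p : p + h, p : p + w]

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}


class BatchNorm2D(Layer):
    """Per-channel batch normalization with running statistics.

    A frozen (non-trainable) instance always normalizes with its running
    statistics and never updates them, matching the convention that a
    frozen backbone is fully inert during training.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros(channels)
        self.dbeta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        # 0 until the first training batch seeds the running statistics;
        # avoids a cold start where validation sees unrelated (0, 1) stats.
        self.initialized = np.zeros(1)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train and self.trainable:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            if not self.initialized[0]:
                self.running_mean[...] = mean
                self.running_var[...] = var
                self.initialized[0] = 1.0
            else:
                self.running_mean[...] = (
                    self.momentum * self.running_mean + (1 - self.momentum) * mean
                )
                self.running_var[...] = (
                    self.momentum * self.running_var + (1 - self.momentum) * var
                )
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv, x.shape)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.dgamma[...] = (grad * xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = grad.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None]
        if not self.trainable:
            # Inference-mode normalization is an affine map with constants.
            return grad * g * inv[None, :, None, None]
        dxhat = grad * g
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
        )
        return term * inv[None, :, None, None]

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def state(self):
        return {
            "gamma": self.gamma,
            "beta": self.beta,
            "running_mean": self.running_mean,
            "running_var": self.running_var,
            "initialized": self.initialized,
        }


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad):
        return grad * self._mask


class MaxPool2D(Layer):
    """2x2 max pooling with stride 2; ties share the gradient equally."""

    def __init__(self, size: int = 2):
        self.size = size
        self._cache = None

    def forward(self, x, train):
        n, c, h, w = x.shape
        s = self.size
        if h % s or w % s:
            raise ValueError(f"spatial dims {h}x{w} not divisible by pool size {s}")
        win = x.reshape(n, c, h // s, s, w // s, s)
        out = win.max(axis=(3, 5))
        if train:
            self._cache = (win, out, x.shape)
        return out

    def backward(self, grad):
        win, out, shape = self._cache
        s = self.size
        mask = win == out[:, :, :, None, :, None]
        counts = mask.sum(axis=(3, 5), keepdims=True)
        d = mask / counts * grad[:, :, :, None, :, None]
        return d.reshape(shape)


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean; the branch pooling before fusion."""

    def __init__(self):
        self._shape = None

    def forward(self, x, train):
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], (n, c, h, w)) / (h * w)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / d_in), (d_in, d_out))
        self.b = np.zeros(d_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.dw[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}


class Dropout(Layer):
    """Inverted dropout; active only during training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


def run_forward(layers: Sequence[Layer], x: np.ndarray, train: bool) -> np.ndarray:
    for layer in layers:
        x = layer.forward(x, train)
    return x


def run_backward(layers: Sequence[Layer], grad: np.ndarray) -> np.ndarray:
    for layer in reversed(layers):
        grad = layer.backward(grad)
    return grad


class Adam:
    """Adam optimizer over the trainable layers of a layer list."""

    def __init__(
        self,
        layers: Iterable[Layer],
        lr: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.entries = []
        for layer in layers:
            if not layer.trainable:
                continue
            grads = layer.grads()
            for name, p in layer.params().items():
                self.entries.append(
                    (p, grads[name], np.zeros_like(p), np.zeros_like(p))
                )
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in self.entries:
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def layers_state(layers: Sequence[Layer], prefix: str = "") -> dict[str, np.ndarray]:
    out = {}
    for i, layer in enumerate(layers):
        for k, v in layer.state().items():
            out[f"{prefix}{i}.{k}"] = v
    return out


def snapshot(layers: Sequence[Layer]) -> dict[str, np.ndarray]:
    return {k: v.copy() for k, v in layers_state(layers).items()}


def restore(layers: Sequence[Layer], snap: dict[str, np.ndarray]) -> None:
    state = layers_state(layers)
    for k, v in snap.items():
        state[k][...] = v
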
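"""Minimal NumPy neural-network engine for 1-D convolutional classifiers.

Implements exactly the pieces the artifact classifier needs — 1-D convolution
(same padding), ReLU, batch normalisation, max pooling, global average pooling,
dense layers, a numerically stable binary cross-entropy on soft targets, the
AdamW optimizer (decoupled weight decay) and a cosine-annealed learning rate.
Everything is float32 and deterministic given a seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv1D",
    "ReLU",
    "BatchNorm1D",
    "MaxPool1D",
    "GlobalAvgPool1D",
    "Dense",
    "Sequential",
    "AdamW",
    "bce_with_logits",
    "bce_probs",
    "cosine_lr",
]


class Param:
    """A trainable tensor with its gradient.

    ``decay`` marks parameters subject to weight decay (connection weights);
    biases and normalisation parameters are excluded, the usual convention.
    """

    def __init__(self, value: np.ndarray, decay: bool = False):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.decay = decay

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv1D:
    """1-D convolution with 'same' zero padding, stride 1.

    Input/output layout is (batch, channels, length). Implemented as
    im2col + GEMM so the heavy lifting runs in BLAS.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        fan_in = c_in * kernel
        self.w = Param(_he_init(rng, (c_out, c_in * kernel), fan_in), decay=True)
        self.b = Param(np.zeros(c_out, dtype=np.float32))
        self._cols: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, length = x.shape
        pad = self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        # (n, c, length, kernel) windows -> (n*length, c*kernel)
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        cols = win.transpose(0, 2, 1, 3).reshape(n * length, c * self.kernel)
        cols = np.ascontiguousarray(cols)
        if train:
            self._cols = cols
            self._shape = (n, c, length)
        y = cols @ self.w.value.T + self.b.value
        return y.reshape(n, length, self.c_out).transpose(0, 2, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, length = self._shape
        d2 = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(n * length, self.c_out)
        self.w.grad += d2.T @ self._cols
        self.b.grad += d2.sum(axis=0)
        dcols = (d2 @ self.w.value).reshape(n, length, c, self.kernel)
        pad = self.kernel // 2
        dxp = np.zeros((n, c, length + 2 * pad), dtype=np.float32)
        for k in range(self.kernel):
            dxp[:, :, k : k + length] += dcols[:, :, :, k].transpose(0, 2, 1)
        self._cols = None
        return dxp[:, :, pad : pad + length]


class ReLU:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class BatchNorm1D:
    """Batch normalisation over (batch, length) per channel, with running stats."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels, dtype=np.float32))
        self.beta = Param(np.zeros(channels, dtype=np.float32))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None]) * inv[:, None]
        if train:
            self._xhat, self._inv = xhat, inv
        return self.gamma.value[:, None] * xhat + self.beta.value[:, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n_eff = dy.shape[0] * dy.shape[2]
        self.gamma.grad += (dy * self._xhat).sum(axis=(0, 2))
        self.beta.grad += dy.sum(axis=(0, 2))
        g = self.gamma.value[:, None]
        dxhat = dy * g
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2), keepdims=True)
            - self._xhat * (dxhat * self._xhat).sum(axis=(0, 2), keepdims=True) / n_eff
        ) * self._inv[:, None]
        self._xhat = self._inv = None
        return dx.astype(np.float32)


class MaxPool1D:
    """Non-overlapping max pooling; input length must be divisible by the factor."""

    def __init__(self, factor: int = 2):
        self.factor = factor

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, length = x.shape
        f = self.factor
        if length % f:
            raise ValueError(f"length {length} not divisible by pool factor {f}")
        xr = x.reshape(n, c, length // f, f)
        idx = xr.argmax(axis=3)
        if train:
            self._idx, self._shape = idx, x.shape
        return np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, length = self._shape
        f = self.factor
        dxr = np.zeros((n, c, length // f, f), dtype=np.float32)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=3)
        return dxr.reshape(n, c, length)


class GlobalAvgPool1D:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._len = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, :, None], self._len, axis=2) / np.float32(self._len)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Param(_he_init(rng, (n_out, n_in), n_in), decay=True)
        self.b = Param(np.zeros(n_out, dtype=np.float32))

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        self._x = None
        return dy @ self.w.value


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    # --- state (de)serialisation -------------------------------------------
    def state(self) -> list[np.ndarray]:
        out = [p.value.copy() for p in self.params()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm1D):
                out.append(layer.running_mean.copy())
                out.append(layer.running_var.copy())
        return out

    def load_state(self, state: list[np.ndarray]) -> None:
        ps = self.params()
        for p, v in zip(ps, state[: len(ps)]):
            p.value = np.asarray(v, dtype=np.float32).copy()
            p.grad = np.zeros_like(p.value)
        extra = iter(state[len(ps) :])
        for layer in self.layers:
            if isinstance(layer, BatchNorm1D):
                layer.running_mean = np.asarray(next(extra), dtype=np.float32).copy()
                layer.running_var = np.asarray(next(extra), dtype=np.float32).copy()


class AdamW:
    """Adam with decoupled weight decay (decay applied only to flagged params)."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            update = mhat / (np.sqrt(vhat) + self.eps)
            if p.decay:
                update = update + self.weight_decay * p.value
            p.value -= np.float32(self.lr) * update.astype(np.float32)


def cosine_lr(initial_lr: float, epoch: int, period: int) -> float:
    """Cosine-annealed learning rate, decaying from ``initial_lr`` to 0 over ``period``."""
    if period <= 1:
        return initial_lr
    frac = min(epoch, period - 1) / (period - 1)
    return 0.5 * initial_lr * (1.0 + np.cos(np.pi * frac))


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy of logits ``z`` against soft targets ``y`` in [0,1].

    Returns (loss, dloss/dz). Stable for large |z|. With 0/1 targets this is
    the standard BCE; with fractional targets it is the soft-label form.
    """
    z = z.astype(np.float64)
    y = y.astype(np.float64)
    loss = np.mean(np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z))))
    p = 1.0 / (1.0 + np.exp(-z))
    dz = ((p - y) / z.size).astype(np.float32)
    return float(loss), dz


def bce_probs(p: np.ndarray, y: np.ndarray, eps: float = 1e-7) -> float:
    """Mean BCE of probabilities against soft targets (evaluation helper)."""
    p = np.clip(np.asarray(p, dtype=np.float64), eps, 1.0 - eps)
    y = np.asarray(y, dtype=np.float64)
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))
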
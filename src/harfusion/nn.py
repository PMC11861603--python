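"""Minimal numpy neural-network engine used by the activity classifiers.

Implements exactly the pieces the fusion architecture needs: 2-D and 1-D
convolutions (stride 1, "same" padding, via im2col + GEMM), max pooling,
dense layers, ReLU, a softmax cross-entropy head, the Adam optimizer and a
reduce-on-plateau learning-rate schedule.  Everything is float32 and runs
single-threaded through BLAS, so training is bit-reproducible for a fixed
seed on a given machine.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "Conv1D",
    "MaxPool2D",
    "MaxPool1D",
    "ReLU",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
    "ReduceLROnPlateau",
    "softmax",
    "softmax_cross_entropy",
]

_F32 = np.float32


def _glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + shape[-1]))
    return rng.uniform(-limit, limit, size=shape).astype(_F32)


class Layer:
    """Base layer: forward caches what backward needs; params/grads align."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


def _im2col2d(x: np.ndarray, k: int) -> np.ndarray:
    """Unfold (N,H,W,C) into contiguous (N*H*W, k*k*C) patch rows for same-conv.

    Built as k*k shifted block copies, which is much faster than a strided
    gather; the trailing reshape is free because the buffer is contiguous.
    """
    n, h, w, c = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    cols = np.empty((n, h, w, k * k, c), dtype=_F32)
    for ki in range(k):
        for kj in range(k):
            cols[:, :, :, ki * k + kj, :] = xp[:, ki:ki + h, kj:kj + w, :]
    return cols.reshape(n * h * w, k * k * c)


class Conv2D(Layer):
    """Stride-1, same-padding 2-D convolution on NHWC tensors.

    ``input_grad=False`` skips the input-gradient GEMM in backward (valid for
    the first layer of a network, where nothing is below).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, input_grad: bool = True) -> None:
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for same padding")
        self.k = kernel_size
        self.cin = in_channels
        self.cout = out_channels
        self.input_grad = input_grad
        fan_in = kernel_size * kernel_size * in_channels
        # weight layout (k*k*cin, cout) so forward is a single GEMM
        self.w = _glorot_uniform(rng, (fan_in, out_channels), fan_in)
        self.b = np.zeros(out_channels, dtype=_F32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[3] != self.cin:
            raise ValueError(f"Conv2D expects (N,H,W,{self.cin}), got {x.shape}")
        self._xshape = x.shape
        self._cols = _im2col2d(x.astype(_F32, copy=False), self.k)
        out = self._cols @ self.w + self.b
        n, h, w = x.shape[:3]
        return out.reshape(n, h, w, self.cout)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, _ = self._xshape
        g2 = np.ascontiguousarray(grad.reshape(n * h * w, self.cout), dtype=_F32)
        self.grads[0][...] = self._cols.T @ g2
        self.grads[1][...] = g2.sum(axis=0)
        self._cols = None
        if not self.input_grad:
            return np.zeros(self._xshape, dtype=_F32)
        # dx = same-conv of grad with spatially flipped, channel-transposed kernels
        k = self.k
        w4 = self.w.reshape(k, k, self.cin, self.cout)
        w_hat = np.ascontiguousarray(
            w4[::-1, ::-1].transpose(0, 1, 3, 2).reshape(k * k * self.cout, self.cin))
        cols = _im2col2d(g2.reshape(n, h, w, self.cout), k)
        dx = cols @ w_hat
        return dx.reshape(n, h, w, self.cin)


def _im2col1d(x: np.ndarray, k: int) -> np.ndarray:
    """Unfold (N,L,C) into contiguous (N*L, k*C) patch rows for same-conv."""
    n, length, c = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
    cols = np.empty((n, length, k, c), dtype=_F32)
    for ki in range(k):
        cols[:, :, ki, :] = xp[:, ki:ki + length, :]
    return cols.reshape(n * length, k * c)


class Conv1D(Layer):
    """Stride-1, same-padding 1-D convolution on (N, L, C) tensors."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, input_grad: bool = True) -> None:
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for same padding")
        self.k = kernel_size
        self.cin = in_channels
        self.cout = out_channels
        self.input_grad = input_grad
        fan_in = kernel_size * in_channels
        self.w = _glorot_uniform(rng, (fan_in, out_channels), fan_in)
        self.b = np.zeros(out_channels, dtype=_F32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 3 or x.shape[2] != self.cin:
            raise ValueError(f"Conv1D expects (N,L,{self.cin}), got {x.shape}")
        self._xshape = x.shape
        self._cols = _im2col1d(x.astype(_F32, copy=False), self.k)
        out = self._cols @ self.w + self.b
        n, length = x.shape[:2]
        return out.reshape(n, length, self.cout)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, length, _ = self._xshape
        g2 = np.ascontiguousarray(grad.reshape(n * length, self.cout), dtype=_F32)
        self.grads[0][...] = self._cols.T @ g2
        self.grads[1][...] = g2.sum(axis=0)
        self._cols = None
        if not self.input_grad:
            return np.zeros(self._xshape, dtype=_F32)
        k = self.k
        w3 = self.w.reshape(k, self.cin, self.cout)
        w_hat = np.ascontiguousarray(
            w3[::-1].transpose(0, 2, 1).reshape(k * self.cout, self.cin))
        cols = _im2col1d(g2.reshape(n, length, self.cout), k)
        dx = cols @ w_hat
        return dx.reshape(n, length, self.cin)


class MaxPool2D(Layer):
    """2x2 max pooling; spatial dims must be even (the 64->2 chain keeps them so)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2D needs even spatial dims, got {x.shape}")
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        # ties (common among ReLU zeros) share the gradient equally
        mask = xr == out[:, :, None, :, None, :]
        self._mask = mask
        self._counts = mask.sum(axis=(2, 4), keepdims=True)
        self._xshape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad[:, :, None, :, None, :] / self._counts
        dx = (self._mask * g).reshape(self._xshape)
        self._mask = None
        return dx


class MaxPool1D(Layer):
    """Size-2 max pooling with floor semantics: an odd trailing element is dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, length, c = x.shape
        if length < 2:
            raise ValueError("MaxPool1D needs length >= 2")
        self._xshape = x.shape
        lt = (length // 2) * 2
        xr = x[:, :lt].reshape(n, length // 2, 2, c)
        out = xr.max(axis=2)
        mask = xr == out[:, :, None, :]
        self._mask = mask
        self._counts = mask.sum(axis=2, keepdims=True)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, length, c = self._xshape
        g = grad[:, :, None, :] / self._counts
        dx = np.zeros(self._xshape, dtype=grad.dtype)
        lt = (length // 2) * 2
        dx[:, :lt] = (self._mask * g).reshape(n, lt, c)
        self._mask = None
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = grad * self._mask
        self._mask = None
        return out


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._xshape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.w = _glorot_uniform(rng, (in_features, out_features), in_features)
        self.b = np.zeros(out_features, dtype=_F32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 2 or x.shape[1] != self.w.shape[0]:
            raise ValueError(f"Dense expects (N,{self.w.shape[0]}), got {x.shape}")
        self._x = x.astype(_F32, copy=False)
        return self._x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad.astype(_F32, copy=False)
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        dx = g @ self.w.T
        self._x = None
        return dx


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def forward_shapes(self, x: np.ndarray) -> list[tuple[int, ...]]:
        """Per-layer output shapes for one input batch (architecture introspection)."""
        shapes = []
        for layer in self.layers:
            x = layer.forward(x)
            shapes.append(x.shape)
        return shapes


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    probs = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = float(-(onehot * np.log(np.clip(probs, 1e-12, None))).sum() / n)
    dlogits = ((probs - onehot) / n).astype(_F32)
    return loss, dlogits


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 0.005,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


class ReduceLROnPlateau:
    """Multiply the learning rate by `factor` when the monitored loss has not
    improved by more than `min_delta` for `patience` consecutive epochs."""

    def __init__(self, optimizer: Adam, factor: float = 0.7, patience: int = 3,
                 min_delta: float = 1e-4, min_lr: float = 0.0) -> None:
        if not 0.0 < factor < 1.0:
            raise ValueError("factor must lie in (0, 1)")
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_delta = min_delta
        self.min_lr = min_lr
        self.best = np.inf
        self.wait = 0

    @property
    def lr(self) -> float:
        return self.optimizer.lr

    def step(self, loss: float) -> bool:
        """Record one epoch's monitored loss; returns True if the rate was reduced."""
        if loss < self.best - self.min_delta:
            self.best = loss
            self.wait = 0
            return False
        self.wait += 1
        if self.wait > self.patience:
            self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
            self.wait = 0
            return True
        return False
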
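"""Minimal NHWC neural-network core: layers with explicit backward passes.

Every layer owns its parameters as :class:`Param` objects (value + gradient
buffer) and implements ``forward(x, train)`` / ``backward(grad_out)``.
Convolutions run as im2col + GEMM with persistent scratch buffers so repeated
batches of the same shape do not re-touch fresh pages.  Arrays are
channels-last: ``(N, H, W, C)`` for 2-D layers, ``(N, C)`` for dense layers.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Dense",
    "Conv2d",
    "BatchNorm",
    "ReLU",
    "MaxPool2",
    "GlobalAvgPool",
    "Dropout",
    "Sequential",
    "silu",
    "silu_grad",
    "softmax",
    "softmax_cross_entropy",
    "Nadam",
]


def silu(x: np.ndarray) -> np.ndarray:
    """SiLU (swish) activation x * sigmoid(x), numerically stable."""
    return x / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def silu_grad(x: np.ndarray) -> np.ndarray:
    s = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
    return s * (1.0 + x * (1.0 - s))


class Param:
    """A learnable tensor together with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.ascontiguousarray(value)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    """Base class; stateless layers only implement forward/backward."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)


class Dense(Layer):
    """Affine map (N, n_in) -> (N, n_out) with optional bias."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True, dtype=np.float32) -> None:
        if n_in <= 0 or n_out <= 0:
            raise ValueError("Dense widths must be positive")
        limit = np.sqrt(6.0 / n_in)
        self.w = Param(rng.uniform(-limit, limit, (n_in, n_out)).astype(dtype), "dense.w")
        self.b = Param(np.zeros(n_out, dtype=dtype), "dense.b") if bias else None
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[-1] != self.w.value.shape[0]:
            raise ValueError(
                f"Dense expected width {self.w.value.shape[0]}, got {x.shape[-1]}")
        self._x = x
        y = x @ self.w.value
        if self.b is not None:
            y += self.b.value
        return y

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ grad_out
        if self.b is not None:
            self.b.grad += grad_out.sum(axis=0)
        return grad_out @ self.w.value.T


class Conv2d(Layer):
    """Same-padded stride-1 convolution, NHWC, square kernel, no bias.

    Runs as im2col + GEMM over batch chunks, with scratch buffers reused
    across calls so peak memory stays bounded regardless of feature-map
    size.  The input gradient uses the transposed-kernel trick (correlate
    the padded output gradient with the spatially flipped kernel); set
    ``input_grad = False`` on a first layer to skip it entirely.
    """

    #: target scratch-buffer size per im2col chunk
    _CHUNK_BYTES = 48 * 1024 * 1024

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 3, dtype=np.float32) -> None:
        if kernel % 2 != 1:
            raise ValueError("only odd kernels supported")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan_in = kernel * kernel * c_in
        limit = np.sqrt(6.0 / fan_in)
        self.w = Param(
            rng.uniform(-limit, limit, (kernel, kernel, c_in, c_out)).astype(dtype),
            "conv.w")
        self.input_grad = True
        self._buffers: dict[tuple, np.ndarray] = {}
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w]

    def _buf(self, key: str, shape: tuple, dtype) -> np.ndarray:
        full = (key,) + shape + (np.dtype(dtype).str,)
        buf = self._buffers.get(full)
        if buf is None:
            buf = np.empty(shape, dtype=dtype)
            self._buffers[full] = buf
        return buf

    def _chunk_size(self, h: int, w: int, c: int, itemsize: int) -> int:
        per_sample = h * w * self.k * self.k * c * itemsize
        return max(1, self._CHUNK_BYTES // max(per_sample, 1))

    def _im2col_chunk(self, x: np.ndarray, c: int, key: str) -> np.ndarray:
        """im2col of one batch chunk into a persistent buffer."""
        n, h, w = x.shape[:3]
        p = self.k // 2
        xp = self._buf(key + ".pad", (n, h + 2 * p, w + 2 * p, c), x.dtype)
        xp.fill(0.0)
        xp[:, p:h + p, p:w + p, :] = x
        win = sliding_window_view(xp, (self.k, self.k, c), axis=(1, 2, 3))[:, :, :, 0]
        cols = self._buf(key + ".cols", (n * h * w, self.k * self.k * c), x.dtype)
        np.copyto(cols.reshape(n, h, w, self.k, self.k, c), win)
        return cols

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[3] != self.c_in:
            raise ValueError(f"Conv2d expected (N,H,W,{self.c_in}), got {x.shape}")
        n, h, w, _ = x.shape
        self._x = x
        wflat = self.w.value.reshape(-1, self.c_out)
        y = self._buf("y", (n, h, w, self.c_out), x.dtype)
        step = self._chunk_size(h, w, self.c_in, x.dtype.itemsize)
        for s in range(0, n, step):
            xb = x[s:s + step]
            cols = self._im2col_chunk(xb, self.c_in, "fwd")
            np.matmul(cols, wflat, out=y[s:s + step].reshape(-1, self.c_out))
        return y

    def backward(self, grad_out: np.ndarray) -> np.ndarray | None:
        x = self._x
        n, h, w, _ = x.shape
        w_rot = np.ascontiguousarray(
            self.w.value[::-1, ::-1].transpose(0, 1, 3, 2)
        ).reshape(-1, self.c_in)  # (k*k*c_out, c_in)
        gx = self._buf("gx", x.shape, grad_out.dtype) if self.input_grad else None
        step_f = self._chunk_size(h, w, self.c_in, x.dtype.itemsize)
        step_b = self._chunk_size(h, w, self.c_out, grad_out.dtype.itemsize)
        step = min(step_f, step_b)
        dw = self.w.grad.reshape(-1, self.c_out)
        for s in range(0, n, step):
            gb = grad_out[s:s + step]
            cols = self._im2col_chunk(x[s:s + step], self.c_in, "fwd")
            dw += cols.T @ gb.reshape(-1, self.c_out)
            if self.input_grad:
                gcols = self._im2col_chunk(gb, self.c_out, "bwd")
                np.matmul(gcols, w_rot,
                          out=gx[s:s + step].reshape(-1, self.c_in))
        return gx


class BatchNorm(Layer):
    """Batch normalization over all axes except the last (channel) axis."""

    def __init__(self, n_ch: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32) -> None:
        self.gamma = Param(np.ones(n_ch, dtype=dtype), "bn.gamma")
        self.beta = Param(np.zeros(n_ch, dtype=dtype), "bn.beta")
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(n_ch, dtype=dtype)
        self.running_var = np.ones(n_ch, dtype=dtype)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            xhat = x - mean  # centered; scaled in place below
            var = np.mean(np.square(xhat), axis=axes)
            m = self.momentum
            # in place: external holders of these arrays stay valid
            self.running_mean *= m
            self.running_mean += (1 - m) * mean
            self.running_var *= m
            self.running_var += (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
            xhat = x - mean
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat *= inv_std
        self._cache = (xhat, inv_std, axes)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        xhat, inv_std, axes = self._cache
        self.gamma.grad += (grad_out * xhat).sum(axis=axes)
        self.beta.grad += grad_out.sum(axis=axes)
        g = grad_out * self.gamma.value
        g -= g.mean(axis=axes)
        g -= xhat * np.mean(g * xhat, axis=axes)
        g *= inv_std
        return g


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        grad_out *= self._mask  # upstream gradients are freshly allocated
        return grad_out


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; odd trailing rows/columns are dropped.

    The gradient is split evenly among tied maxima within a window (a
    valid subgradient; ties are common after ReLU zeros).
    """

    @staticmethod
    def _quadrants(x: np.ndarray):
        h2, w2 = x.shape[1] // 2, x.shape[2] // 2
        return [x[:, i:2 * h2:2, j:2 * w2:2, :] for i in (0, 1) for j in (0, 1)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        q = self._quadrants(x)
        y = np.maximum(np.maximum(q[0], q[1]), np.maximum(q[2], q[3]))
        self._y = y
        return y

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x, y = self._x, self._y
        masks = [q == y for q in self._quadrants(x)]
        count = masks[0].astype(grad_out.dtype)
        for m in masks[1:]:
            count += m
        scale = grad_out / count
        gx = np.zeros_like(x)
        for m, gq in zip(masks, self._quadrants(gx)):
            gq[...] = m * scale
        return gx


class GlobalAvgPool(Layer):
    """Mean over the spatial axes: (N, H, W, C) -> (N, C)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        return np.broadcast_to(grad_out[:, None, None, :] / (h * w),
                               self._in_shape).astype(grad_out.dtype)


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate, self.rng = rate, rng
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out if self._mask is None else grad_out * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy of integer labels; returns (loss, dloss/dlogits)."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = np.finfo(p.dtype).tiny
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


class Nadam:
    """Nesterov-accelerated Adam (Dozat 2016, simplified schedule)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad.fill(0.0)

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c1n = 1.0 - b1 ** (self.t + 1)
        c2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = b1 * m / c1n + (1 - b1) * g / c1
            v_hat = v / c2
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
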
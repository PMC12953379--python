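"""Minimal neural-network layers on numpy with explicit backpropagation.

The staging model needs 1-D (dilated) convolutions, pooling, batch/layer
normalization, dense layers, multi-head self-attention and an AdamW
optimizer. Each layer is an object with ``forward(x, train)`` /
``backward(grad_out)`` methods and a ``params()`` list; gradients accumulate
into ``Param.grad`` so several nights can contribute to one optimizer step
(gradient accumulation). All layers are verified against finite-difference
gradients in the test suite.

Shapes: convolutional layers operate on ``(channels, length)`` arrays;
dense/attention layers on ``(time, features)``. One forward call processes
one night (no batch axis); batching is by gradient accumulation.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv1d",
    "MaxPool1d",
    "BatchNorm1d",
    "LayerNorm",
    "ReLU",
    "Dropout",
    "Linear",
    "MultiHeadSelfAttention",
    "Sequential",
    "masked_cross_entropy",
    "softmax",
    "AdamW",
]


_GRAD_ENABLED = True


class no_grad:
    """Context manager that disables caching of backprop intermediates.

    Inside the context, ``backward`` is unavailable but large forward passes
    (e.g. a full 10-h window) use far less memory.
    """

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def grad_enabled() -> bool:
    return _GRAD_ENABLED


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)


class Conv1d(Layer):
    """Same-padded 1-D convolution on (C_in, L) -> (C_out, L)."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 dilation: int = 1, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.w = Param((rng.standard_normal((c_out, kernel * c_in)) * scale)
                       .astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self.c_in, self.c_out, self.kernel, self.dilation = c_in, c_out, kernel, dilation

    def _cols(self, x: np.ndarray) -> np.ndarray:
        k, d = self.kernel, self.dilation
        L = x.shape[1]
        span = (k - 1) * d
        left = span // 2
        xp = np.zeros((x.shape[0], L + span), dtype=x.dtype)
        xp[:, left:left + L] = x
        # (k*C_in, L) column matrix
        return np.concatenate([xp[:, i * d:i * d + L] for i in range(k)], axis=0)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[0] != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {x.shape[0]}")
        cols = self._cols(x)
        self._cache = (cols, x.shape) if _GRAD_ENABLED else None
        # w is (C_out, k*C_in) with kernel-major blocks matching _cols order
        return self.w.value @ cols + self.b.value[:, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        self.w.grad += gy @ cols.T
        self.b.grad += gy.sum(axis=1)
        gcols = self.w.value.T @ gy  # (k*C_in, L)
        k, d = self.kernel, self.dilation
        C, L = xshape
        span = (k - 1) * d
        left = span // 2
        gxp = np.zeros((C, L + span), dtype=gy.dtype)
        for i in range(k):
            gxp[:, i * d:i * d + L] += gcols[i * C:(i + 1) * C]
        return gxp[:, left:left + L]

    def params(self) -> list[Param]:
        return [self.w, self.b]


class MaxPool1d(Layer):
    """Non-overlapping max pooling along the length axis."""

    def __init__(self, factor: int = 2):
        self.factor = factor

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        f = self.factor
        C, L = x.shape
        if L % f:
            raise ValueError(f"length {L} not divisible by pool factor {f}")
        xr = x.reshape(C, L // f, f)
        if _GRAD_ENABLED:
            self._arg = xr.argmax(axis=2)
            self._shape = (C, L)
        return xr.max(axis=2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        C, L = self._shape
        f = self.factor
        gx = np.zeros((C, L // f, f), dtype=gy.dtype)
        ci, li = np.ogrid[:C, :L // f]
        gx[ci, li, self._arg] = gy
        return gx.reshape(C, L)


class BatchNorm1d(Layer):
    """Per-channel normalization over the length axis with running stats.

    With one night per forward pass this normalizes each channel over time
    (instance statistics); running estimates are used in eval mode.
    """

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Param(np.ones(c, dtype=dtype))
        self.beta = Param(np.zeros(c, dtype=dtype))
        self.run_mean = np.zeros(c, dtype=np.float64)
        self.run_var = np.ones(c, dtype=np.float64)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mu = x.mean(axis=1)
            var = x.var(axis=1)
            self.run_mean += self.momentum * (mu - self.run_mean)
            self.run_var += self.momentum * (var - self.run_var)
        else:
            mu, var = self.run_mean.astype(x.dtype), self.run_var.astype(x.dtype)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[:, None]) * inv[:, None]
        self._cache = (xhat, inv.astype(x.dtype), train) if _GRAD_ENABLED else None
        return self.gamma.value[:, None] * xhat + self.beta.value[:, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv, train = self._cache
        self.gamma.grad += (gy * xhat).sum(axis=1)
        self.beta.grad += gy.sum(axis=1)
        gxhat = gy * self.gamma.value[:, None]
        if not train:
            return gxhat * inv[:, None]
        N = xhat.shape[1]
        return (inv[:, None] / N) * (
            N * gxhat
            - gxhat.sum(axis=1, keepdims=True)
            - xhat * (gxhat * xhat).sum(axis=1, keepdims=True)
        )

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class LayerNorm(Layer):
    """Normalization over the feature (last) axis of (T, D) inputs."""

    def __init__(self, d: int, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Param(np.ones(d, dtype=dtype))
        self.beta = Param(np.zeros(d, dtype=dtype))
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv) if _GRAD_ENABLED else None
        return self.gamma.value * xhat + self.beta.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self.gamma.grad += (gy * xhat).sum(axis=0)
        self.beta.grad += gy.sum(axis=0)
        gxhat = gy * self.gamma.value
        D = xhat.shape[-1]
        return (inv / D) * (
            D * gxhat
            - gxhat.sum(axis=-1, keepdims=True)
            - xhat * (gxhat * xhat).sum(axis=-1, keepdims=True)
        )

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if _GRAD_ENABLED:
            self._mask = x > 0
            return x * self._mask
        return np.maximum(x, 0.0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator | None = None):
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask.astype(x.dtype)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return gy
        return gy * self._mask.astype(gy.dtype)


class Linear(Layer):
    """Dense map on the last axis: (T, D_in) -> (T, D_out)."""

    def __init__(self, d_in: int, d_out: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / d_in)
        self.w = Param((rng.standard_normal((d_in, d_out)) * scale).astype(dtype))
        self.b = Param(np.zeros(d_out, dtype=dtype))
        self.d_in, self.d_out = d_in, d_out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[-1] != self.d_in:
            raise ValueError(f"expected {self.d_in} input features, got {x.shape[-1]}")
        self._x = x if _GRAD_ENABLED else None
        return x @ self.w.value + self.b.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ gy
        self.b.grad += gy.sum(axis=0)
        return gy @ self.w.value.T

    def params(self) -> list[Param]:
        return [self.w, self.b]


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class MultiHeadSelfAttention(Layer):
    """Full-sequence multi-head self-attention on (T, D)."""

    def __init__(self, d: int, heads: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        if d % heads:
            raise ValueError("model dim must be divisible by the head count")
        rng = rng or np.random.default_rng(0)
        self.d, self.heads, self.dh = d, heads, d // heads
        scale = np.sqrt(1.0 / d)

        def mk():
            return Param((rng.standard_normal((d, d)) * scale).astype(dtype))

        self.wq, self.wk, self.wv, self.wo = mk(), mk(), mk(), mk()

    def _split(self, x: np.ndarray) -> np.ndarray:
        T = x.shape[0]
        return x.reshape(T, self.heads, self.dh).transpose(1, 0, 2)  # (H, T, dh)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        H, T, dh = x.shape
        return x.transpose(1, 0, 2).reshape(T, H * dh)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        q = self._split(x @ self.wq.value)
        k = self._split(x @ self.wk.value)
        v = self._split(x @ self.wv.value)
        att = softmax(q @ k.transpose(0, 2, 1) / np.sqrt(self.dh), axis=-1)
        ctx = att @ v  # (H, T, dh)
        out = self._merge(ctx)
        self._cache = (x, q, k, v, att, out) if _GRAD_ENABLED else None
        return out @ self.wo.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x, q, k, v, att, out = self._cache
        self.wo.grad += out.T @ gy
        gout = gy @ self.wo.value.T
        gctx = self._split(gout)
        gatt = gctx @ v.transpose(0, 2, 1)
        gv = att.transpose(0, 2, 1) @ gctx
        # softmax backward per row
        gscore = att * (gatt - (gatt * att).sum(axis=-1, keepdims=True))
        gscore /= np.sqrt(self.dh)
        gq = gscore @ k
        gk = gscore.transpose(0, 2, 1) @ q
        gx = np.zeros_like(x)
        for w, g in ((self.wq, gq), (self.wk, gk), (self.wv, gv)):
            gm = self._merge(g)
            w.grad += x.T @ gm
            gx += gm @ w.value.T
        return gx

    def params(self) -> list[Param]:
        return [self.wq, self.wk, self.wv, self.wo]


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            gy = l.backward(gy)
        return gy

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]


def masked_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, mask: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over masked-in epochs and its gradient wrt logits.

    Epochs with ``mask`` False contribute exactly zero loss and gradient.
    Returns ``(nan, zeros)`` if the mask is empty.
    """
    mask = mask.astype(bool)
    n = int(mask.sum())
    glogits = np.zeros_like(logits)
    if n == 0:
        return float("nan"), glogits
    p = softmax(logits[mask], axis=-1)
    picked = p[np.arange(n), labels[mask]]
    loss = -np.log(np.maximum(picked, 1e-12)).mean()
    g = p.copy()
    g[np.arange(n), labels[mask]] -= 1.0
    glogits[mask] = g / n
    return float(loss), glogits


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.ps = params
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.value, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p.value, dtype=np.float64) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.ps, self.m, self.v):
            g = p.grad.astype(np.float64)
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            upd = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.value -= (self.lr * (upd + self.wd * p.value)).astype(p.value.dtype)

    def zero_grad(self) -> None:
        for p in self.ps:
            p.zero_grad()
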
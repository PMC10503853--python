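"""Minimal numpy neural-network kernel: LSTM layer, linear head, dropout, Adam.

Layers follow the usual define-forward/backward contract: ``forward`` caches
what the analytic backward pass needs, ``backward`` consumes the upstream
gradient, accumulates parameter gradients in-place and returns the input
gradient. Gate layout inside the fused LSTM weight matrices is
``[input, forget, cell, output]``. Gradients are exercised against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as sigmoid

__all__ = ["Parameter", "LSTMLayer", "Linear", "Dropout", "Adam", "sigmoid"]


class Parameter:
    """A learnable tensor with an in-place accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray, dtype: np.dtype | str = np.float32):
        self.value = np.asarray(value, dtype=dtype)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0

    @property
    def size(self) -> int:
        return self.value.size


class LSTMLayer:
    """A batched LSTM scanning (B, T, in_dim) → (B, T, hidden).

    Weights may be shared with another layer (``share_with``), in which case
    both layers hold the *same* :class:`Parameter` objects and gradients
    accumulate across both uses — this is how weight-tied directional cores
    are built.
    """

    def __init__(
        self,
        in_dim: int,
        hidden: int,
        rng: np.random.Generator | None = None,
        share_with: "LSTMLayer | None" = None,
        dtype: np.dtype | str = np.float32,
    ):
        self.in_dim = in_dim
        self.hidden = hidden
        self.dtype = np.dtype(dtype)
        if share_with is not None:
            if (share_with.in_dim, share_with.hidden) != (in_dim, hidden):
                raise ValueError("cannot share weights across mismatched layer sizes")
            self.wx, self.wh, self.b = share_with.wx, share_with.wh, share_with.b
            self.dtype = share_with.dtype
        else:
            if rng is None:
                raise ValueError("rng required when not sharing weights")
            k = 1.0 / np.sqrt(hidden)
            self.wx = Parameter(rng.uniform(-k, k, (in_dim, 4 * hidden)), dtype)
            self.wh = Parameter(rng.uniform(-k, k, (hidden, 4 * hidden)), dtype)
            b = np.zeros(4 * hidden)
            b[hidden : 2 * hidden] = 1.0  # forget-gate bias: remember by default
            self.b = Parameter(b, dtype)
        self._cache: list[tuple] | None = None
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.wx, self.wh, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=self.dtype)
        b_sz, t_len, _ = x.shape
        hh = self.hidden
        h = np.zeros((b_sz, hh), dtype=self.dtype)
        c = np.zeros((b_sz, hh), dtype=self.dtype)
        out = np.empty((b_sz, t_len, hh), dtype=self.dtype)
        wh, bias = self.wh.value, self.b.value
        # input projection for all time steps in one matmul
        xw = x.reshape(-1, self.in_dim) @ self.wx.value + bias
        xw = xw.reshape(b_sz, t_len, 4 * hh)
        cache = []
        for t in range(t_len):
            z = xw[:, t] + h @ wh
            i = sigmoid(z[:, :hh])
            f = sigmoid(z[:, hh : 2 * hh])
            g = np.tanh(z[:, 2 * hh : 3 * hh])
            o = sigmoid(z[:, 3 * hh :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            out[:, t] = h_new
        self._x = x
        self._cache = cache
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called before forward")
        cache = self._cache
        dout = np.ascontiguousarray(dout, dtype=self.dtype)
        b_sz, t_len, hh = dout.shape
        dz_all = np.empty((b_sz, t_len, 4 * hh), dtype=self.dtype)
        dh_next = np.zeros((b_sz, hh), dtype=self.dtype)
        dc_next = np.zeros((b_sz, hh), dtype=self.dtype)
        wh = self.wh.value
        dwh = self.wh.grad
        for t in range(t_len - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = cache[t]
            dh = dout[:, t] + dh_next
            dc = dh * o * (1.0 - tc * tc) + dc_next
            dz = dz_all[:, t]
            dz[:, :hh] = dc * g * i * (1.0 - i)
            dz[:, hh : 2 * hh] = dc * c_prev * f * (1.0 - f)
            dz[:, 2 * hh : 3 * hh] = dc * i * (1.0 - g * g)
            dz[:, 3 * hh :] = dh * tc * o * (1.0 - o)
            dwh += h_prev.T @ dz
            dh_next = dz @ wh.T
            dc_next = dc * f
        dz2 = dz_all.reshape(-1, 4 * hh)
        x2 = self._x.reshape(-1, self.in_dim)
        self.wx.grad += x2.T @ dz2
        self.b.grad += dz2.sum(axis=0)
        dx = (dz2 @ self.wx.value.T).reshape(b_sz, t_len, self.in_dim)
        self._cache = None
        self._x = None
        return dx


class Linear:
    """Affine map over the trailing axis: (..., in_dim) → (..., out_dim)."""

    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        rng: np.random.Generator | None = None,
        share_with: "Linear | None" = None,
        dtype: np.dtype | str = np.float32,
    ):
        self.in_dim = in_dim
        self.out_dim = out_dim
        self.dtype = np.dtype(dtype)
        if share_with is not None:
            self.w, self.b = share_with.w, share_with.b
            self.dtype = share_with.dtype
        else:
            if rng is None:
                raise ValueError("rng required when not sharing weights")
            k = 1.0 / np.sqrt(in_dim)
            self.w = Parameter(rng.uniform(-k, k, (in_dim, out_dim)), dtype)
            self.b = Parameter(np.zeros(out_dim), dtype)
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        if x is None:
            raise RuntimeError("backward called before forward")
        x2 = x.reshape(-1, self.in_dim)
        d2 = np.asarray(dout, dtype=self.dtype).reshape(-1, self.out_dim)
        self.w.grad += x2.T @ d2
        self.b.grad += d2.sum(axis=0)
        self._x = None
        return dout @ self.w.value.T


class Dropout:
    """Inverted dropout; identity (and cache-free) in evaluation mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / x.dtype.type(keep)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Adam:
    """Adam optimizer over a list of (deduplicated) Parameters."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
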
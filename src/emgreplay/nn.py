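"""Minimal 1-D neural-network layer stack with manual backpropagation.

Implements exactly the pieces the densely connected classifier needs —
1-D convolution, batch normalization, ReLU, max/average pooling, global
average pooling, a linear head, and Adam — on float32 numpy arrays shaped
``(batch, channels, length)``. Forward passes cache what the backward pass
needs; gradients are written into :class:`Param` objects consumed by
:class:`Adam`.

Everything is driven by explicitly seeded :class:`numpy.random.Generator`
instances, so training is bit-reproducible on a fixed BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable array plus its gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)


class Module:
    """Base class: a differentiable op with optional parameters."""

    def parameters(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Module):
    """Bias-free 1-D convolution (cross-correlation) via im2col + GEMM."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding = kernel, stride, padding
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (in_ch * kernel))  # He init for ReLU nets
        self.w = Param(rng.normal(0.0, std, size=(out_ch, in_ch, kernel)))

    def parameters(self):
        return [self.w]

    def forward(self, x, train):
        B, C, L = x.shape
        if self.padding:
            x = np.pad(x, ((0, 0), (0, 0), (self.padding, self.padding)))
        Lp = x.shape[2]
        K = self.kernel
        win = sliding_window_view(x, K, axis=2)[:, :, :: self.stride]
        Lout = win.shape[2]
        # (B, Lout, C*K) patch matrix
        P = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(B * Lout, C * K)
        Wm = self.w.data.reshape(self.out_ch, C * K)
        out = P @ Wm.T
        self._cache = (P, (B, C, Lp, Lout))
        return np.ascontiguousarray(out.reshape(B, Lout, self.out_ch).transpose(0, 2, 1))

    def backward(self, g):
        P, (B, C, Lp, Lout) = self._cache
        K, s, p = self.kernel, self.stride, self.padding
        L = Lp - 2 * p
        G = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(B * Lout, self.out_ch)
        self.w.grad = (G.T @ P).reshape(self.w.data.shape)
        # grad wrt input = correlation of the (stride-dilated) output gradient
        # with the kernel flipped and transposed, as one GEMM
        Ld = (Lout - 1) * s + 1
        if s == 1:
            gd = np.ascontiguousarray(g, dtype=np.float32)
        else:
            gd = np.zeros((B, self.out_ch, Ld), dtype=np.float32)
            gd[:, :, ::s] = g
        pad_left = K - 1 - p
        pad_right = max(L + p - Ld, 0)  # strided convs leave a remainder tail
        gd = np.pad(gd, ((0, 0), (0, 0), (pad_left, pad_right)))
        win = sliding_window_view(gd, K, axis=2)
        Lx = win.shape[2]
        Pg = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(B * Lx, self.out_ch * K)
        # w_flip[c, o*K + k] = w[o, c, K-1-k]
        w_flip = np.ascontiguousarray(
            self.w.data[:, :, ::-1].transpose(1, 0, 2)
        ).reshape(C, self.out_ch * K)
        gx = (Pg @ w_flip.T).reshape(B, Lx, C).transpose(0, 2, 1)
        if Lx < L:  # trailing samples no window ever covered
            gx = np.pad(gx, ((0, 0), (0, 0), (0, L - Lx)))
        self._cache = None
        return np.ascontiguousarray(gx[:, :, :L], dtype=np.float32)


class BatchNorm1d(Module):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_ch))
        self.beta = Param(np.zeros(n_ch))
        self.running_mean = np.zeros(n_ch, dtype=np.float32)
        self.running_var = np.ones(n_ch, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * invstd[None, :, None]
        self._cache = (xhat, invstd, x.shape[0] * x.shape[2], train)
        return self.gamma.data[None, :, None] * xhat + self.beta.data[None, :, None]

    def backward(self, g):
        xhat, invstd, M, train = self._cache
        self.gamma.grad = (g * xhat).sum(axis=(0, 2))
        self.beta.grad = g.sum(axis=(0, 2))
        scale = (self.gamma.data * invstd)[None, :, None]
        if not train:
            self._cache = None
            return (g * scale).astype(np.float32)
        sum_g = g.sum(axis=(0, 2))[None, :, None]
        sum_gx = (g * xhat).sum(axis=(0, 2))[None, :, None]
        dx = scale / M * (M * g - sum_g - xhat * sum_gx)
        self._cache = None
        return dx.astype(np.float32)


class ReLU(Module):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, g):
        out = np.where(self._mask, g, 0.0).astype(np.float32)
        self._mask = None
        return out


class MaxPool1d(Module):
    """Max pooling; padding uses -inf so padded positions never win."""

    def __init__(self, kernel: int, stride: int, padding: int = 0):
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x, train):
        B, C, L = x.shape
        p = self.padding
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p)), constant_values=-np.inf)
        Lp = x.shape[2]
        win = sliding_window_view(x, self.kernel, axis=2)[:, :, :: self.stride]
        idx = win.argmax(axis=3)
        out = np.take_along_axis(win, idx[..., None], axis=3)[..., 0]
        self._cache = (idx, (B, C, L, Lp, win.shape[2]))
        return np.ascontiguousarray(out)

    def backward(self, g):
        idx, (B, C, L, Lp, Lout) = self._cache
        starts = np.arange(Lout) * self.stride
        flat_pos = idx + starts[None, None, :]  # position within padded axis
        gxp = np.zeros((B * C, Lp), dtype=np.float32)
        rows = np.repeat(np.arange(B * C), Lout)
        np.add.at(gxp, (rows, flat_pos.reshape(B * C, Lout).ravel()), g.reshape(-1))
        gxp = gxp.reshape(B, C, Lp)
        p = self.padding
        self._cache = None
        return gxp[:, :, p : Lp - p] if p else gxp


class AvgPool1d(Module):
    """Non-overlapping average pooling (kernel == stride); trailing remainder dropped."""

    def __init__(self, kernel: int):
        self.kernel = kernel

    def forward(self, x, train):
        B, C, L = x.shape
        K = self.kernel
        Lout = L // K
        self._shape = (B, C, L, Lout)
        return x[:, :, : Lout * K].reshape(B, C, Lout, K).mean(axis=3)

    def backward(self, g):
        B, C, L, Lout = self._shape
        K = self.kernel
        gx = np.zeros((B, C, L), dtype=np.float32)
        gx[:, :, : Lout * K] = np.repeat(g / K, K, axis=2)
        return gx


class GlobalAvgPool(Module):
    """Mean over the temporal axis: (B, C, L) -> (B, C)."""

    def forward(self, x, train):
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, g):
        return (np.repeat(g[:, :, None], self._L, axis=2) / self._L).astype(np.float32)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / in_dim)
        self.w = Param(rng.normal(0.0, std, size=(out_dim, in_dim)))
        self.b = Param(np.zeros(out_dim))

    def parameters(self):
        return [self.w, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.w.data.T + self.b.data

    def backward(self, g):
        self.w.grad = g.T @ self._x
        self.b.grad = g.sum(axis=0)
        out = g @ self.w.data
        self._x = None
        return out


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def parameters(self):
        return [p for m in self.modules for p in m.parameters()]

    def forward(self, x, train):
        for m in self.modules:
            x = m.forward(x, train)
        return x

    def backward(self, g):
        for m in reversed(self.modules):
            g = m.backward(g)
        return g


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy of softmax(logits) and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = np.finfo(np.float32).tiny
    loss = float(-np.log(np.maximum(p[np.arange(n), labels], eps)).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(np.float32)


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.data -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = np.zeros_like(p.data)
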
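"""Minimal NumPy neural-network stack: layers with explicit backprop, AdamW, EMA.

Everything operates on arrays of shape ``(batch, channels, time)``.  Each layer
caches what its backward pass needs during ``forward`` and accumulates
parameter gradients into ``Param.grad`` during ``backward``.  The stack is
deliberately small — dense 1-D convolutions, FFT-based depthwise long
convolutions, block-sparse channel mixing, GELU, layer/batch normalization —
which is exactly what the denoiser architecture requires, and nothing else.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import next_fast_len, rfft, irfft

__all__ = [
    "Param",
    "Module",
    "Conv1d",
    "FFTLongConv",
    "BlockSparseLinear",
    "GELU",
    "LayerNorm",
    "BatchNorm",
    "sinusoidal_embedding",
    "Linear",
    "AdamW",
    "EMA",
]


class Param:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    """Base class; subclasses define forward(x) and backward(gout)."""

    def params(self) -> list[Param]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Param):
                        out.append(item)
                    elif isinstance(item, Module):
                        out.extend(item.params())
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Conv1d(Module):
    """Dense 1-D convolution with 'same' zero padding (odd kernel size)."""

    def __init__(self, in_ch: int, out_ch: int, kernel_size: int, rng: np.random.Generator):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for 'same' padding")
        self.k = kernel_size
        self.w = Param(_he_init(rng, (out_ch, in_ch, kernel_size), in_ch * kernel_size))
        self.b = Param(np.zeros(out_ch))

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (B, Cin, L) -> (B, Cout, L)
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        self._win = win  # (B, Cin, L, k)
        y = np.einsum("bclk,ock->bol", win, self.w.value, optimize=True)
        return y + self.b.value[None, :, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.w.grad += np.einsum("bclk,bol->ock", self._win, g, optimize=True)
        self.b.grad += g.sum(axis=(0, 2))
        p = self.k // 2
        gp = np.pad(g, ((0, 0), (0, 0), (p, p)))
        gwin = np.lib.stride_tricks.sliding_window_view(gp, self.k, axis=2)
        # correlation with flipped kernel
        wf = self.w.value[:, :, ::-1]
        return np.einsum("bolk,ock->bcl", gwin, wf, optimize=True)


class FFTLongConv(Module):
    """Causal depthwise convolution with an externally supplied long kernel.

    The kernel (one per hidden channel) is passed to ``forward`` so that the
    caller can build it from structured sub-kernels; gradients with respect to
    both the signal and the kernel are returned by ``backward``.
    """

    def forward(self, x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
        # x: (B, D, L); kernel: (D, K); causal linear convolution truncated to L
        B, D, L = x.shape
        K = kernel.shape[-1]
        n = next_fast_len(L + K - 1)
        self._shapes = (L, K, n)
        self._Fx = rfft(x, n=n, axis=-1)
        self._Fk = rfft(kernel, n=n, axis=-1)
        y = irfft(self._Fx * self._Fk[None], n=n, axis=-1)[..., :L]
        return y

    def backward(self, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        L, K, n = self._shapes
        Fg = rfft(g, n=n, axis=-1)
        gx = irfft(Fg * np.conj(self._Fk)[None], n=n, axis=-1)[..., :L]
        gk = irfft((Fg * np.conj(self._Fx)).sum(axis=0), n=n, axis=-1)[..., :K]
        return gx, gk


class Linear(Module):
    """Plain dense linear map applied to the channel axis of (B, D, L) or to (B, E)."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.w = Param(_he_init(rng, (out_dim, in_dim), in_dim))
        self.b = Param(np.zeros(out_dim))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        if x.ndim == 2:
            return x @ self.w.value.T + self.b.value
        return np.einsum("od,bdl->bol", self.w.value, x) + self.b.value[None, :, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        if x.ndim == 2:
            self.w.grad += g.T @ x
            self.b.grad += g.sum(axis=0)
            return g @ self.w.value
        self.w.grad += np.einsum("bol,bdl->od", g, x)
        self.b.grad += g.sum(axis=(0, 2))
        return np.einsum("od,bol->bdl", self.w.value, g)


def block_sparse_mask(dim: int, block_size: int) -> np.ndarray:
    """Boolean mask: dense diagonal blocks of edge ``block_size`` plus the two
    off-diagonal stripes at offsets +-block_size.

    With ``block_size == dim`` the mask is all-true (dense map).  Active count
    for b < dim, b | dim:  dim*b diagonal-block weights + 2*(dim - b) stripe
    weights — linear in dim for fixed b.
    """
    if not 1 <= block_size <= dim:
        raise ValueError("block_size must be in [1, dim]")
    i = np.arange(dim)
    same_block = (i[:, None] // block_size) == (i[None, :] // block_size)
    stripe = np.abs(i[:, None] - i[None, :]) == block_size
    return same_block | stripe


class BlockSparseLinear(Module):
    """Per-timepoint linear channel mixing with a fixed sparsity mask."""

    def __init__(self, dim: int, block_size: int, rng: np.random.Generator):
        self.mask = block_sparse_mask(dim, block_size)
        fan_in = max(int(self.mask.sum(axis=1).mean()), 1)
        w = _he_init(rng, (dim, dim), fan_in)
        self.w = Param(np.where(self.mask, w, 0.0))
        self.b = Param(np.zeros(dim))

    @property
    def active_weight_count(self) -> int:
        return int(self.mask.sum())

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        w = np.where(self.mask, self.w.value, 0.0)
        return np.einsum("od,bdl->bol", w, x) + self.b.value[None, :, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        gw = np.einsum("bol,bdl->od", g, self._x)
        self.w.grad += np.where(self.mask, gw, 0.0)
        self.b.grad += g.sum(axis=(0, 2))
        w = np.where(self.mask, self.w.value, 0.0)
        return np.einsum("od,bol->bdl", w, g)


class GELU(Module):
    """Exact (erf-based) Gaussian error linear unit."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        from scipy.special import erf

        self._x = x
        self._cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        return x * self._cdf

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        pdf = np.exp(-0.5 * x**2) / np.sqrt(2.0 * np.pi)
        return g * (self._cdf + x * pdf)


class LayerNorm(Module):
    """Normalize over the channel axis at each (batch, time) position."""

    eps = 1e-5

    def __init__(self, dim: int):
        self.gain = Param(np.ones(dim))
        self.bias = Param(np.zeros(dim))

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mu = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self._xhat * self.gain.value[None, :, None] + self.bias.value[None, :, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        D = g.shape[1]
        self.gain.grad += (g * self._xhat).sum(axis=(0, 2))
        self.bias.grad += g.sum(axis=(0, 2))
        gx = g * self.gain.value[None, :, None]
        m1 = gx.mean(axis=1, keepdims=True)
        m2 = (gx * self._xhat).mean(axis=1, keepdims=True)
        return self._inv * (gx - m1 - self._xhat * m2)


class BatchNorm(Module):
    """Normalize each channel over the (batch, time) axes; running stats for eval."""

    eps = 1e-5

    def __init__(self, dim: int, momentum: float = 0.1):
        self.gain = Param(np.ones(dim))
        self.bias = Param(np.zeros(dim))
        self.momentum = momentum
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        self._n = x.shape[0] * x.shape[2]
        self._train = train
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu[None, :, None]) * self._inv[None, :, None]
        return self._xhat * self.gain.value[None, :, None] + self.bias.value[None, :, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.gain.grad += (g * self._xhat).sum(axis=(0, 2))
        self.bias.grad += g.sum(axis=(0, 2))
        gx = g * self.gain.value[None, :, None]
        if not self._train:
            return gx * self._inv[None, :, None]
        m1 = gx.mean(axis=(0, 2))[None, :, None]
        m2 = (gx * self._xhat).mean(axis=(0, 2))[None, :, None]
        return self._inv[None, :, None] * (gx - m1 - self._xhat * m2)


def sinusoidal_embedding(t: np.ndarray, dim: int, max_period: float = 10000.0) -> np.ndarray:
    """Transformer-style sinusoidal embedding of (possibly fractional) steps t: (B,) -> (B, dim)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    half = dim // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half) / half)
    ang = t[:, None] * freqs[None, :]
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=1)


class AdamW(Module):
    """AdamW with decoupled weight decay."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.p = params
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.p, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.value -= self.lr * (
                (m / bc1) / (np.sqrt(v / bc2) + self.eps) + self.wd * p.value
            )


class EMA:
    """Exponential moving average of parameter values, used for sampling."""

    def __init__(self, params: list[Param], decay: float = 0.999):
        if not 0.0 <= decay < 1.0:
            raise ValueError("EMA decay must be in [0, 1)")
        self.decay = decay
        self.shadow = [p.value.copy() for p in params]

    def update(self, params: list[Param]) -> None:
        for s, p in zip(self.shadow, params):
            s *= self.decay
            s += (1.0 - self.decay) * p.value

    def copy_to(self, params: list[Param]) -> list[np.ndarray]:
        backup = [p.value.copy() for p in params]
        for p, s in zip(params, self.shadow):
            p.value = s.copy()
        return backup

    @staticmethod
    def restore(params: list[Param], backup: list[np.ndarray]) -> None:
        for p, b in zip(params, backup):
            p.value = b
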
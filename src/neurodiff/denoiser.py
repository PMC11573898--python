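"""The epsilon-prediction network: structured long convolutions + sparse channel mixing.

The network is fully convolutional in time (no pooling or striding), so the
same weights apply to windows of any length.  Each hidden block runs a
depthwise *structured* long convolution — a kernel assembled by concatenating
linearly interpolated, exponentially downscaled copies of short learnable
sub-kernels, giving receptive fields of length ``kernel_size * 2**(num_scales-1)``
at the parameter cost of ``num_scales * kernel_size`` weights per channel —
followed by a GELU, a block-sparsified linear layer that mixes information
across hidden channels, and a normalization layer, wrapped in a residual
connection.  The diffusion step t enters through a sinusoidal embedding with a
learned per-block projection; class labels through a learned embedding added
to the step embedding; observed channels (conditional mode) as extra input
channels ``(mask, mask * observed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import next_fast_len, rfft, irfft

from .nn import (
    AdamW,  # noqa: F401  (re-exported for training code)
    BlockSparseLinear,
    Conv1d,
    FFTLongConv,
    GELU,
    BatchNorm,
    LayerNorm,
    Linear,
    Module,
    Param,
    sinusoidal_embedding,
)

__all__ = [
    "StructuredKernelSpec",
    "DenoiserConfig",
    "build_structured_kernel",
    "long_convolve",
    "sparse_mixing",
    "Denoiser",
]


@dataclass(frozen=True)
class StructuredKernelSpec:
    """Shape of a structured long-convolution kernel.

    ``kernel_size`` is the length k of each learnable sub-kernel, ``num_scales``
    the number S of concatenated segments; segment i >= 1 is the sub-kernel
    linearly interpolated to length k * 2**(i-1) and attenuated by ``decay**i``.
    The total kernel length is k * 2**(S-1).
    """

    kernel_size: int = 8
    num_scales: int = 3
    decay: float = 0.5

    def __post_init__(self) -> None:
        if self.kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        if self.num_scales < 1:
            raise ValueError("num_scales must be >= 1")
        if not 0.0 <= self.decay <= 1.0:
            raise ValueError("decay must be in [0, 1]")

    @property
    def total_length(self) -> int:
        return self.kernel_size * 2 ** (self.num_scales - 1)

    @property
    def segment_lengths(self) -> list[int]:
        k, S = self.kernel_size, self.num_scales
        return [k] + [k * 2 ** (i - 1) for i in range(1, S)]


def _interp_matrix(k: int, out_len: int) -> np.ndarray:
    """Fixed linear map performing 1-D linear interpolation from k to out_len points."""
    if k == 1:
        return np.ones((out_len, 1))
    pos = np.linspace(0.0, k - 1.0, out_len)
    lo = np.minimum(np.floor(pos).astype(int), k - 2)
    frac = pos - lo
    P = np.zeros((out_len, k))
    P[np.arange(out_len), lo] = 1.0 - frac
    P[np.arange(out_len), lo + 1] = frac
    return P


def build_structured_kernel(base: np.ndarray, spec: StructuredKernelSpec) -> np.ndarray:
    """Assemble the long kernel from per-scale sub-kernels.

    Parameters
    ----------
    base:
        Array of shape ``(..., num_scales, kernel_size)``: one independent
        sub-kernel per scale (leading axes, e.g. hidden channels, broadcast).

    Returns
    -------
    Kernel of shape ``(..., total_length)``.
    """
    base = np.asarray(base, dtype=float)
    if base.shape[-2:] != (spec.num_scales, spec.kernel_size):
        raise ValueError(
            f"base must end in shape ({spec.num_scales}, {spec.kernel_size}), got {base.shape}"
        )
    segs = []
    for i, seg_len in enumerate(spec.segment_lengths):
        P = _interp_matrix(spec.kernel_size, seg_len)
        seg = base[..., i, :] @ P.T
        segs.append(spec.decay**i * seg)
    return np.concatenate(segs, axis=-1)


def long_convolve(signal: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal linear convolution along the last axis via FFT, truncated to the
    signal length.  Numerically equal to direct convolution."""
    signal = np.asarray(signal, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if not (np.all(np.isfinite(signal)) and np.all(np.isfinite(kernel))):
        raise ValueError("non-finite input to long_convolve")
    L = signal.shape[-1]
    K = kernel.shape[-1]
    n = next_fast_len(L + K - 1)
    y = irfft(rfft(signal, n=n, axis=-1) * rfft(kernel, n=n, axis=-1), n=n, axis=-1)
    return y[..., :L]


def sparse_mixing(h: np.ndarray, weights: np.ndarray, bias: np.ndarray | None = None) -> np.ndarray:
    """Per-timepoint linear map of hidden channels: ``y[.,o,l] = sum_d W[o,d] h[.,d,l]``.

    ``weights`` carries its sparsity implicitly (masked entries are zero);
    with a dense matrix this is an ordinary channel-mixing linear layer.
    """
    h = np.asarray(h, dtype=float)
    if weights.shape[1] != h.shape[-2]:
        raise ValueError("weight matrix does not match hidden dimension")
    y = np.einsum("od,...dl->...ol", weights, h)
    if bias is not None:
        y = y + bias[..., :, None]
    return y


@dataclass
class DenoiserConfig:
    """Architecture hyperparameters of the denoising network."""

    channels: int
    latent_dims_per_channel: int = 8
    num_blocks: int = 2
    kernel: StructuredKernelSpec = field(default_factory=StructuredKernelSpec)
    mixing_block_size: int | None = None  # None -> dense (full latent dim)
    norm: str = "layer"
    conditioning: str = "none"  # none | channel | class | both
    num_classes: int = 0
    emb_dim: int = 32
    io_kernel_size: int = 5
    normalize_kernel: bool = False

    def __post_init__(self) -> None:
        if self.norm not in ("layer", "batch"):
            raise ValueError("norm must be 'layer' or 'batch'")
        if self.conditioning not in ("none", "channel", "class", "both"):
            raise ValueError(f"unknown conditioning mode {self.conditioning!r}")
        if self.conditioning in ("class", "both") and self.num_classes < 1:
            raise ValueError("class conditioning requires num_classes >= 1")

    @property
    def latent_dim(self) -> int:
        return self.channels * self.latent_dims_per_channel

    @property
    def in_channels(self) -> int:
        # channel conditioning appends (mask, mask * observed) input planes
        if self.conditioning in ("channel", "both"):
            return 3 * self.channels
        return self.channels


class _Block(Module):
    def __init__(self, cfg: DenoiserConfig, rng: np.random.Generator):
        D = cfg.latent_dim
        ks = cfg.kernel
        self.cfg = cfg
        self.bases = Param(
            rng.standard_normal((D, ks.num_scales, ks.kernel_size))
            / np.sqrt(ks.kernel_size * ks.num_scales)
        )
        self.conv = FFTLongConv()
        self.emb_proj = Linear(cfg.emb_dim, D, rng)
        self.act = GELU()
        bs = cfg.mixing_block_size or D
        self.mix = BlockSparseLinear(D, bs, rng)
        self.norm = LayerNorm(D) if cfg.norm == "layer" else BatchNorm(D)

    def _kernel(self) -> np.ndarray:
        k = build_structured_kernel(self.bases.value, self.cfg.kernel)
        if self.cfg.normalize_kernel:
            self._knorm = np.linalg.norm(k, axis=-1, keepdims=True) + 1e-12
            self._kunit = k / self._knorm
            return self._kunit
        return k

    def forward(self, h: np.ndarray, emb: np.ndarray, train: bool) -> np.ndarray:
        u = self.conv.forward(h, self._kernel())
        u = u + self.emb_proj.forward(emb)[:, :, None]
        u = self.act.forward(u)
        u = self.mix.forward(u)
        u = self.norm.forward(u, train=train)
        return h + u

    def backward(self, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        gu = self.norm.backward(g)
        gu = self.mix.backward(gu)
        gu = self.act.backward(gu)
        gemb = self.emb_proj.backward(gu.sum(axis=2))
        gh, gk = self.conv.backward(gu)
        if self.cfg.normalize_kernel:
            gk = (gk - self._kunit * (self._kunit * gk).sum(-1, keepdims=True)) / self._knorm
        # kernel -> per-scale bases (linear interpolation is a fixed linear map)
        ks = self.cfg.kernel
        off = 0
        for i, seg_len in enumerate(ks.segment_lengths):
            P = _interp_matrix(ks.kernel_size, seg_len)
            self.bases.grad[:, i, :] += ks.decay**i * (gk[:, off : off + seg_len] @ P)
            off += seg_len
        return g + gh, gemb


class Denoiser(Module):
    """epsilon_theta(x_t, t, cond): predicts the noise added to a window."""

    def __init__(self, cfg: DenoiserConfig, rng: np.random.Generator | int = 0):
        if isinstance(rng, int):
            rng = np.random.default_rng(rng)
        self.cfg = cfg
        D = cfg.latent_dim
        self.in_conv = Conv1d(cfg.in_channels, D, cfg.io_kernel_size, rng)
        self.blocks = [_Block(cfg, rng) for _ in range(cfg.num_blocks)]
        self.out_conv = Conv1d(D, cfg.channels, cfg.io_kernel_size, rng)
        if cfg.conditioning in ("class", "both"):
            self.class_emb = Param(0.1 * rng.standard_normal((cfg.num_classes, cfg.emb_dim)))
        else:
            self.class_emb = None

    # -- embedding -----------------------------------------------------------
    def _embed(self, t: np.ndarray, batch: int, class_label) -> np.ndarray:
        t = np.broadcast_to(np.atleast_1d(np.asarray(t, dtype=float)), (batch,))
        emb = sinusoidal_embedding(t, self.cfg.emb_dim)
        if self.class_emb is not None and class_label is not None:
            labels = np.broadcast_to(np.atleast_1d(class_label), (batch,)).astype(int)
            self._emb_labels = labels
            emb = emb + self.class_emb.value[labels]
        else:
            self._emb_labels = None
        return emb

    def _assemble_input(self, xt: np.ndarray, cond) -> np.ndarray:
        if self.cfg.conditioning not in ("channel", "both"):
            return xt
        B, C, L = xt.shape
        if cond is not None and getattr(cond, "observed_mask", None) is not None:
            mask = np.broadcast_to(cond.observed_mask.astype(float), (B, C, L))
            obs = np.broadcast_to(np.asarray(cond.observed_values, dtype=float), (B, C, L))
            obs = mask * np.nan_to_num(obs)
        else:
            mask = np.zeros((B, C, L))
            obs = np.zeros((B, C, L))
        return np.concatenate([xt, mask, obs], axis=1)

    # -- forward / backward --------------------------------------------------
    def forward(self, xt: np.ndarray, t, cond=None, train: bool = True) -> np.ndarray:
        xt = np.asarray(xt, dtype=float)
        squeeze = xt.ndim == 2
        if squeeze:
            xt = xt[None]
        if xt.shape[1] != self.cfg.channels:
            raise ValueError(
                f"expected {self.cfg.channels} channels, got {xt.shape[1]}"
            )
        B = xt.shape[0]
        label = getattr(cond, "class_label", None) if cond is not None else None
        emb = self._embed(t, B, label)
        self._emb = emb
        h = self.in_conv.forward(self._assemble_input(xt, cond))
        for blk in self.blocks:
            h = blk.forward(h, emb, train)
        out = self.out_conv.forward(h)
        return out[0] if squeeze else out

    def backward(self, g: np.ndarray) -> np.ndarray:
        """Backpropagate d(loss)/d(eps_pred); returns d(loss)/d(x_t)."""
        squeeze = g.ndim == 2
        if squeeze:
            g = g[None]
        gh = self.out_conv.backward(g)
        gemb = np.zeros_like(self._emb)
        for blk in reversed(self.blocks):
            gh, ge = blk.backward(gh)
            gemb += ge
        if self.class_emb is not None and self._emb_labels is not None:
            np.add.at(self.class_emb.grad, self._emb_labels, gemb)
        gx_full = self.in_conv.backward(gh)
        gx = gx_full[:, : self.cfg.channels]
        return gx[0] if squeeze else gx

    # -- (de)serialization ---------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p.value for p in self.params()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.params()
        if len(arrays) != len(params):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            if p.value.shape != a.shape:
                raise ValueError("state array shape mismatch")
            p.value = np.asarray(a, dtype=float).copy()
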
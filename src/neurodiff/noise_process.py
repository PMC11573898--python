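"""Gaussian noise laws driving the diffusion: white noise and the Ornstein-Uhlenbeck process.

The OU process is the stationary Gauss-Markov process with exponential covariance

    k(dt) = sigma^2 * exp(-rho * |dt|),

with ``rho`` an inverse lengthscale in units of 1/sample.  Sampled on a uniform
grid it is an AR(1) process with coefficient ``phi = exp(-rho)``, which gives
linear-time exact sampling and a tridiagonal precision matrix, so the
Sigma-weighted quadratic forms needed by the diffusion objective cost O(L)
per channel instead of O(L^3).

White noise is treated as the rho -> infinity limit of the OU process and takes
the same code paths; with ``sigma = 1`` it reproduces the standard
identity-covariance diffusion exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GaussianProcessSpec",
    "ou_kernel_value",
    "build_covariance",
    "sample_process_noise",
    "precision_apply",
    "precision_quadratic_form",
    "whiten",
    "log_det_covariance",
]


@dataclass(frozen=True)
class GaussianProcessSpec:
    """Specification of a stationary Gaussian noise law.

    Parameters
    ----------
    kind:
        ``"white"`` for i.i.d. Gaussian noise or ``"ou"`` for the
        Ornstein-Uhlenbeck process.
    sigma:
        Marginal standard deviation, so the implied covariance has
        ``sigma**2`` on the diagonal.  Default 1 matches the unit-variance
        convention of the standard diffusion noising chain.
    rho:
        Inverse lengthscale per sample (OU only).  Larger values decorrelate
        faster; the lag-1 autocorrelation is ``exp(-rho)``.
    """

    kind: str = "white"
    sigma: float = 1.0
    rho: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("white", "ou"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if self.kind == "ou":
            if self.rho is None or not self.rho > 0:
                raise ValueError("ou spec requires rho > 0")

    @property
    def phi(self) -> float:
        """Lag-1 autocorrelation of the sampled process (0 for white noise)."""
        if self.kind == "white":
            return 0.0
        return float(np.exp(-self.rho))


def ou_kernel_value(dt: float | np.ndarray, spec: GaussianProcessSpec) -> float | np.ndarray:
    """Stationary OU covariance ``sigma^2 * exp(-rho * |dt|)`` at lag ``dt`` (samples)."""
    if spec.kind != "ou":
        raise ValueError("ou_kernel_value requires an OU spec")
    return spec.sigma**2 * np.exp(-spec.rho * np.abs(dt))


def build_covariance(n: int, spec: GaussianProcessSpec) -> np.ndarray:
    """Dense n-by-n covariance matrix of the process on a uniform grid.

    Cubic-cost oracle intended for testing and for small windows; runtime code
    uses the AR(1) recursion and the tridiagonal precision instead.
    """
    if n <= 0:
        raise ValueError("n must be >= 1")
    if spec.kind == "white":
        return spec.sigma**2 * np.eye(n)
    lags = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    return ou_kernel_value(lags, spec)


def sample_process_noise(
    channels: int,
    length: int,
    spec: GaussianProcessSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a ``channels x length`` window with independent channels.

    OU channels are generated by the exact stationary AR(1) recursion

        x[0] ~ N(0, sigma^2),   x[i+1] = phi x[i] + sigma sqrt(1 - phi^2) xi,

    with ``phi = exp(-rho)``.  White noise consumes exactly one standard
    normal per sample (``sigma * rng.standard_normal``), so it is
    bit-compatible with an independent N(0, 1) sampler given the same stream.
    """
    if channels < 1 or length < 1:
        raise ValueError("channels and length must be >= 1")
    if spec.kind == "white":
        return spec.sigma * rng.standard_normal((channels, length))
    phi = spec.phi
    innov_scale = spec.sigma * np.sqrt(1.0 - phi**2)
    x = np.empty((channels, length))
    x[:, 0] = spec.sigma * rng.standard_normal(channels)
    xi = rng.standard_normal((channels, max(length - 1, 0)))
    for i in range(1, length):
        x[:, i] = phi * x[:, i - 1] + innov_scale * xi[:, i - 1]
    return x


def _tridiag_precision_apply(r: np.ndarray, spec: GaussianProcessSpec) -> np.ndarray:
    """Apply the banded OU precision Sigma^{-1} to rows of ``r`` in O(L)."""
    phi = spec.phi
    s2 = spec.sigma**2
    L = r.shape[-1]
    if L == 1:
        return r / s2
    scale = 1.0 / (s2 * (1.0 - phi**2))
    out = np.empty_like(r)
    diag_inner = 1.0 + phi**2
    out[..., 0] = r[..., 0] - phi * r[..., 1]
    out[..., -1] = r[..., -1] - phi * r[..., -2]
    if L > 2:
        out[..., 1:-1] = diag_inner * r[..., 1:-1] - phi * (r[..., :-2] + r[..., 2:])
    return scale * out


def precision_apply(r: np.ndarray, spec: GaussianProcessSpec) -> np.ndarray:
    """``Sigma^{-1} r`` applied along the last (time) axis, channelwise."""
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite input to precision_apply")
    if spec.kind == "white":
        return r / spec.sigma**2
    return _tridiag_precision_apply(r, spec)


def precision_quadratic_form(r: np.ndarray, spec: GaussianProcessSpec) -> float:
    """Sum over channels of ``r^T Sigma^{-1} r`` along time, in O(L) per channel.

    For white noise with ``sigma = 1`` this is exactly ``sum(r**2)``.
    """
    r = np.asarray(r, dtype=float)
    return float(np.sum(r * precision_apply(r, spec)))


def whiten(x: np.ndarray, spec: GaussianProcessSpec) -> np.ndarray:
    """Map ``x ~ N(0, Sigma)`` to N(0, I) via the AR(1) innovation transform.

    Acts along the last axis.  For white noise this is division by sigma.
    """
    x = np.asarray(x, dtype=float)
    if spec.kind == "white":
        return x / spec.sigma
    phi = spec.phi
    out = np.empty_like(x)
    out[..., 0] = x[..., 0] / spec.sigma
    out[..., 1:] = (x[..., 1:] - phi * x[..., :-1]) / (spec.sigma * np.sqrt(1.0 - phi**2))
    return out


def log_det_covariance(length: int, spec: GaussianProcessSpec) -> float:
    """``log |Sigma|`` of one channel of the given length."""
    if spec.kind == "white":
        return 2.0 * length * np.log(spec.sigma)
    phi = spec.phi
    return 2.0 * length * np.log(spec.sigma) + (length - 1) * np.log(1.0 - phi**2)
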
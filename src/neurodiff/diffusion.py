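"""Denoising diffusion for multichannel time series.

Forward process: x_t = sqrt(abar_t) x_0 + sqrt(1 - abar_t) eps with eps drawn
from a configurable Gaussian law (white or OU, see
:mod:`neurodiff.noise_process`).  The denoiser eps_theta is trained on the
Sigma-weighted residual (eps - eps_pred)^T Sigma^{-1} (eps - eps_pred), which
reduces to the plain squared error when Sigma = I.  Reverse sampling follows
the standard ancestral denoising chain; imputation is supported both by
inpainting (clamping observed entries to their forward-diffused values after
every reverse step) and by conditional models trained with random
channel dropout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import noise_process as npr
from .denoiser import Denoiser, DenoiserConfig, StructuredKernelSpec
from .nn import AdamW, EMA
from .noise_process import GaussianProcessSpec

__all__ = [
    "DiffusionSchedule",
    "ConditioningInfo",
    "TrainConfig",
    "TrainState",
    "make_schedule",
    "forward_marginal",
    "diffusion_loss",
    "denoise_step",
    "generate",
    "sample_channel_dropout_mask",
    "train_model",
    "impute_inpaint",
    "impute_conditional",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class DiffusionSchedule:
    """The beta/alpha/abar ladder over T diffusion steps (1-indexed steps)."""

    beta: np.ndarray

    @property
    def T(self) -> int:
        return len(self.beta)

    @property
    def alpha(self) -> np.ndarray:
        return 1.0 - self.beta

    @property
    def alpha_bar(self) -> np.ndarray:
        return np.cumprod(self.alpha)

    def abar(self, t: int) -> float:
        """Cumulative signal fraction at step t; abar(0) = 1 by convention."""
        if t == 0:
            return 1.0
        return float(self.alpha_bar[t - 1])


@dataclass
class ConditioningInfo:
    """Conditioning supplied to the denoiser and the samplers.

    ``observed_mask`` is boolean, True where the value is observed; it may be
    per-channel ``(C,)``, per-entry ``(C, L)``, or batched ``(B, C, L)``.
    An all-false (or None) mask means unconditional.
    """

    observed_mask: np.ndarray | None = None
    observed_values: np.ndarray | None = None
    class_label: int | np.ndarray | None = None

    def entry_mask(self, channels: int, length: int) -> np.ndarray:
        if self.observed_mask is None:
            return np.zeros((channels, length), dtype=bool)
        m = np.asarray(self.observed_mask, dtype=bool)
        if m.ndim == 1:
            m = m[:, None]
        return np.broadcast_to(m, (channels, length))


def make_schedule(
    T: int, beta_start: float = 1e-4, beta_end: float = 0.02, kind: str = "linear"
) -> DiffusionSchedule:
    """Linear beta schedule; alpha and abar follow from the ladder identities."""
    if kind != "linear":
        raise ValueError(f"unknown schedule kind {kind!r}")
    if T < 1:
        raise ValueError("T must be >= 1")
    if not (0.0 < beta_start <= beta_end < 1.0):
        raise ValueError("need 0 < beta_start <= beta_end < 1")
    return DiffusionSchedule(beta=np.linspace(beta_start, beta_end, T))


def forward_marginal(
    x0: np.ndarray, t: int, schedule: DiffusionSchedule, eps: np.ndarray
) -> np.ndarray:
    """Closed-form noised state sqrt(abar_t) x0 + sqrt(1 - abar_t) eps."""
    x0 = np.asarray(x0, dtype=float)
    eps = np.asarray(eps, dtype=float)
    if x0.shape != eps.shape:
        raise ValueError("x0 and eps must share a shape")
    ab = schedule.abar(t)
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps


def diffusion_loss(
    eps: np.ndarray, eps_pred: np.ndarray, spec: GaussianProcessSpec
) -> float:
    """Sigma-weighted residual (eps - eps_pred)^T Sigma^{-1} (eps - eps_pred).

    With white noise and sigma = 1 this is exactly the summed squared error of
    the simplified diffusion objective.
    """
    r = np.asarray(eps, dtype=float) - np.asarray(eps_pred, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite residual in diffusion_loss")
    return npr.precision_quadratic_form(r, spec)


def denoise_step(
    xt: np.ndarray,
    t: int,
    eps_pred: np.ndarray,
    schedule: DiffusionSchedule,
    spec: GaussianProcessSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """One reverse (ancestral) step x_t -> x_{t-1}.

    Mean (x_t - beta_t / sqrt(1 - abar_t) * eps_pred) / sqrt(alpha_t); injected
    noise has variance (1 - abar_{t-1}) / (1 - abar_t) * beta_t and is drawn
    from the same process law as the forward noise.  No noise at t = 1.
    """
    if not 1 <= t <= schedule.T:
        raise ValueError("t out of range")
    xt = np.asarray(xt, dtype=float)
    beta_t = schedule.beta[t - 1]
    alpha_t = 1.0 - beta_t
    ab_t = schedule.abar(t)
    mean = (xt - beta_t / np.sqrt(1.0 - ab_t) * eps_pred) / np.sqrt(alpha_t)
    if t == 1:
        return mean
    ab_prev = schedule.abar(t - 1)
    sigma_t = np.sqrt((1.0 - ab_prev) / (1.0 - ab_t) * beta_t)
    zeta = npr.sample_process_noise(xt.shape[-2], xt.shape[-1], spec, rng)
    return mean + sigma_t * zeta


def sample_channel_dropout_mask(C: int, rng: np.random.Generator) -> np.ndarray:
    """Per-channel observation mask with k ~ Uniform{1..C} channels dropped.

    Returns a boolean ``(C,)`` array, False = missing (to be imputed).
    """
    if C < 1:
        raise ValueError("C must be >= 1")
    k = int(rng.integers(1, C + 1))
    mask = np.ones(C, dtype=bool)
    mask[rng.choice(C, size=k, replace=False)] = False
    return mask


def generate(
    model: Denoiser,
    channels: int,
    length: int,
    schedule: DiffusionSchedule,
    spec: GaussianProcessSpec,
    cond: ConditioningInfo | None = None,
    rng: np.random.Generator | int = 0,
    n_samples: int = 1,
) -> np.ndarray:
    """Ancestral sampling: draw x_T from the noise law, denoise for t = T..1.

    Returns ``(n_samples, channels, length)`` (or ``(channels, length)`` when
    n_samples is 1).  Conditioning, when given, is passed to the network at
    every step.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    if channels != model.cfg.channels:
        raise ValueError("channel count does not match the trained model")
    x = np.stack(
        [npr.sample_process_noise(channels, length, spec, rng) for _ in range(n_samples)]
    )
    for t in range(schedule.T, 0, -1):
        eps_pred = model.forward(x, float(t), cond=cond, train=False)
        x = np.stack(
            [denoise_step(x[i], t, eps_pred[i], schedule, spec, rng) for i in range(n_samples)]
        )
    return x[0] if n_samples == 1 else x


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    steps: int = 2000
    batch_size: int = 32
    lr: float = 2e-3
    weight_decay: float = 1e-4
    ema_decay: float = 0.999
    seed: int = 0
    conditioning: str = "none"  # none | channel | class | both
    log_every: int = 100


@dataclass
class TrainState:
    """Weights, optimizer and EMA state of a (partially) trained model."""

    model: Denoiser
    schedule: DiffusionSchedule
    noise: GaussianProcessSpec
    optimizer: AdamW
    ema: EMA
    step: int = 0
    seed: int = 0
    loss_history: list = field(default_factory=list)

    def ema_model(self) -> Denoiser:
        """A copy of the model carrying the EMA weights (used for sampling)."""
        m = Denoiser(self.model.cfg, rng=0)
        m.load_state_arrays([s.copy() for s in self.ema.shadow])
        return m


def train_model(
    windows: np.ndarray,
    model_cfg: DenoiserConfig,
    schedule: DiffusionSchedule,
    spec: GaussianProcessSpec,
    cfg: TrainConfig,
    labels: np.ndarray | None = None,
    state: TrainState | None = None,
) -> TrainState:
    """Minimize the Sigma-weighted denoising objective with AdamW.

    ``windows`` is ``(n, C, L)`` and assumed standardized.  In channel-dropout
    conditional mode every batch element receives a fresh random mask and the
    network sees the clean observed channels as additional input; in class
    mode ``labels`` supplies an integer class per window.
    """
    windows = np.asarray(windows, dtype=float)
    n, C, L = windows.shape
    rng = np.random.default_rng(cfg.seed)
    cond_channels = cfg.conditioning in ("channel", "both")
    cond_class = cfg.conditioning in ("class", "both")
    if cond_class and labels is None:
        raise ValueError("class-conditional training requires labels")

    if state is None:
        model = Denoiser(model_cfg, rng=np.random.default_rng(cfg.seed + 1))
        opt = AdamW(model.params(), lr=cfg.lr, weight_decay=cfg.weight_decay)
        ema = EMA(model.params(), decay=cfg.ema_decay)
        state = TrainState(model, schedule, spec, opt, ema, seed=cfg.seed)
    model, opt, ema = state.model, state.optimizer, state.ema

    norm = cfg.batch_size * C * L
    for _ in range(cfg.steps):
        idx = rng.integers(0, n, size=cfg.batch_size)
        x0 = windows[idx]
        t = rng.integers(1, schedule.T + 1, size=cfg.batch_size)
        eps = np.stack(
            [npr.sample_process_noise(C, L, spec, rng) for _ in range(cfg.batch_size)]
        )
        ab = schedule.alpha_bar[t - 1][:, None, None]
        xt = np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps

        cond = None
        if cond_channels or cond_class:
            mask = None
            obs = None
            if cond_channels:
                chan_mask = np.stack(
                    [sample_channel_dropout_mask(C, rng) for _ in range(cfg.batch_size)]
                )
                mask = np.repeat(chan_mask[:, :, None], L, axis=2)
                obs = x0
            lab = labels[idx] if cond_class else None
            cond = ConditioningInfo(observed_mask=mask, observed_values=obs, class_label=lab)

        eps_pred = model.forward(xt, t.astype(float), cond=cond, train=True)
        resid = eps_pred - eps
        loss = npr.precision_quadratic_form(resid, spec) / norm
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"diffusion loss diverged at step {state.step} (loss={loss})"
            )
        model.zero_grad()
        model.backward(2.0 * npr.precision_apply(resid, spec) / norm)
        opt.step()
        ema.update(model.params())
        state.step += 1
        if state.step % cfg.log_every == 0 or state.step == 1:
            state.loss_history.append((state.step, float(loss)))
    return state


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


def impute_inpaint(
    model: Denoiser,
    observed: ConditioningInfo,
    schedule: DiffusionSchedule,
    spec: GaussianProcessSpec,
    rng: np.random.Generator | int = 0,
    length: int | None = None,
) -> np.ndarray:
    """Imputation by inpainting with an unconditionally trained model.

    After every reverse step the observed entries are overwritten with the
    analytical forward-diffused state of the observed values at the new step,
    so the reverse chain is guided along the observed part; at t = 0 the
    observed entries equal the observations exactly.  Supports arbitrary
    missingness patterns.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    C = model.cfg.channels
    obs = np.asarray(observed.observed_values, dtype=float)
    L = length or obs.shape[-1]
    mask = observed.entry_mask(C, L)
    x = npr.sample_process_noise(C, L, spec, rng)
    for t in range(schedule.T, 0, -1):
        eps_pred = model.forward(x, float(t), train=False)
        x = denoise_step(x, t, eps_pred, schedule, spec, rng)
        if mask.any():
            noise = npr.sample_process_noise(C, L, spec, rng)
            x_obs = forward_marginal(obs, t - 1, schedule, noise)
            x = np.where(mask, x_obs, x)
    return x


def impute_conditional(
    model: Denoiser,
    observed: ConditioningInfo,
    schedule: DiffusionSchedule,
    spec: GaussianProcessSpec,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Imputation with a channel-dropout-conditionally trained model.

    Only whole-channel missingness is supported in this mode; the observed
    channels are fed to the network at every reverse step and copied through
    unchanged in the output.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    C = model.cfg.channels
    obs = np.asarray(observed.observed_values, dtype=float)
    L = obs.shape[-1]
    mask = observed.entry_mask(C, L)
    whole = np.all(mask == mask[:, :1], axis=1)
    if not whole.all():
        raise ValueError("conditional imputation supports whole-channel masks only")
    cond = ConditioningInfo(
        observed_mask=mask, observed_values=np.where(mask, obs, 0.0),
        class_label=observed.class_label,
    )
    x = npr.sample_process_noise(C, L, spec, rng)
    for t in range(schedule.T, 0, -1):
        eps_pred = model.forward(x, float(t), cond=cond, train=False)
        x = denoise_step(x, t, eps_pred, schedule, spec, rng)
    return np.where(mask, obs, x)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(state: TrainState, path) -> None:
    """Portable .npz checkpoint: weights, EMA weights, config metadata."""
    cfg = state.model.cfg
    meta = {
        "channels": cfg.channels,
        "latent_dims_per_channel": cfg.latent_dims_per_channel,
        "num_blocks": cfg.num_blocks,
        "kernel_size": cfg.kernel.kernel_size,
        "num_scales": cfg.kernel.num_scales,
        "decay": cfg.kernel.decay,
        "mixing_block_size": cfg.mixing_block_size,
        "norm": cfg.norm,
        "conditioning": cfg.conditioning,
        "num_classes": cfg.num_classes,
        "emb_dim": cfg.emb_dim,
        "io_kernel_size": cfg.io_kernel_size,
        "normalize_kernel": cfg.normalize_kernel,
        "T": state.schedule.T,
        "beta_start": float(state.schedule.beta[0]),
        "beta_end": float(state.schedule.beta[-1]),
        "noise_kind": state.noise.kind,
        "noise_sigma": state.noise.sigma,
        "noise_rho": state.noise.rho,
        "step": state.step,
        "seed": state.seed,
    }
    arrays = {f"w{i}": a for i, a in enumerate(state.model.state_arrays())}
    arrays.update({f"ema{i}": a for i, a in enumerate(state.ema.shadow)})
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> TrainState:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        n = len([k for k in z.files if k.startswith("w")])
        weights = [z[f"w{i}"] for i in range(n)]
        ema_w = [z[f"ema{i}"] for i in range(n)]
    cfg = DenoiserConfig(
        channels=meta["channels"],
        latent_dims_per_channel=meta["latent_dims_per_channel"],
        num_blocks=meta["num_blocks"],
        kernel=StructuredKernelSpec(meta["kernel_size"], meta["num_scales"], meta["decay"]),
        mixing_block_size=meta["mixing_block_size"],
        norm=meta["norm"],
        conditioning=meta["conditioning"],
        num_classes=meta["num_classes"],
        emb_dim=meta["emb_dim"],
        io_kernel_size=meta["io_kernel_size"],
        normalize_kernel=meta["normalize_kernel"],
    )
    model = Denoiser(cfg, rng=0)
    model.load_state_arrays(weights)
    schedule = make_schedule(meta["T"], meta["beta_start"], meta["beta_end"])
    spec = GaussianProcessSpec(meta["noise_kind"], meta["noise_sigma"], meta["noise_rho"])
    opt = AdamW(model.params())
    ema = EMA(model.params())
    ema.shadow = [np.asarray(a, dtype=float).copy() for a in ema_w]
    return TrainState(
        model, schedule, spec, opt, ema, step=meta["step"], seed=meta["seed"]
    )
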
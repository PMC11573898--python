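"""Shared fixtures.

The expensive fixtures train small diffusion models once per session and are
shared between the behavioural tests and the acceptance tests; sizes are the
package's desk-scale defaults (T=200 with the endpoint rescaled so the
terminal signal fraction stays below 1%, windows of 128 samples).
"""

from __future__ import annotations

import numpy as np
import pytest

from neurodiff.denoiser import DenoiserConfig, StructuredKernelSpec
from neurodiff.diffusion import TrainConfig, make_schedule, train_model
from neurodiff.noise_process import GaussianProcessSpec
from neurodiff.synthetic import gen_ar1_windows, gen_linear_mixture, gen_two_state_dataset


@pytest.fixture(scope="session")
def schedule200():
    # beta_end chosen so abar_T < 0.01 at T=200 (same role as the
    # standard T=1000, beta in [1e-4, 0.02] ladder)
    return make_schedule(200, 1e-4, 0.05)


@pytest.fixture(scope="session")
def white():
    return GaussianProcessSpec("white", 1.0)


@pytest.fixture(scope="session")
def ar1_state(schedule200, white):
    """Unconditional model trained on 1-channel AR(1) windows."""
    ws, _ = gen_ar1_windows(n=2000, length=128, fs=200.0, phi=0.9, seed=11)
    cfg = DenoiserConfig(
        channels=1, latent_dims_per_channel=24, num_blocks=2,
        kernel=StructuredKernelSpec(8, 4, 0.5),
    )
    tc = TrainConfig(steps=2500, batch_size=48, lr=2e-3, ema_decay=0.995, seed=3)
    return train_model(ws.windows, cfg, schedule200, white, tc), ws


@pytest.fixture(scope="session")
def duplicate_data():
    """Two channels carrying (nearly) the same 1/f source."""
    ws, meta = gen_linear_mixture(
        n=1500, channels=2, latent_dim=1, length=128, fs=200.0,
        mixing=np.array([[1.0], [1.0]]), noise_std=0.02, source_exponent=1.5, seed=21,
    )
    return ws, meta


@pytest.fixture(scope="session")
def dup_uncond_state(duplicate_data, schedule200, white):
    ws, _ = duplicate_data
    cfg = DenoiserConfig(
        channels=2, latent_dims_per_channel=12, num_blocks=2,
        kernel=StructuredKernelSpec(8, 4, 0.5),
    )
    tc = TrainConfig(steps=2200, batch_size=48, lr=2e-3, ema_decay=0.995, seed=5)
    return train_model(ws.windows, cfg, schedule200, white, tc)


@pytest.fixture(scope="session")
def dup_cond_state(duplicate_data, schedule200, white):
    ws, _ = duplicate_data
    cfg = DenoiserConfig(
        channels=2, latent_dims_per_channel=12, num_blocks=2,
        kernel=StructuredKernelSpec(8, 4, 0.5), conditioning="channel",
    )
    tc = TrainConfig(
        steps=2200, batch_size=48, lr=2e-3, ema_decay=0.995, seed=7,
        conditioning="channel",
    )
    return train_model(ws.windows, cfg, schedule200, white, tc)


@pytest.fixture(scope="session")
def two_state_data():
    return gen_two_state_dataset(n_per_class=500, length=128, fs=200.0, seed=31)


@pytest.fixture(scope="session")
def two_state_state(two_state_data, schedule200, white):
    ws, _ = two_state_data
    cfg = DenoiserConfig(
        channels=1, latent_dims_per_channel=24, num_blocks=2,
        kernel=StructuredKernelSpec(8, 4, 0.5), conditioning="class", num_classes=2,
    )
    tc = TrainConfig(
        steps=2500, batch_size=48, lr=2e-3, ema_decay=0.995, seed=9,
        conditioning="class",
    )
    return train_model(ws.windows, cfg, schedule200, white, tc, labels=ws.labels)
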
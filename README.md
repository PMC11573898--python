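# neurodiff

Denoising diffusion probabilistic models (DDPMs) for multichannel neural
time series — LFP, ECoG, and EEG-style recordings.  The package is aimed at
computational neuroscientists who want to generate realistic surrogate
recordings, impute missing channels, and score windows by model likelihood,
together with the evaluation metrics this field actually uses.

## What it does

A recording window x₀ ∈ ℝ^{C×L} is noised by the forward chain
q(x_t | x_{t-1}) = N(√(1-β_t)·x_{t-1}, β_t Σ) for t = 1…T, so that
x_t = √ᾱ_t·x₀ + √(1-ᾱ_t)·ε with ᾱ_t = ∏(1-β_s).  A fully convolutional
network ε_θ(x_t, t, cond) — structured long convolutions interleaved with
block-sparse channel-mixing layers — learns to predict the noise by
minimizing E[(ε-ε_θ)ᵀΣ⁻¹(ε-ε_θ)], and new data are generated by running the
reverse chain from x_T ~ N(0, Σ).  The noise law Σ is white by default or an
Ornstein-Uhlenbeck process (k(Δ) = σ²e^{-ρ|Δ|}, sampled and weighted in
linear time through its AR(1) form) to bias the model toward the 1/f-like
continuity of neural field recordings.

On top of the generative core:

- **Imputation** of missing channels, either by inpainting with an
  unconditional model (observed entries clamped to their forward-diffused
  state after every reverse step) or with a conditional model trained under
  random channel dropout.
- **Log-likelihoods** via the probability-flow ODE, used for two-class
  brain-state classification, sliding-window state tracking, and outlier
  scoring.
- **Evaluation metrics**: full-window PSD percentiles, sharp-wave-ripple
  (SWR) detection (100-275 Hz band power, mean + 3 SD threshold, fuse-10 /
  minimum-20-sample rules), phase-amplitude and phase-occurrence coupling
  profiles (31 / 21 phase bins), window-level F1 with a permutation test,
  channelwise imputation correlations, and a nearest-neighbour memorization
  check.
- **Synthetic generators** with known ground truth (1/f noise, AR(1)/OU
  windows, phase-locked ripple bursts, two-state spectra, linear mixtures,
  evoked trials) so the whole pipeline is testable without any data
  download.

The network stack (layers, backprop, AdamW, EMA) is implemented directly in
NumPy; every layer's gradient is verified against finite differences in the
test suite.

## Worked example

Train a 1-channel model on AR(1) windows (the discretized OU process, whose
spectrum is known in closed form) and check the generated spectrum:

```python
import numpy as np
from neurodiff import (GaussianProcessSpec, make_schedule, train_model,
                       generate, TrainConfig, DenoiserConfig, StructuredKernelSpec)
from neurodiff.synthetic import gen_ar1_windows, ar1_spectrum
from neurodiff.metrics import psd_percentiles

ws, _ = gen_ar1_windows(n=2000, length=128, fs=200.0, phi=0.9, seed=11)
sched = make_schedule(T=200, beta_start=1e-4, beta_end=0.05)
white = GaussianProcessSpec("white")
cfg = DenoiserConfig(channels=1, latent_dims_per_channel=24, num_blocks=2,
                     kernel=StructuredKernelSpec(8, 4, 0.5))
state = train_model(ws.windows, cfg, sched, white,
                    TrainConfig(steps=2500, batch_size=48, ema_decay=0.995, seed=3))
gen = generate(state.ema_model(), 1, 128, sched, white, rng=1, n_samples=192)

summ = psd_percentiles(gen[:, 0, :], 200.0)
ana = np.log(2) * ar1_spectrum(summ.freqs, 0.9, 200.0)   # median periodogram = ln2 * S(f)
band = (summ.freqs >= 5) & (summ.freqs <= 40)
dev = 10 * np.log10(summ.median[band] / ana[band])
print(f"first/last training loss: {state.loss_history[0][1]:.2f} / {state.loss_history[-1][1]:.2f}")
print(f"generated variance: {gen.var():.2f}")
print(f"max |PSD deviation|: {np.abs(dev).max():.2f} dB")
```

which prints (about 3 minutes on one CPU):

```
first/last training loss: 6.80 / 0.26
generated variance: 0.92
max |PSD deviation|: 1.35 dB
```

The training loss falls from ~6.8 (untrained network, Σ-weighted mean squared
error per sample) to ~0.26; the 192 generated windows carry approximately
unit variance, and their median power spectrum tracks the analytic AR(1)
Lorentzian within 1.4 dB across 5-40 Hz — the model has recovered the
spectral law of the training data rather than memorized windows.

The same workflow is available from the shell:

```
neurodiff synthesize ar1 train.h5 --n 2000 --length 128 --param phi=0.9
neurodiff train train.h5 model.npz --config config.yaml
neurodiff sample model.npz gen.h5 --n 192 --length 128
neurodiff evaluate train.h5 gen.h5 tables/
```

plus `preprocess`, `impute`, and `likelihood` subcommands; see
`neurodiff --help` and `docs/methods.md` for the model, parameter, and
metric details.

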
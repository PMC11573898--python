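# Methods

## Model

`neurodiff` implements denoising diffusion probabilistic models (DDPMs) for
multichannel, densely sampled neural time series (LFP, ECoG, EEG).  A window
x₀ ∈ ℝ^{C×L} is progressively noised by the fixed Markov chain

    q(x_t | x_{t-1}) = N(x_t; √(1-β_t) x_{t-1}, β_t Σ),    t = 1…T,

with noise levels β_t and a noise covariance Σ that is either the identity
(white noise) or the covariance of an Ornstein-Uhlenbeck (OU) process applied
independently per channel.  The closed-form marginal is
x_t = √ᾱ_t·x₀ + √(1-ᾱ_t)·ε with ᾱ_t = ∏_{s≤t}(1-β_s) and ε ~ N(0, Σ).  A
neural network ε_θ(x_t, t, cond) is trained to predict the noise by
minimizing the Σ-weighted residual

    E[ (ε - ε_θ)ᵀ Σ⁻¹ (ε - ε_θ) ],

which reduces to the standard simplified DDPM objective when Σ = I.
Sampling runs the learned reverse chain from x_T ~ N(0, Σ): each step takes
the posterior mean (x_t - β_t/√(1-ᾱ_t)·ε_θ)/√α_t and injects noise of
variance (1-ᾱ_{t-1})/(1-ᾱ_t)·β_t drawn from the same process Σ, none at the
final step.

### OU noise

The OU process has kernel k(Δ) = σ²·e^{-ρ|Δ|} with Δ in samples and ρ an
inverse lengthscale (1/samples).  On a uniform grid it is an AR(1) process
with coefficient φ = e^{-ρ}, so: (i) exact stationary sampling is linear-time
via x[i+1] = φx[i] + σ√(1-φ²)ξ with x[0] ~ N(0, σ²); (ii) the precision
matrix Σ⁻¹ is tridiagonal, so the weighted training objective costs O(L) per
channel; (iii) the innovation transform whitens OU-distributed data exactly.
σ defaults to 1 so diag(Σ) = 1, matching the unit-variance convention of the
white-noise chain at every step.  White noise takes the same code paths as
the φ → 0 limit and is bit-identical to an independent N(0,1) sampler given
the same random stream.  Dense covariance construction exists only as a
small-n test oracle; no runtime path is cubic.  ρ has no universal default —
it is a per-dataset configuration value.

## Denoiser architecture

The ε-network is fully convolutional in time (no pooling/striding), so
weights trained at one window length apply at any length.  Input and output
are standard 1-D convolutions mapping C channels to and from a latent space
of C × latent_dims_per_channel hidden channels.  Each of the `num_blocks`
hidden blocks applies, with a residual connection:

1. a depthwise *structured long convolution*: the kernel is the
   concatenation of S segments, segment 0 the k learnable base weights,
   segment i ≥ 1 the (independent, per-scale) base linearly interpolated to
   length k·2^{i-1} and attenuated by decayⁱ (decay default 0.5), for a total
   length k·2^{S-1} at parameter cost S·k per channel.  Convolution is causal
   and computed by FFT with zero padding (numerically equal to direct
   convolution).  This segment-length scheme is the unique concatenation of
   doubling segments consistent with the total k·2^{S-1}.  Optional L2
   normalization of the assembled kernel is available but off by default.
2. addition of the diffusion-step embedding: a sinusoidal embedding of t
   (fractional t allowed, as needed by the continuous-time likelihood) with a
   learned per-block linear projection, broadcast over time.
3. GELU (exact, erf-based).
4. *block-sparse channel mixing*: a per-timepoint linear map over the latent
   dimension D whose weight matrix is masked to dense diagonal blocks of edge
   b = `mixing_block_size` plus the two off-diagonal stripes at offsets ±b.
   Active weights number D·b + 2(D-b) — linear in D for fixed b, against the
   quadratic cost of a dense map — while the stripes let information
   propagate across all blocks over depth.  b = D recovers a dense layer
   (the default for the small desk-scale models).
5. layer normalization over channels (batch normalization available).

Class conditioning adds a learned per-class embedding to the step embedding;
channel conditioning (for conditional imputation) concatenates the
observation mask and the masked observed values as 2C extra input channels.

Training uses AdamW on mini-batches with per-element diffusion steps
t ~ U{1..T}, an exponential moving average of the weights (decay 0.999 by
default; shorter desk-scale runs use 0.995) for all sampling, and aborts on
non-finite loss.  Checkpoints are NumPy `.npz` archives holding raw and EMA
weights plus the full configuration.  The network stack (layers, backprop,
AdamW, EMA) is a purpose-built NumPy implementation; gradients of every
layer are verified against finite differences in the test suite.

## Imputation

Two modes:

- **Inpainting** (unconditional model, arbitrary missingness pattern): after
  every reverse step the observed entries are replaced by the analytical
  forward-diffused state of the observed values at the new step, guiding the
  chain along the observations; at t = 0 observed entries equal the
  observations exactly.  This does not target the exact conditional
  distribution but needs no special training.
- **Conditional** (model trained with random channel dropout): during
  training each batch element drops k ~ U{1..C} random channels and the
  network is conditioned on the clean remaining channels; at imputation time
  the observed channels are fed to the network at every step and copied
  through unchanged.  Only whole-channel missingness is supported here.

## Probability-flow likelihood

The discrete ladder is lifted to continuous time by piecewise-linear
interpolation of log ᾱ(t) (exact at integer steps), giving a
variance-preserving flow with piecewise-constant β(t) = -d log ᾱ/dt.  The
probability-flow ODE dx/dt = -½β(t)[x - ε_θ(x,t)/√(1-ᾱ(t))] is integrated
with an adaptive Runge-Kutta method (tolerance 1e-5 by default) from a small
cutoff t₀ = 0.01·T (the score is singular at t = 0; the cutoff is shared
across classes, so classification differences are unaffected) to t = T,
accumulating the divergence of the drift:
log p(x) = log N(x(T); 0, I) + ∫ div f dt.  The divergence uses the exact
trace (one vector-Jacobian product per coordinate) for windows up to 4096
values and a Hutchinson estimator with fixed Rademacher probes (default 32)
beyond; both routes go through the same hand-verified backward pass.
The Hutchinson error scales with the off-diagonal Jacobian mass, which is
small for (near-)optimal denoisers but can exceed 1% for untrained networks.
Models trained with OU noise are handled by whitening the data with the
AR(1) innovation transform and adding the constant log-Jacobian
-½ log|Σ|; this treats the whitened model as a white-noise model and is an
approximation documented as such.

Applications: per-class log-likelihoods give two-class brain-state
classification (argmax of log p(x|c) + log prior, ties to the first class),
sliding-window state tracking (log-likelihood difference over windows), and
outlier scoring by total log-likelihood log Σ_c prior(c)p(x|c) via
log-sum-exp, summarized as an ROC AUC with real windows as positives.

## Evaluation metrics

- **PSD percentiles**: one-sided periodogram over the whole window (no Welch
  segmentation — across-window percentiles supply the variability), then
  pointwise median/10%/90% across windows.  When comparing a median PSD to an
  analytic spectrum S(f), the correct reference is ln 2 · S(f): the
  periodogram is S(f)·χ²₂/2 pointwise, whose median is ln 2 ≈ -1.59 dB below
  the mean.  This matters at the 3 dB scale used in the recovery checks.
- **Band-pass filtering**: zero-phase; Butterworth (order 5 default) applied
  forward-backward, Hamming-window FIR applied by 'same' convolution with an
  odd-length linear-phase kernel (exact group-delay compensation).  The
  automatic FIR order is ~3 cycles of the low band edge, capped at a third
  of the window length — short windows cannot support longer kernels, and an
  uncapped kernel corrupts phase estimates.
- **SWR detection**: band-pass 100-275 Hz, instantaneous power = squared
  Hilbert envelope (the power estimator is a choice; the envelope is the
  standard one), threshold at mean + 3 SD of reference power statistics
  computed once over the whole real set and reused unchanged for generated
  data; supra-threshold runs closer than 10 samples are fused, runs shorter
  than 20 samples discarded; the event peak is the sample of maximal band
  power.
- **Couplings**: phase-amplitude coupling bins the Hilbert amplitude of the
  fast band by the Hilbert phase of the slow band into 31 equal bins over
  [-180°, 180°); phase-occurrence coupling histograms the slow-band phase at
  detected event peaks into 21 bins.  Degrees, inclusive-left bin edges.
- **Window-level F1 and permutation test**: positive = "window contains ≥ 1
  event"; F1 = 2TP/(2TP+FP+FN) (defined as 1 when the denominator is 0,
  i.e. perfect all-negative agreement).  The permutation test shuffles the
  prediction-to-window assignment and uses the add-one estimator
  p = (1 + #{F1_perm ≥ F1_obs})/(1 + n_perm), which cannot return 0.  The
  estimator is slightly conservative under heavy ties (few distinct F1
  values at small window counts); the conservatism scales inversely with
  the spread of the permutation statistic, so calibration tests use several
  thousand windows per replicate, where the p-values are uniform to KS
  precision.
- **Imputation correlation**: Pearson correlation per imputed channel per
  window, averaged; constant channels (e.g. mean imputation) have no defined
  correlation and are excluded with a warning.
- **Memorization check**: nearest-neighbour Euclidean distances (raw samples
  or amplitude spectra) from each generated window to the training set,
  compared to the leave-one-out train-vs-train minima with a two-sample KS
  test.  Generated minima far below the train-train distribution flag
  copying.

## Synthetic data

The generators reproduce, with known ground truth, the statistical structure
the evaluation needs: 1/f^a spectra (FFT-shaped Gaussian noise), AR(1)/OU
windows with an analytic Lorentzian spectrum, three-channel recordings with
ripple-band bursts phase-locked to a slow oscillation (von Mises-thinned
Poisson point process, normalized by e^κ/I₀(κ) so the realized burst rate
equals the nominal rate independent of coupling strength; default 0.5
bursts/s — ripples are rare events, and a rare-event regime is required for
the mean + 3 SD threshold to sit below the bursts), two-state datasets with
class-specific spectral peaks (awake-like 40 Hz vs anesthetized-like 8 Hz
with steeper 1/f), linear mixtures of latent colored sources for imputation
oracles, and trial-locked evoked responses (template + 12 Hz oscillation +
1/f noise).  Every generator is deterministic under a fixed seed and records
its sampling law in a metadata dict.

What the generators do *not* emulate: nonstationarity across hours,
electrode drift and artifacts, cross-frequency structure beyond the injected
couplings, non-Gaussian heavy tails, and volume-conduction geometry.
Passing tests therefore demonstrate correctness of the machinery and
recoverability of the injected structure, not performance on real
recordings.

## Desk-scale study conditions

All trained-model checks run at reduced size on one CPU: T = 200 diffusion
steps with a linear β ∈ [1e-4, 0.05] schedule (the endpoint is scaled so the
terminal signal fraction ᾱ_T ≈ 0.006 stays below 1%, the same role the
standard T = 1000, β ∈ [1e-4, 0.02] ladder plays), windows of L = 128
samples, ~1500-2000 training windows, latent dimension 24, two blocks,
structured kernels of total length 64, 2200-2500 AdamW steps at batch 48,
EMA decay 0.995.  Likelihood-based evaluations use the Hutchinson divergence
with 8 probes and tolerance 1e-3, which empirically preserves the ranking
accuracy of the exact trace at a small fraction of its cost.  Monte-Carlo
checks of the OU law use 10⁵ sampled paths, where the entrywise tolerance of
0.02 sits ~4 standard errors above the estimator noise.

## Known limitations

- No accelerated samplers (DDIM-style); generation costs T network passes.
- Conditional imputation handles whole-channel missingness only (inpainting
  handles arbitrary masks).
- OU likelihoods rely on the whitening approximation described above.
- The NumPy network stack is single-threaded beyond BLAS/FFT parallelism and
  is sized for desk-scale experiments, not 100-channel production training.
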
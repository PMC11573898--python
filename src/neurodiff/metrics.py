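"""Evaluation procedures for real vs. generated neural time series.

Covers full-window periodogram summaries (pointwise median and 10/90
percentiles over a set of windows), trial averages, zero-phase band-pass
filtering, sharp-wave-ripple (SWR) detection with the classic
mean + 3 SD band-power threshold, phase-amplitude and phase-occurrence
coupling profiles, window-level F1 with a permutation test, channelwise
imputation correlations, and a nearest-neighbour memorization check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.stats import ks_2samp

__all__ = [
    "PSDSummary",
    "SWREvent",
    "CouplingProfile",
    "compute_psd",
    "psd_percentiles",
    "trial_average",
    "bandpass",
    "ripple_power",
    "ripple_power_stats",
    "detect_swr",
    "phase_amplitude_coupling",
    "phase_count_coupling",
    "f1_swr_prediction",
    "permutation_test",
    "channelwise_correlation",
    "memorization_check",
]

RIPPLE_BAND = (100.0, 275.0)
SWR_FUSE_GAP = 10  # events closer than this many samples are fused
SWR_MIN_LEN = 20  # events shorter than this many samples are discarded


@dataclass
class PSDSummary:
    """Pointwise spectral percentiles over a set of windows."""

    freqs: np.ndarray
    median: np.ndarray
    p10: np.ndarray
    p90: np.ndarray


@dataclass(frozen=True)
class SWREvent:
    """A detected ripple interval [start, end) with its band-power peak index."""

    start: int
    end: int
    peak: int

    def __post_init__(self):
        if not (self.start <= self.peak < self.end):
            raise ValueError("peak must lie inside [start, end)")


@dataclass
class CouplingProfile:
    """Binned coupling profile over phase; 31 bins for PAC, 21 for phase counts."""

    bin_edges: np.ndarray  # degrees, [-180, 180]
    values: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


# ---------------------------------------------------------------------------
# spectra and trial averages
# ---------------------------------------------------------------------------


def compute_psd(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram over the whole window (no segmenting)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("compute_psd expects a 1-D window of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    freqs, pxx = sps.periodogram(x, fs=fs, window="boxcar", detrend=False)
    return freqs, pxx


def psd_percentiles(windows: np.ndarray, fs: float) -> PSDSummary:
    """Pointwise median / p10 / p90 of per-window periodograms."""
    windows = np.asarray(windows, dtype=float)
    if windows.ndim != 2:
        raise ValueError("windows must be (n, length)")
    spectra = []
    for w in windows:
        freqs, pxx = compute_psd(w, fs)
        spectra.append(pxx)
    S = np.stack(spectra)
    return PSDSummary(
        freqs=freqs,
        median=np.median(S, axis=0),
        p10=np.percentile(S, 10, axis=0),
        p90=np.percentile(S, 90, axis=0),
    )


def trial_average(trials: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and SD across trials of shape (n, channels, length)."""
    trials = np.asarray(trials, dtype=float)
    if trials.shape[0] < 2:
        raise ValueError("need at least 2 trials for a standard deviation")
    return trials.mean(axis=0), trials.std(axis=0, ddof=0)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def bandpass(
    x: np.ndarray,
    fs: float,
    low: float,
    high: float,
    method: str = "fir_hamming",
    order: int | None = None,
) -> np.ndarray:
    """Zero-phase band-pass along the last axis.

    FIR (Hamming window) filters are applied by 'same'-mode convolution with
    an odd-length linear-phase kernel, which compensates the group delay
    exactly; IIR (Butterworth) filters are applied forward-backward.
    """
    if not (0.0 < low < high < fs / 2.0):
        raise ValueError(f"invalid band ({low}, {high}) for fs={fs}")
    x = np.asarray(x, dtype=float)
    if method == "butterworth":
        sos = sps.butter(order or 5, [low, high], btype="bandpass", fs=fs, output="sos")
        return sps.sosfiltfilt(sos, x, axis=-1)
    if method == "fir_hamming":
        if order is None:
            # ~3 cycles of the low band edge, but never longer than a third of
            # the window (short windows cannot support very long kernels)
            order = min(int(3 * fs / low), x.shape[-1] // 3)
        ntaps = order + 1 if (order + 1) % 2 == 1 else order + 2  # odd taps
        ntaps = min(ntaps, x.shape[-1] - (1 - x.shape[-1] % 2))
        if ntaps < 3:
            raise ValueError("window too short for the requested FIR filter")
        taps = sps.firwin(ntaps, [low, high], pass_zero=False, window="hamming", fs=fs)
        return np.apply_along_axis(lambda v: np.convolve(v, taps, mode="same"), -1, x)
    raise ValueError(f"unknown filter method {method!r}")


# ---------------------------------------------------------------------------
# SWR detection
# ---------------------------------------------------------------------------


def ripple_power(x: np.ndarray, fs: float, band=RIPPLE_BAND) -> np.ndarray:
    """Instantaneous ripple-band power: squared Hilbert envelope of the
    band-passed signal."""
    filt = bandpass(x, fs, band[0], band[1], method="fir_hamming")
    return np.abs(sps.hilbert(filt, axis=-1)) ** 2


def ripple_power_stats(windows: np.ndarray, fs: float, band=RIPPLE_BAND) -> tuple[float, float]:
    """Mean and SD of ripple-band power pooled over a whole set of real windows.

    These reference statistics are reused unchanged when detecting ripples in
    generated data, so both sets face the same threshold.
    """
    windows = np.atleast_2d(np.asarray(windows, dtype=float))
    power = ripple_power(windows, fs, band)
    return float(power.mean()), float(power.std())


def detect_swr(
    ca1: np.ndarray,
    fs: float,
    reference_stats: tuple[float, float],
    band=RIPPLE_BAND,
    fuse_gap: int = SWR_FUSE_GAP,
    min_len: int = SWR_MIN_LEN,
) -> list[SWREvent]:
    """Threshold-based ripple detection on a single channel.

    The signal is band-passed to the ripple band, its instantaneous power
    thresholded at reference mean + 3 SD; supra-threshold runs closer than
    ``fuse_gap`` samples are fused and runs shorter than ``min_len`` samples
    are discarded.  The event peak is the sample of maximal band power.
    """
    if fs < 2.0 * band[1]:
        raise ValueError(f"fs={fs} too low for the {band} Hz band")
    if reference_stats is None:
        raise ValueError("reference_stats (mean, SD of real ripple power) required")
    mean, sd = reference_stats
    power = ripple_power(np.asarray(ca1, dtype=float), fs, band)
    above = power > mean + 3.0 * sd
    if not above.any():
        return []
    # supra-threshold runs
    d = np.diff(above.astype(int))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    # fuse runs separated by short gaps
    fused = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - fused[-1][1] < fuse_gap:
            fused[-1][1] = e
        else:
            fused.append([s, e])
    events = []
    for s, e in fused:
        if e - s < min_len:
            continue
        peak = s + int(np.argmax(power[s:e]))
        events.append(SWREvent(start=s, end=e, peak=peak))
    return events


# ---------------------------------------------------------------------------
# coupling profiles
# ---------------------------------------------------------------------------

PAC_BINS = 31
PHASE_COUNT_BINS = 21


def _instantaneous_phase_deg(x: np.ndarray, fs: float, band) -> np.ndarray:
    filt = bandpass(x, fs, band[0], band[1], method="fir_hamming")
    return np.degrees(np.angle(sps.hilbert(filt)))


def phase_amplitude_coupling(
    phase_src: np.ndarray,
    amp_src: np.ndarray,
    fs: float,
    phase_band: tuple[float, float],
    amp_band: tuple[float, float] = RIPPLE_BAND,
) -> CouplingProfile:
    """Mean high-band amplitude of ``amp_src`` in 31 equal bins of the
    low-band phase of ``phase_src``."""
    for band in (phase_band, amp_band):
        if band[1] >= fs / 2.0:
            raise ValueError(f"band {band} exceeds Nyquist for fs={fs}")
    phase = _instantaneous_phase_deg(np.asarray(phase_src, float), fs, phase_band)
    amp = np.abs(sps.hilbert(bandpass(np.asarray(amp_src, float), fs, *amp_band)))
    edges = np.linspace(-180.0, 180.0, PAC_BINS + 1)
    idx = np.clip(np.digitize(phase, edges) - 1, 0, PAC_BINS - 1)
    values = np.array(
        [amp[idx == b].mean() if np.any(idx == b) else np.nan for b in range(PAC_BINS)]
    )
    return CouplingProfile(bin_edges=edges, values=values)


def phase_count_coupling(
    events: list[SWREvent],
    phase_src: np.ndarray,
    fs: float,
    band: tuple[float, float],
) -> CouplingProfile:
    """Histogram (21 bins) of the low-band phase at each event's power peak."""
    edges = np.linspace(-180.0, 180.0, PHASE_COUNT_BINS + 1)
    if len(events) == 0:
        return CouplingProfile(bin_edges=edges, values=np.zeros(PHASE_COUNT_BINS))
    phase = _instantaneous_phase_deg(np.asarray(phase_src, float), fs, band)
    peaks = np.array([ev.peak for ev in events])
    counts, _ = np.histogram(phase[peaks], bins=edges)
    return CouplingProfile(bin_edges=edges, values=counts.astype(float))


# ---------------------------------------------------------------------------
# F1 + permutation test
# ---------------------------------------------------------------------------


def f1_swr_prediction(real_flags: np.ndarray, pred_flags: np.ndarray) -> float:
    """Window-level F1 = 2 TP / (2 TP + FP + FN), positive = window has >= 1 SWR."""
    real = np.asarray(real_flags, dtype=bool)
    pred = np.asarray(pred_flags, dtype=bool)
    if real.shape != pred.shape or real.size == 0:
        raise ValueError("flag vectors must be nonempty and equal length")
    tp = int(np.sum(real & pred))
    fp = int(np.sum(~real & pred))
    fn = int(np.sum(real & ~pred))
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2.0 * tp / denom


def permutation_test(
    real_flags: np.ndarray,
    pred_flags: np.ndarray,
    n_perm: int = 1000,
    rng: np.random.Generator | int = 0,
) -> float:
    """Permutation p-value for the window-level F1.

    The prediction-to-window assignment is shuffled ``n_perm`` times;
    p = (1 + #{F1_perm >= F1_obs}) / (1 + n_perm).
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pred = np.asarray(pred_flags, dtype=bool)
    observed = f1_swr_prediction(real_flags, pred)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pred)
        if f1_swr_prediction(real_flags, perm) >= observed:
            count += 1
    return (1 + count) / (1 + n_perm)


# ---------------------------------------------------------------------------
# imputation correlation and memorization check
# ---------------------------------------------------------------------------


def channelwise_correlation(
    truth: np.ndarray,
    imputed: np.ndarray,
    mask: np.ndarray,
) -> float:
    """Mean Pearson correlation between true and imputed channels.

    ``truth`` and ``imputed`` are (n, C, L); ``mask`` is a boolean (C,) or
    (n, C) array marking the *imputed* channels.  Constant channels have no
    defined correlation and are excluded with a warning.
    """
    truth = np.asarray(truth, dtype=float)
    imputed = np.asarray(imputed, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim == 1:
        mask = np.broadcast_to(mask, truth.shape[:2])
    cors = []
    skipped = 0
    for i in range(truth.shape[0]):
        for c in np.where(mask[i])[0]:
            a, b = truth[i, c], imputed[i, c]
            if a.std() == 0 or b.std() == 0:
                skipped += 1
                continue
            cors.append(np.corrcoef(a, b)[0, 1])
    if skipped:
        warnings.warn(f"excluded {skipped} constant channel(s) from correlation")
    if not cors:
        raise ValueError("no non-constant imputed channels to correlate")
    return float(np.mean(cors))


def memorization_check(
    train: np.ndarray,
    generated: np.ndarray,
    domain: str = "time",
) -> dict:
    """Nearest-neighbour distances between generated and training windows.

    For each generated window, the minimum Euclidean distance to any training
    window (raw samples, or amplitude spectra when ``domain='frequency'``),
    reported alongside the leave-one-out train-vs-train minima as the
    reference distribution.  Generated minima far below the train-train
    distribution indicate memorization.
    """
    if domain not in ("time", "frequency"):
        raise ValueError("domain must be 'time' or 'frequency'")
    tr = np.asarray(train, dtype=float).reshape(len(train), -1)
    ge = np.asarray(generated, dtype=float).reshape(len(generated), -1)
    if tr.shape[1] != ge.shape[1]:
        raise ValueError("train and generated windows must share channels x length")
    if domain == "frequency":
        n = train.shape[-1]
        tr = np.abs(np.fft.rfft(np.asarray(train, float), axis=-1)).reshape(len(train), -1)
        ge = np.abs(np.fft.rfft(np.asarray(generated, float), axis=-1)).reshape(len(generated), -1)
    # pairwise distances
    d_gt = np.sqrt(
        np.maximum(
            (ge**2).sum(1)[:, None] + (tr**2).sum(1)[None, :] - 2.0 * ge @ tr.T, 0.0
        )
    )
    gen_min = d_gt.min(axis=1)
    d_tt = np.sqrt(
        np.maximum(
            (tr**2).sum(1)[:, None] + (tr**2).sum(1)[None, :] - 2.0 * tr @ tr.T, 0.0
        )
    )
    np.fill_diagonal(d_tt, np.inf)
    train_min = d_tt.min(axis=1)
    ks = ks_2samp(gen_min, train_min)
    return {
        "generated_min": gen_min,
        "train_min": train_min,
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
    }
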
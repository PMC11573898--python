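"""Preprocessing and I/O: recordings, windows, splits, outlier-channel masking.

The canonical on-disk layout is an HDF5 file with ``/data`` (channel x time,
float32) plus ``fs`` and ``channel_names`` attributes for recordings, and
``/windows`` (n x channel x time) with optional ``/labels``, ``/norm_mean``,
``/norm_std``, ``/channel_mask`` datasets for window sets.  NPZ and CSV
(channels as rows) are supported for small fixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .metrics import bandpass

logger = logging.getLogger("neurodiff")

__all__ = [
    "Recording",
    "WindowSet",
    "NormalizationParams",
    "standardize_channels",
    "extract_windows",
    "train_eval_split",
    "mask_outlier_channels",
    "read_recording",
    "write_recording",
    "read_windows",
    "write_windows",
]


@dataclass
class Recording:
    """A continuous multichannel recording."""

    data: np.ndarray  # channels x samples
    fs: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaN; mask bad channels explicitly")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]


@dataclass
class NormalizationParams:
    mean: np.ndarray  # per channel
    std: np.ndarray


@dataclass
class WindowSet:
    """n standardized windows of shape channels x length with optional labels."""

    windows: np.ndarray  # n x channels x length
    fs: float
    labels: np.ndarray | None = None
    norm: NormalizationParams | None = None
    channel_mask: np.ndarray | None = None  # True = channel kept

    def __post_init__(self):
        self.windows = np.asarray(self.windows, dtype=float)
        if self.windows.ndim != 3:
            raise ValueError("windows must be (n, channels, length)")

    @property
    def n(self) -> int:
        return self.windows.shape[0]

    @property
    def channels(self) -> int:
        return self.windows.shape[1]

    @property
    def length(self) -> int:
        return self.windows.shape[2]


def standardize_channels(
    data: np.ndarray, stats: NormalizationParams | None = None
) -> tuple[np.ndarray, NormalizationParams]:
    """Channel-by-channel (x - mean) / SD standardization.

    ``data`` is (channels, samples) or (n, channels, length); statistics are
    estimated over the full duration (aggregating windows), or applied
    unchanged when ``stats`` is given — the train-to-eval transfer.  The
    inverse transform is ``x * std + mean``.
    """
    data = np.asarray(data, dtype=float)
    ax = (1,) if data.ndim == 2 else (0, 2)
    if stats is None:
        mean = data.mean(axis=ax)
        std = data.std(axis=ax)
        bad = np.where(std == 0)[0]
        if bad.size:
            raise ValueError(f"constant channel(s) {bad.tolist()} cannot be standardized")
        stats = NormalizationParams(mean=mean, std=std)
    m = stats.mean[:, None] if data.ndim == 2 else stats.mean[None, :, None]
    s = stats.std[:, None] if data.ndim == 2 else stats.std[None, :, None]
    return (data - m) / s, stats


def extract_windows(rec: Recording, window_len: int, stride: int | None = None) -> WindowSet:
    """Consecutive windows at the given stride (default: non-overlapping)."""
    stride = stride or window_len
    C, N = rec.data.shape
    if window_len > N:
        raise ValueError("window_len exceeds recording length")
    starts = np.arange(0, N - window_len + 1, stride)
    windows = np.stack([rec.data[:, s : s + window_len] for s in starts])
    logger.info("extracted %d windows of %d samples (stride %d)", len(starts), window_len, stride)
    return WindowSet(windows=windows, fs=rec.fs)


def train_eval_split(
    ws: WindowSet, train_frac: float, rng: np.random.Generator | int = 0
) -> tuple[WindowSet, WindowSet]:
    """Random partition with floor(train_frac * n) training windows."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    if ws.n < 2:
        raise ValueError("need at least 2 windows to split")
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    perm = rng.permutation(ws.n)
    n_train = int(np.floor(train_frac * ws.n))
    tr, ev = perm[:n_train], perm[n_train:]
    logger.info("split %d windows into %d train / %d eval", ws.n, len(tr), len(ev))

    def subset(idx):
        return WindowSet(
            windows=ws.windows[idx],
            fs=ws.fs,
            labels=None if ws.labels is None else ws.labels[idx],
            norm=ws.norm,
            channel_mask=ws.channel_mask,
        )

    return subset(tr), subset(ev)


def mask_outlier_channels(ws: WindowSet, factor: float = 5.0) -> np.ndarray:
    """Flag extreme outlier channels on the aggregated training data.

    A channel is masked (False = excluded from loss and metrics) when its
    peak-to-peak range is ``factor`` or more times its interquartile range.
    Channels with zero IQR are masked with a warning.
    """
    data = ws.windows.transpose(1, 0, 2).reshape(ws.channels, -1)
    rng_ = data.max(axis=1) - data.min(axis=1)
    q75, q25 = np.percentile(data, [75, 25], axis=1)
    iqr = q75 - q25
    keep = np.ones(ws.channels, dtype=bool)
    for c in range(ws.channels):
        if iqr[c] == 0:
            logger.warning("channel %d has zero IQR; masked", c)
            keep[c] = False
        elif rng_[c] >= factor * iqr[c]:
            keep[c] = False
    ws.channel_mask = keep
    return keep


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_recording(rec: Recording, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=rec.data.astype(np.float32))
        d.attrs["fs"] = rec.fs
        d.attrs["channel_names"] = rec.channel_names


def read_recording(path, format: str | None = None) -> Recording:
    """Load a recording from HDF5, NPZ, or CSV (channels as rows).

    NPZ files need ``data`` and ``fs`` entries; CSV files carry no sampling
    rate, so a ``# fs=...`` first-line comment is required.
    """
    path = Path(path)
    fmt = format or {".h5": "hdf5", ".hdf5": "hdf5", ".npz": "npz", ".csv": "csv"}.get(
        path.suffix.lower()
    )
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            d = f["data"]
            if "fs" not in d.attrs:
                raise ValueError(f"{path}: missing fs attribute")
            names = [str(n) for n in d.attrs.get("channel_names", [])]
            return Recording(data=d[()], fs=float(d.attrs["fs"]), channel_names=names)
    if fmt == "npz":
        with np.load(path) as z:
            if "fs" not in z:
                raise ValueError(f"{path}: missing fs entry")
            return Recording(data=z["data"], fs=float(z["fs"]))
    if fmt == "csv":
        with open(path) as f:
            first = f.readline().strip()
        if not first.startswith("# fs="):
            raise ValueError(f"{path}: CSV requires a '# fs=<Hz>' header line")
        fs = float(first.split("=", 1)[1])
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return Recording(data=data, fs=fs)
    raise ValueError(f"unknown format for {path}")


def write_windows(ws: WindowSet, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("windows", data=ws.windows.astype(np.float32))
        d.attrs["fs"] = ws.fs
        if ws.labels is not None:
            f.create_dataset("labels", data=np.asarray(ws.labels))
        if ws.norm is not None:
            f.create_dataset("norm_mean", data=ws.norm.mean)
            f.create_dataset("norm_std", data=ws.norm.std)
        if ws.channel_mask is not None:
            f.create_dataset("channel_mask", data=ws.channel_mask)


def read_windows(path) -> WindowSet:
    with h5py.File(path, "r") as f:
        d = f["windows"]
        if "fs" not in d.attrs:
            raise ValueError(f"{path}: missing fs attribute")
        norm = None
        if "norm_mean" in f:
            norm = NormalizationParams(mean=f["norm_mean"][()], std=f["norm_std"][()])
        return WindowSet(
            windows=d[()].astype(float),
            fs=float(d.attrs["fs"]),
            labels=f["labels"][()] if "labels" in f else None,
            norm=norm,
            channel_mask=f["channel_mask"][()].astype(bool) if "channel_mask" in f else None,
        )


def preprocess_recording(
    rec: Recording,
    window_seconds: float,
    train_frac: float = 0.8,
    seed: int = 0,
    band: tuple[float, float] | None = None,
    filter_order: int = 5,
) -> tuple[WindowSet, WindowSet]:
    """Standard pipeline: optional Butterworth band-pass, channelwise
    standardization over the whole recording, non-overlapping windowing, and a
    random train/eval split."""
    data = rec.data
    if band is not None:
        data = bandpass(data, rec.fs, band[0], band[1], method="butterworth", order=filter_order)
    data, norm = standardize_channels(data)
    ws = extract_windows(Recording(data, rec.fs, rec.channel_names), int(round(window_seconds * rec.fs)))
    ws.norm = norm
    train, evalset = train_eval_split(ws, train_frac, rng=seed)
    return train, evalset
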
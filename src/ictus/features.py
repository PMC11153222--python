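"""Sliding-window segmentation and STFT spectrogram features.

A filtered recording is cut into 1.35-s windows (345 samples at 256 Hz) with
1-s overlap. Each window is transformed channel-by-channel with a short-time
Fourier transform using a 2-sample Hamming window, 1-sample hop and a
128-point transform (2 Hz bin spacing at 256 Hz), giving 344 frames per
window. Band-limited log-power bins (default 20–60 Hz, half-open, 20 bins)
from the six channels are stacked vertically into the 120 x 344 spectrogram
epoch the classifier consumes.

Power is normalized per frame as ``|X_k|^2 / (nfft * sum(w^2))`` so that the
sum over all two-sided bins equals the mean power of the windowed frame
(Parseval); values are reported as ``10 log10`` dB with a configurable floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import windows as sig_windows

from .io import DEFAULT_CHANNELS, Recording, SeizureAnnotation

__all__ = [
    "WindowConfig",
    "StftParams",
    "WindowSegment",
    "SpectrogramEpoch",
    "RHYTHM_BANDS",
    "rhythm_band",
    "sliding_windows",
    "frame_power",
    "stft_channel",
    "stack_channels",
    "epoch_from_segment",
    "label_window",
    "recording_to_epochs",
    "save_epochs",
    "load_epochs",
]

SEIZURE_ACTIVE = "seizure-active"
SEIZURE_FREE = "seizure-free"
UNLABELED = "unlabeled"

#: Named rhythm bands (Hz), half-open [low, high).
RHYTHM_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 60.0),
    "selected": (20.0, 60.0),
}


def rhythm_band(name: str) -> tuple[float, float]:
    """Return the (low_hz, high_hz) edges of a named rhythm band."""
    try:
        return RHYTHM_BANDS[name]
    except KeyError:
        raise ValueError(
            f"unknown band {name!r}; expected one of {sorted(RHYTHM_BANDS)}"
        ) from None


@dataclass(frozen=True)
class WindowConfig:
    """Sliding analysis-window geometry.

    window_s  : window duration in seconds (default 1.35, i.e. 345 samples).
    overlap_s : overlap between consecutive windows (default 1.0 s).
    fs        : sampling rate in Hz.
    """

    fs: float = 256.0
    window_s: float = 1.35
    overlap_s: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_s < self.window_s:
            raise ValueError("overlap must satisfy 0 <= overlap_s < window_s")
        if self.hop_samples < 1:
            raise ValueError("window hop must be at least one sample")

    @property
    def window_samples(self) -> int:
        return int(math.floor(self.window_s * self.fs))

    @property
    def hop_samples(self) -> int:
        return self.window_samples - int(round(self.overlap_s * self.fs))


@dataclass(frozen=True)
class StftParams:
    """Per-window STFT parameters.

    win_len  : analysis window length in samples (default 2, Hamming).
    hop      : frame hop in samples (default 1, i.e. 1-sample overlap).
    nfft     : transform length; bin spacing = fs / nfft (2 Hz at defaults).
    band     : half-open [low_hz, high_hz) selection of bin centers.
    floor_db : log-power floor in dB, guarantees finite output.
    """

    fs: float = 256.0
    win_len: int = 2
    hop: int = 1
    nfft: int = 128
    band: tuple[float, float] = (20.0, 60.0)
    floor_db: float = -120.0

    def __post_init__(self) -> None:
        if self.win_len < 1 or self.hop < 1:
            raise ValueError("win_len and hop must be positive")
        if self.nfft < self.win_len:
            raise ValueError("nfft must be at least win_len")
        low, high = self.band
        if not (0 <= low < high <= self.fs / 2):
            raise ValueError("band must lie within [0, fs/2]")
        if len(self.band_bin_indices) == 0:
            raise ValueError(f"band {self.band} selects zero STFT bins")

    @property
    def window(self) -> np.ndarray:
        return sig_windows.hamming(self.win_len, sym=True)

    @property
    def bin_freqs(self) -> np.ndarray:
        """One-sided bin center frequencies (Hz)."""
        return np.arange(self.nfft // 2 + 1) * (self.fs / self.nfft)

    @property
    def band_bin_indices(self) -> np.ndarray:
        f = self.bin_freqs
        low, high = self.band
        return np.nonzero((f >= low) & (f < high))[0]

    @property
    def band_bin_freqs(self) -> np.ndarray:
        return self.bin_freqs[self.band_bin_indices]

    def n_frames(self, n_samples: int) -> int:
        if n_samples < self.win_len:
            return 0
        return (n_samples - self.win_len) // self.hop + 1


@dataclass
class WindowSegment:
    """One sliding window of multichannel samples (channels x samples, uV)."""

    start_s: float
    samples: np.ndarray
    label: str = UNLABELED


@dataclass
class SpectrogramEpoch:
    """Stacked band-limited log-power image for one window.

    ``values`` has shape (6 * n_band_bins, n_frames); rows
    ``[i * n_band_bins, (i + 1) * n_band_bins)`` belong to channel ``i`` in
    ``channel_block_order``.
    """

    values: np.ndarray
    start_s: float
    band_bins: np.ndarray
    channel_block_order: tuple[str, ...]


def sliding_windows(rec: Recording, cfg: WindowConfig) -> list[WindowSegment]:
    """Cut a recording into fully-contained sliding windows.

    Windows start at sample offsets 0, hop, 2*hop, ...; the last window lies
    entirely inside the recording (no padding). A recording shorter than one
    window yields an empty list.
    """
    if abs(rec.fs - cfg.fs) > 1e-9:
        raise ValueError(f"recording fs {rec.fs} != window config fs {cfg.fs}")
    w, hop = cfg.window_samples, cfg.hop_samples
    out: list[WindowSegment] = []
    for offset in range(0, rec.n_samples - w + 1, hop):
        out.append(
            WindowSegment(start_s=offset / rec.fs, samples=rec.signals[:, offset : offset + w])
        )
    return out


def frame_power(samples: np.ndarray, p: StftParams, two_sided: bool = False) -> np.ndarray:
    """Linear STFT power of one channel, shape (n_frames, n_bins).

    Frames of ``win_len`` samples at ``hop`` spacing are windowed, zero-padded
    to ``nfft`` and transformed; power is ``|X|^2 / (nfft * sum(w^2))`` so the
    two-sided sum over bins equals the mean power of the windowed frame.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("frame_power expects a single channel")
    if x.size < p.win_len:
        raise ValueError(f"need at least win_len={p.win_len} samples, got {x.size}")
    frames = sliding_window_view(x, p.win_len)[:: p.hop] * p.window
    norm = p.nfft * float(np.sum(p.window**2))
    if two_sided:
        spec = np.fft.fft(frames, n=p.nfft, axis=-1)
    else:
        spec = np.fft.rfft(frames, n=p.nfft, axis=-1)
    return (spec.real**2 + spec.imag**2) / norm


def _to_db(power: np.ndarray, floor_db: float) -> np.ndarray:
    floor_lin = 10.0 ** (floor_db / 10.0)
    return 10.0 * np.log10(np.maximum(power, floor_lin))


def stft_channel(samples: np.ndarray, p: StftParams) -> np.ndarray:
    """Band-limited log-power spectrogram of one channel.

    Returns an (n_band_bins, n_frames) array of dB values floored at
    ``p.floor_db``; 20 x 344 at defaults for a 345-sample window.
    """
    power = frame_power(samples, p)
    return _to_db(power[:, p.band_bin_indices].T, p.floor_db)


def stack_channels(
    per_channel: Sequence[np.ndarray],
    start_s: float,
    band_bins: np.ndarray | None = None,
    channel_block_order: Sequence[str] = DEFAULT_CHANNELS,
) -> SpectrogramEpoch:
    """Vertically concatenate six per-channel spectrograms into one epoch."""
    if len(per_channel) != 6:
        raise ValueError(f"expected 6 channel spectrograms, got {len(per_channel)}")
    shapes = {m.shape for m in per_channel}
    if len(shapes) != 1:
        raise ValueError(f"channel spectrogram shapes differ: {sorted(shapes)}")
    values = np.concatenate(list(per_channel), axis=0)
    return SpectrogramEpoch(
        values=values,
        start_s=start_s,
        band_bins=np.asarray(band_bins) if band_bins is not None else np.array([]),
        channel_block_order=tuple(channel_block_order),
    )


def epoch_from_segment(seg: WindowSegment, p: StftParams) -> SpectrogramEpoch:
    """Transform one 6-channel window segment into a spectrogram epoch."""
    mats = [stft_channel(seg.samples[ch], p) for ch in range(seg.samples.shape[0])]
    return stack_channels(mats, seg.start_s, band_bins=p.band_bin_freqs)


def label_window(
    w: WindowSegment | tuple[float, float],
    ann: SeizureAnnotation,
    min_overlap_frac: float = 0.5,
    window_s: float | None = None,
) -> str:
    """Label a window seizure-active iff it overlaps an annotated interval enough.

    The window span ``[start, start + window_s)`` must overlap a single
    annotated interval by at least ``min_overlap_frac * window_s`` seconds.
    Accepts a :class:`WindowSegment` or a bare ``(start_s, end_s)`` pair.
    """
    if isinstance(w, WindowSegment):
        if window_s is None:
            raise ValueError("window_s is required to label a WindowSegment")
        start, end = w.start_s, w.start_s + window_s
    else:
        start, end = w
    span = end - start
    return SEIZURE_ACTIVE if ann.overlap_s(start, end) >= min_overlap_frac * span else SEIZURE_FREE


def recording_to_epochs(
    rec: Recording,
    wcfg: WindowConfig,
    p: StftParams,
    ann: SeizureAnnotation | None = None,
    min_overlap_frac: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Transform a whole recording into stacked epochs (vectorized).

    Returns ``(epochs, labels, starts)`` where ``epochs`` has shape
    ``(n_windows, 6 * n_band_bins, n_frames)`` (float32 dB), ``labels`` is an
    int8 array (1 = seizure-active, 0 = seizure-free, -1 = unlabeled) and
    ``starts`` gives window start times in seconds.

    When the window hop is a multiple of the STFT hop, per-channel frames are
    computed once for the full recording and sliced per window; this equals
    the per-window computation exactly (frames only use samples inside their
    window, so the pipeline stays causal).
    """
    if rec.n_channels != 6:
        raise ValueError("recording must already be reduced to the 6 analysis channels")
    w, hop = wcfg.window_samples, wcfg.hop_samples
    n_windows = 0 if rec.n_samples < w else (rec.n_samples - w) // hop + 1
    nf = p.n_frames(w)
    nb = len(p.band_bin_indices)
    starts = np.arange(n_windows) * hop / rec.fs
    epochs = np.empty((n_windows, 6 * nb, nf), dtype=np.float32)
    if n_windows:
        if hop % p.hop == 0:
            frames_per_window_hop = hop // p.hop
            for ch in range(6):
                full = frame_power(rec.signals[ch], p)[:, p.band_bin_indices]  # (frames, bins)
                view = sliding_window_view(full, nf, axis=0)[::frames_per_window_hop]
                # view: (n_windows_full, bins, frames)
                epochs[:, ch * nb : (ch + 1) * nb, :] = _to_db(view[:n_windows], p.floor_db)
        else:
            for k, seg in enumerate(sliding_windows(rec, wcfg)):
                epochs[k] = epoch_from_segment(seg, p).values
    if ann is None:
        labels = np.full(n_windows, -1, dtype=np.int8)
    else:
        labels = np.fromiter(
            (
                1 if label_window((s, s + wcfg.window_s), ann, min_overlap_frac) == SEIZURE_ACTIVE
                else 0
                for s in starts
            ),
            dtype=np.int8,
            count=n_windows,
        )
    return epochs, labels, starts


def save_epochs(
    path: str | Path,
    epochs: np.ndarray,
    labels: np.ndarray,
    starts: np.ndarray,
    p: StftParams | None = None,
) -> Path:
    """Persist an epoch tensor to HDF5 (datasets: epochs, labels, starts)."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("epochs", data=np.asarray(epochs, dtype=np.float32))
        fh.create_dataset("labels", data=np.asarray(labels, dtype=np.int8))
        fh.create_dataset("starts", data=np.asarray(starts, dtype=np.float64))
        if p is not None:
            fh.attrs["fs"] = p.fs
            fh.attrs["win_len"] = p.win_len
            fh.attrs["hop"] = p.hop
            fh.attrs["nfft"] = p.nfft
            fh.attrs["band"] = list(p.band)
            fh.attrs["floor_db"] = p.floor_db
    return path


def load_epochs(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Load an epoch tensor saved by :func:`save_epochs`."""
    import h5py

    with h5py.File(path, "r") as fh:
        return fh["epochs"][()], fh["labels"][()], fh["starts"][()]
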
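"""Seeded synthetic multichannel EEG with annotated seizure episodes.

The generator targets the statistical structure the detection pipeline keys
on, not clinical realism: background activity is 1/f ("pink") noise plus a
10 Hz alpha rhythm plus broadband white noise, independent per channel;
seizure episodes superimpose a periodic train of exponentially-decaying sharp
transients (a spike-and-wave caricature) and band-limited 20-60 Hz noise
calibrated, per channel and per episode, so the total in-band power during the
seizure exceeds the local background by the configured boost in dB. Seizure
components are applied to all six channels with per-channel gains drawn from
[0.5, 1]; the band-noise calibration absorbs the gain so the spectral contract
holds on every channel.

Everything is reproducible from the configuration seed. An optional flag
generates amplitude-depression episodes (suppressed background, no band
boost) for negative testing; these are deliberately not produced by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import signal

from .io import (
    DEFAULT_CHANNELS,
    Recording,
    SeizureAnnotation,
    write_edf_recording,
)

__all__ = [
    "SeizureSpec",
    "SynthConfig",
    "generate_recording",
    "generate_dataset",
    "write_synthetic_edf",
    "band_power",
]


@dataclass(frozen=True)
class SeizureSpec:
    """One synthetic seizure episode."""

    onset_s: float
    duration_s: float
    spike_rate_hz: float = 4.0  # sharp-transient rate, 3-5 Hz range
    band_boost_db: float = 20.0  # 20-60 Hz power elevation over background
    amplitude_uv: float = 100.0  # spike peak amplitude
    depression: bool = False  # amplitude-depression episode (no boost)

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class SynthConfig:
    """Synthetic recording configuration.

    Background is parameterized by the 1/f spectral exponent (power ~ f^-exp),
    the 1/f component RMS, the 10 Hz alpha-rhythm amplitude and the broadband
    white-noise sigma, all in microvolts.
    """

    duration_s: float
    fs: float = 256.0
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    one_over_f_exponent: float = 1.0
    one_over_f_rms_uv: float = 20.0
    alpha_amp_uv: float = 10.0
    broadband_sigma_uv: float = 5.0
    seizures: tuple[SeizureSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration and sampling rate must be positive")
        ordered = sorted(self.seizures, key=lambda s: s.onset_s)
        prev_end = 0.0
        for s in ordered:
            if s.onset_s < 0 or s.offset_s > self.duration_s:
                raise ValueError(
                    f"seizure ({s.onset_s}, {s.offset_s}) outside recording span"
                )
            if s.onset_s < prev_end:
                raise ValueError("seizure intervals must not overlap")
            if not s.depression and s.band_boost_db <= 0:
                raise ValueError("band_boost_db must be positive for detectable seizures")
            prev_end = s.offset_s

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)


def band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Mean power of ``x`` inside ``[low, high)`` Hz (periodogram integral)."""
    freqs, psd = signal.periodogram(x, fs=fs)
    mask = (freqs >= band[0]) & (freqs < band[1])
    if freqs.size < 2 or not mask.any():
        return 0.0
    df = freqs[1] - freqs[0]
    return float(np.sum(psd[mask]) * df)


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise with power spectral density ~ f^-exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    freqs[0] = freqs[1]  # avoid the DC singularity
    spec *= freqs ** (-exponent / 2.0)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    return x / np.std(x)


def _spike_kernel(fs: float) -> np.ndarray:
    """Unit-peak sharp transient: fast biphasic swing with exponential decay."""
    t = np.arange(int(round(0.25 * fs))) / fs
    k = np.exp(-t / 0.04) * np.sin(2 * np.pi * 6.0 * t)
    return k / np.max(np.abs(k))


_BAND = (20.0, 60.0)


def generate_recording(cfg: SynthConfig) -> tuple[Recording, SeizureAnnotation]:
    """Generate one recording and its annotation, reproducibly from cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    n = int(round(cfg.duration_s * fs))
    n_ch = cfg.n_channels
    t = np.arange(n) / fs

    background = np.empty((n_ch, n))
    for ch in range(n_ch):
        pink = cfg.one_over_f_rms_uv * _pink_noise(n, cfg.one_over_f_exponent, rng)
        alpha = cfg.alpha_amp_uv * np.sin(2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi))
        white = cfg.broadband_sigma_uv * rng.standard_normal(n)
        background[ch] = pink + alpha + white

    signals = background.copy()
    sos = signal.butter(4, _BAND, btype="bandpass", fs=fs, output="sos")
    kernel = _spike_kernel(fs)

    for sz in sorted(cfg.seizures, key=lambda s: s.onset_s):
        i0 = int(round(sz.onset_s * fs))
        i1 = min(n, int(round(sz.offset_s * fs)))
        length = i1 - i0
        if length <= 0:
            continue
        gains = rng.uniform(0.5, 1.0, n_ch)
        if sz.depression:
            signals[:, i0:i1] = background[:, i0:i1] * 0.2
            continue
        # periodic spike train shared across channels (scaled per channel)
        train = np.zeros(length)
        step = int(round(fs / sz.spike_rate_hz))
        for start in range(0, length, step):
            seg = kernel[: length - start]
            train[start : start + len(seg)] += seg
        train *= sz.amplitude_uv
        spike_inband = band_power(train, fs, _BAND)

        raw_band = signal.sosfiltfilt(sos, rng.standard_normal(length))
        raw_band /= math.sqrt(max(band_power(raw_band, fs, _BAND), 1e-30))

        boost = 10.0 ** (sz.band_boost_db / 10.0)
        for ch in range(n_ch):
            p_bg = band_power(background[ch, i0:i1], fs, _BAND)
            target_added = (boost - 1.0) * p_bg
            noise_power = max(target_added - gains[ch] ** 2 * spike_inband, 0.0)
            signals[ch, i0:i1] += gains[ch] * train + math.sqrt(noise_power) * raw_band

    rec = Recording(signals=signals, fs=fs, channel_labels=cfg.channel_labels)
    ann = SeizureAnnotation(tuple((s.onset_s, s.offset_s) for s in cfg.seizures))
    return rec, ann


def generate_dataset(
    n_subjects: int,
    template: SynthConfig,
    seed: int | None = None,
) -> dict[str, tuple[Recording, SeizureAnnotation]]:
    """Generate a cohort of subjects from one template configuration.

    Subjects differ by derived seeds, mildly jittered background parameters
    and jittered seizure onsets; each keeps at least one seizure. The result
    supports leave-one-subject-out folds directly.
    """
    if n_subjects < 2:
        raise ValueError("a dataset needs at least 2 subjects")
    if not template.seizures:
        raise ValueError("template must define at least one seizure per subject")
    base = template.seed if seed is None else seed
    meta_rng = np.random.default_rng(base)
    out: dict[str, tuple[Recording, SeizureAnnotation]] = {}
    for i in range(n_subjects):
        seizures = []
        prev_end = 0.0
        for sz in sorted(template.seizures, key=lambda s: s.onset_s):
            jitter = meta_rng.uniform(-5.0, 5.0)
            onset = min(
                max(prev_end + 1.0, sz.onset_s + jitter),
                template.duration_s - sz.duration_s,
            )
            seizures.append(replace(sz, onset_s=onset))
            prev_end = onset + sz.duration_s
        cfg = replace(
            template,
            seed=(base + 1 + i) % (2**31 - 1),
            alpha_amp_uv=template.alpha_amp_uv * meta_rng.uniform(0.8, 1.2),
            broadband_sigma_uv=template.broadband_sigma_uv * meta_rng.uniform(0.8, 1.2),
            one_over_f_exponent=template.one_over_f_exponent + meta_rng.uniform(-0.1, 0.1),
            seizures=tuple(seizures),
        )
        out[f"subject{i + 1:02d}"] = generate_recording(cfg)
    return out


def write_synthetic_edf(
    rec: Recording,
    ann: SeizureAnnotation,
    out_dir: str | Path,
    stem: str = "synthetic",
) -> dict[str, Path]:
    """Write an EDF file plus a CHB-MIT-style summary naming its seizures.

    Returns the paths written; both round-trip through the readers in
    :mod:`ictus.io`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    edf_path = write_edf_recording(rec, out_dir / f"{stem}.edf")
    lines = [
        f"Data Sampling Rate: {rec.fs:g} Hz",
        "",
        f"File Name: {stem}.edf",
        f"Number of Seizures in File: {ann.n_seizures}",
    ]
    for k, (onset, offset) in enumerate(ann.intervals, start=1):
        lines.append(f"Seizure {k} Start Time: {onset:g} seconds")
        lines.append(f"Seizure {k} End Time: {offset:g} seconds")
    summary_path = out_dir / f"{stem}-summary.txt"
    summary_path.write_text("\n".join(lines) + "\n")
    return {"edf": edf_path, "summary": summary_path}
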
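"""Pipeline configuration: one file, every stage's knobs, YAML round trip.

Defaults reproduce the reference pipeline: six fixed bipolar channels, a
6th-order 1-60 Hz zero-phase Butterworth band-pass, 1.35-s windows with 1-s
overlap, a 2-sample-Hamming / 1-sample-hop / 128-point STFT restricted to
20-60 Hz, the full-width 29-level architecture and the reference training
protocol (learning rate 0.01, 30 epochs, 20% validation split evaluated every
50 iterations).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .features import RHYTHM_BANDS, StftParams, WindowConfig
from .io import DEFAULT_CHANNELS, ChannelSelection
from .model import TrainConfig
from .preprocess import FilterSpec

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """Full pipeline configuration with reference defaults."""

    seed: int = 0
    fs: float = 256.0
    channels: tuple[str, ...] = DEFAULT_CHANNELS

    # preprocessing
    filter_order: int = 6
    filter_band: tuple[float, float] = (1.0, 60.0)

    # sliding windows
    window_s: float = 1.35
    overlap_s: float = 1.0
    train_overlap_s: float = 1.0  # overlap of the training-window grid
    train_decimate: int = 1  # keep every k-th training window

    # STFT
    stft_win_len: int = 2
    stft_hop: int = 1
    stft_nfft: int = 128
    stft_band: tuple[float, float] = (20.0, 60.0)
    stft_floor_db: float = -120.0

    # architecture / training
    arch_width: float = 1.0
    learning_rate: float = 0.01
    epochs: int = 30
    val_fraction: float = 0.20
    val_frequency: int = 50
    batch_size: int = 32
    momentum: float = 0.9
    class_weighting: bool = False

    # training-segment extraction around each onset
    pre_onset_min: float = 10.0
    post_onset_min: float = 5.0

    # detector
    pre_tolerance_s: float = 0.0
    smoothing_k: int = 1

    # synthetic data
    synth_n_subjects: int = 3
    synth_duration_s: float = 300.0
    synth_n_seizures: int = 4
    synth_seizure_duration_s: float = 25.0
    synth_band_boost_db: float = 20.0
    synth_spike_rate_hz: float = 4.0
    synth_spike_amplitude_uv: float = 100.0

    # ---- derived stage configs -------------------------------------------
    def channel_selection(self) -> ChannelSelection:
        return ChannelSelection(self.channels)

    def filter_spec(self) -> FilterSpec:
        return FilterSpec(fs=self.fs, order=self.filter_order, band=tuple(self.filter_band))

    def window_config(self, training: bool = False) -> WindowConfig:
        overlap = self.train_overlap_s if training else self.overlap_s
        return WindowConfig(fs=self.fs, window_s=self.window_s, overlap_s=overlap)

    def stft_params(self) -> StftParams:
        return StftParams(
            fs=self.fs,
            win_len=self.stft_win_len,
            hop=self.stft_hop,
            nfft=self.stft_nfft,
            band=tuple(self.stft_band),
            floor_db=self.stft_floor_db,
        )

    def train_config(self, seed: int | None = None) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            val_fraction=self.val_fraction,
            val_frequency=self.val_frequency,
            batch_size=self.batch_size,
            momentum=self.momentum,
            seed=self.seed if seed is None else seed,
            class_weighting=self.class_weighting,
        )

    def with_band(self, band_name: str) -> "PipelineConfig":
        """Switch the STFT rhythm band by name (delta/theta/.../selected)."""
        return replace(self, stft_band=RHYTHM_BANDS[band_name])

    # ---- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("channels", "filter_band", "stft_band"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw = dict(d)
        for key in ("channels", "filter_band", "stft_band"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
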
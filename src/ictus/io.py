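"""Recording and annotation I/O.

Defines the shared data model (:class:`Recording`, :class:`SeizureAnnotation`,
:class:`ChannelSelection`) consumed by every pipeline stage, plus readers and
writers for EDF signals, seizure annotations (CHB-MIT-style summary text, CSV,
JSON) and detection-event CSV files.

All times are seconds from recording start; seizure intervals are half-open
``[onset, offset)``.
"""

from __future__ import annotations

import csv
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DEFAULT_CHANNELS",
    "ChannelSelection",
    "Recording",
    "SeizureAnnotation",
    "Event",
    "canonical_label",
    "read_edf_recording",
    "write_edf_recording",
    "read_annotations",
    "select_channels",
    "write_events",
    "read_events",
]

#: The six bipolar analysis channels, in fixed order.
DEFAULT_CHANNELS = ("P3-O1", "FP2-F8", "P8-O2", "P7-T7", "T7-FT9", "FT10-T8")


class ConfigurationError(ValueError):
    """Raised when file contents contradict the declared configuration."""


def canonical_label(label: str) -> str:
    """Canonicalize a bipolar channel label for comparison.

    Uppercases and normalizes every dash variant ("-", "–", "—", with or
    without surrounding spaces) to a bare "-", so that e.g. "P3 – O1",
    "p3-o1" and "P3-O1" all compare equal.
    """
    return re.sub(r"\s*[-–—]\s*", "-", label.strip().upper())


@dataclass(frozen=True)
class ChannelSelection:
    """An ordered selection of exactly six bipolar channel labels."""

    labels: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        if len(self.labels) != 6:
            raise ValueError(f"expected exactly 6 channel labels, got {len(self.labels)}")
        canon = [canonical_label(l) for l in self.labels]
        if len(set(canon)) != 6:
            raise ValueError("channel labels must be unique after canonicalization")


@dataclass
class Recording:
    """A multichannel EEG recording.

    Parameters
    ----------
    signals
        Array of shape ``(n_channels, n_samples)``, in microvolts.
    fs
        Sampling rate in Hz.
    channel_labels
        One label per signal row, unique.
    start_time
        Offset of the first sample, in seconds (default 0).
    """

    signals: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float64)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a 2-D (channels x samples) array")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.signals.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.signals.shape[0]} signal rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class SeizureAnnotation:
    """Annotated seizure intervals for one recording.

    ``intervals`` is a sorted tuple of ``(onset_s, offset_s)`` pairs, each
    half-open ``[onset, offset)``, non-overlapping.
    """

    intervals: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        ivs = tuple(sorted((float(a), float(b)) for a, b in self.intervals))
        for onset, offset in ivs:
            if not onset < offset:
                raise ValueError(f"interval onset {onset} must precede offset {offset}")
            if onset < 0:
                raise ValueError("interval times must be non-negative")
        for (_, b0), (a1, _) in zip(ivs, ivs[1:]):
            if a1 < b0:
                raise ValueError("seizure intervals must not overlap")
        object.__setattr__(self, "intervals", ivs)

    @property
    def n_seizures(self) -> int:
        return len(self.intervals)

    def validate_against(self, rec: Recording) -> None:
        """Raise if any interval falls outside the recording span."""
        for onset, offset in self.intervals:
            if offset > rec.duration_s + 1e-9:
                raise ValueError(
                    f"interval ({onset}, {offset}) exceeds recording duration {rec.duration_s:.3f} s"
                )

    def overlap_s(self, start_s: float, end_s: float) -> float:
        """Largest overlap (seconds) between [start_s, end_s) and any interval."""
        best = 0.0
        for onset, offset in self.intervals:
            best = max(best, min(end_s, offset) - max(start_s, onset))
        return best


@dataclass(frozen=True)
class Event:
    """One detection event row: a timestamp, a label and a probability."""

    time_s: float
    label: str
    probability: float


# ---------------------------------------------------------------------------
# EDF signals
# ---------------------------------------------------------------------------

def read_edf_recording(path: str | Path, fs_expected: float | None = None) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (microvolts).

    The sampling rate and channel labels come from the file header; no
    resampling is performed. If ``fs_expected`` is given and disagrees with
    the header, a :class:`ConfigurationError` is raised.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    if fs_expected is not None and not math.isclose(fs, fs_expected, rel_tol=1e-9):
        raise ConfigurationError(
            f"{path.name}: header sampling rate {fs} Hz != expected {fs_expected} Hz"
        )
    # mne returns SI volts; the data model is microvolts
    signals = raw.get_data() * 1e6
    return Recording(signals=signals, fs=fs, channel_labels=tuple(raw.ch_names))


def _ascii_field(value: str, width: int) -> bytes:
    out = value.encode("ascii", errors="replace")[:width]
    return out + b" " * (width - len(out))


def write_edf_recording(rec: Recording, path: str | Path) -> Path:
    """Write a :class:`Recording` to a plain EDF file.

    Samples are quantized to 16 bits over a per-channel symmetric physical
    range (microvolts), so the write→read round trip preserves values within
    one quantization step. The sampling rate must be an integer (one data
    record per second); recordings are zero-padded to a whole number of
    records. Header timestamps are fixed so identical recordings produce
    byte-identical files.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s data record
    n_records = int(math.ceil(rec.n_samples / spr))
    n_sig = rec.n_channels

    data = np.zeros((n_sig, n_records * spr), dtype=np.float64)
    data[:, : rec.n_samples] = rec.signals

    dig_min, dig_max = -32768, 32767
    phys_max = np.maximum(1.0, np.ceil(np.max(np.abs(data), axis=1)))
    phys_min = -phys_max
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((data - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    header = b"".join(
        [
            _ascii_field("0", 8),
            _ascii_field("X X X X", 80),
            _ascii_field("Startdate 01-JAN-2000 X X X", 80),
            _ascii_field("01.01.00", 8),
            _ascii_field("00.00.00", 8),
            _ascii_field(str(256 + 256 * n_sig), 8),
            _ascii_field("", 44),
            _ascii_field(str(n_records), 8),
            _ascii_field("1", 8),
            _ascii_field(str(n_sig), 4),
        ]
    )

    def sig_block(values: Iterable[str], width: int) -> bytes:
        return b"".join(_ascii_field(v, width) for v in values)

    header += sig_block(rec.channel_labels, 16)
    header += sig_block([""] * n_sig, 80)  # transducer
    header += sig_block(["uV"] * n_sig, 8)
    header += sig_block([f"{v:g}" for v in phys_min], 8)
    header += sig_block([f"{v:g}" for v in phys_max], 8)
    header += sig_block([str(dig_min)] * n_sig, 8)
    header += sig_block([str(dig_max)] * n_sig, 8)
    header += sig_block([""] * n_sig, 80)  # prefiltering
    header += sig_block([str(spr)] * n_sig, 8)
    header += sig_block([""] * n_sig, 32)

    with open(path, "wb") as fh:
        fh.write(header)
        # EDF interleaves records: all channels' samples for record r, in order
        records = digital.reshape(n_sig, n_records, spr).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(records).tobytes())
    return path


# ---------------------------------------------------------------------------
# Seizure annotations
# ---------------------------------------------------------------------------

_SUMMARY_FILE_RE = re.compile(r"^\s*File Name\s*:\s*(\S+)", re.IGNORECASE)
_SUMMARY_START_RE = re.compile(
    r"^\s*Seizure(?:\s+\d+)?\s+Start\s+Time\s*:\s*([\d.]+)\s*sec", re.IGNORECASE
)
_SUMMARY_END_RE = re.compile(
    r"^\s*Seizure(?:\s+\d+)?\s+End\s+Time\s*:\s*([\d.]+)\s*sec", re.IGNORECASE
)


def _parse_chbmit_summary(text: str) -> dict[str, SeizureAnnotation]:
    """Parse the minimal CHB-MIT summary subset: File Name / Seizure Start/End Time lines."""
    out: dict[str, list[tuple[float, float]]] = {}
    current: str | None = None
    pending_start: float | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        m = _SUMMARY_FILE_RE.match(line)
        if m:
            if pending_start is not None:
                raise ValueError(f"line {lineno}: seizure start without matching end time")
            current = m.group(1)
            out.setdefault(current, [])
            continue
        m = _SUMMARY_START_RE.match(line)
        if m:
            if current is None:
                raise ValueError(f"line {lineno}: seizure time before any 'File Name:' line")
            if pending_start is not None:
                raise ValueError(f"line {lineno}: two start times without an end time")
            pending_start = float(m.group(1))
            continue
        m = _SUMMARY_END_RE.match(line)
        if m:
            if current is None or pending_start is None:
                raise ValueError(f"line {lineno}: seizure end time without a start time")
            end = float(m.group(1))
            if end <= pending_start:
                raise ValueError(
                    f"line {lineno}: seizure end {end} s must exceed start {pending_start} s"
                )
            out[current].append((pending_start, end))
            pending_start = None
    if pending_start is not None:
        raise ValueError("summary ended with a seizure start lacking an end time")
    return {name: SeizureAnnotation(tuple(ivs)) for name, ivs in out.items()}


def _parse_csv_annotations(path: Path) -> dict[str, SeizureAnnotation]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty annotation CSV")
        fields = [f.strip() for f in reader.fieldnames]
        if "onset_s" not in fields or "offset_s" not in fields:
            raise ValueError(f"{path}: annotation CSV needs onset_s and offset_s columns")
        has_rec = "recording" in fields
        rows: dict[str, list[tuple[float, float]]] = {}
        for row in reader:
            key = row["recording"].strip() if has_rec else path.stem
            rows.setdefault(key, []).append((float(row["onset_s"]), float(row["offset_s"])))
    return {k: SeizureAnnotation(tuple(v)) for k, v in rows.items()}


def read_annotations(
    path: str | Path, dialect: str = "chbmit_summary"
) -> dict[str, SeizureAnnotation]:
    """Read seizure annotations, keyed by recording name.

    Dialects: ``chbmit_summary`` (File Name / Seizure Start Time / Seizure End
    Time lines), ``csv`` (columns ``onset_s,offset_s`` with an optional
    ``recording`` column; without one, the file stem is the key) and ``json``
    (mapping of recording name to a list of ``[onset, offset]`` pairs).
    """
    path = Path(path)
    if dialect == "chbmit_summary":
        return _parse_chbmit_summary(path.read_text())
    if dialect == "csv":
        return _parse_csv_annotations(path)
    if dialect == "json":
        data = json.loads(path.read_text())
        return {
            name: SeizureAnnotation(tuple((float(a), float(b)) for a, b in ivs))
            for name, ivs in data.items()
        }
    raise ValueError(f"unknown annotation dialect: {dialect!r}")


def select_channels(rec: Recording, sel: ChannelSelection | None = None) -> Recording:
    """Reduce a recording to the six analysis channels, in selection order.

    Labels are matched after canonicalization (case and dash style are
    ignored). Missing labels raise a :class:`KeyError` naming them.
    """
    sel = sel or ChannelSelection()
    available = {canonical_label(l): i for i, l in enumerate(rec.channel_labels)}
    missing = [l for l in sel.labels if canonical_label(l) not in available]
    if missing:
        raise KeyError(f"channels not found in recording: {', '.join(missing)}")
    idx = [available[canonical_label(l)] for l in sel.labels]
    return Recording(
        signals=rec.signals[idx].copy(),
        fs=rec.fs,
        channel_labels=tuple(sel.labels),
        start_time=rec.start_time,
    )


# ---------------------------------------------------------------------------
# Detection-event CSV
# ---------------------------------------------------------------------------

def write_events(events: Sequence, path: str | Path) -> Path:
    """Write detection events to CSV with header ``time_s,label,probability``.

    Accepts any objects exposing those attributes (``start_s`` accepted in
    place of ``time_s``, so window decisions can be written directly). Floats
    are written with full repr precision so the round trip is lossless.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "label", "probability"])
        for ev in events:
            t = getattr(ev, "time_s", None)
            if t is None:
                t = ev.start_s
            writer.writerow([repr(float(t)), ev.label, repr(float(ev.probability))])
    return path


def read_events(path: str | Path) -> list[Event]:
    """Read back a detection-event CSV written by :func:`write_events`."""
    out: list[Event] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            out.append(Event(float(row["time_s"]), row["label"], float(row["probability"])))
    return out
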
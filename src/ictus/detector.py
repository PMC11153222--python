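"""Causal sliding-window detection and event extraction.

A trained model is streamed over a recording one analysis window at a time;
each decision uses only the samples inside its own window, so truncating the
recording reproduces the prefix of decisions exactly. Per-window decisions
are then matched against annotated seizure intervals to produce true
positives (with onset delay), missed seizures and false-positive runs.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .features import (
    SEIZURE_ACTIVE,
    StftParams,
    WindowConfig,
    recording_to_epochs,
)
from .io import Recording, SeizureAnnotation
from .model import CLASS_NAMES, TrainedModel
from .preprocess import FilterSpec, apply_zero_phase

__all__ = [
    "WindowDecision",
    "DetectionEvent",
    "stream_detect",
    "extract_events",
    "measure_latency",
]


@dataclass(frozen=True)
class WindowDecision:
    """Model decision for one sliding window."""

    start_s: float
    label: str
    probability: float  # probability of seizure-active
    elapsed_s: float | None = None  # per-window wall time when timing enabled


@dataclass(frozen=True)
class DetectionEvent:
    """One event-level outcome: TP, FP_event or missed."""

    kind: str  # "TP" | "FP_event" | "missed"
    annotation_index: int | None = None
    detection_time_s: float | None = None
    delay_s: float | None = None


def stream_detect(
    model: TrainedModel,
    rec: Recording,
    wcfg: WindowConfig,
    p: StftParams,
    preprocess: FilterSpec | None = None,
    batch_size: int = 64,
    timing: bool = False,
) -> list[WindowDecision]:
    """Run the model over every sliding window of a recording.

    ``preprocess`` optionally applies the zero-phase band-pass first (pass
    ``None`` when the recording is already filtered). With ``timing=True``
    windows are processed one at a time and each decision carries its
    feature-plus-inference wall time; otherwise inference is batched (the
    decisions are identical either way).
    """
    if preprocess is not None:
        rec = apply_zero_phase(rec, preprocess)
    decisions: list[WindowDecision] = []
    if timing:
        from .features import epoch_from_segment, sliding_windows

        for seg in sliding_windows(rec, wcfg):
            t0 = time.perf_counter()
            epoch = epoch_from_segment(seg, p)
            probs = model.predict_proba(epoch.values)
            elapsed = time.perf_counter() - t0
            decisions.append(
                WindowDecision(seg.start_s, CLASS_NAMES[int(probs.argmax())],
                               float(probs[1]), elapsed)
            )
        return decisions

    epochs, _, starts = recording_to_epochs(rec, wcfg, p)
    for i in range(0, len(epochs), batch_size):
        probs = model.predict_proba(epochs[i : i + batch_size])
        for s, pr in zip(starts[i : i + batch_size], probs):
            decisions.append(
                WindowDecision(float(s), CLASS_NAMES[int(pr.argmax())], float(pr[1]))
            )
    return decisions


def _asserted_positive(decisions: list[WindowDecision], smoothing_k: int) -> np.ndarray:
    """Positivity after requiring smoothing_k consecutive positive windows.

    With k=1 this is the raw decision sequence; with k>1 a window is asserted
    positive only when it ends a run of >= k positive windows (causal).
    """
    pos = np.array([d.label == SEIZURE_ACTIVE for d in decisions], dtype=bool)
    if smoothing_k <= 1:
        return pos
    run = 0
    out = np.zeros_like(pos)
    for i, v in enumerate(pos):
        run = run + 1 if v else 0
        out[i] = run >= smoothing_k
    return out


def extract_events(
    decisions: list[WindowDecision],
    ann: SeizureAnnotation,
    pre_tolerance_s: float = 0.0,
    smoothing_k: int = 1,
) -> list[DetectionEvent]:
    """Convert window decisions into TP / missed / FP_event outcomes.

    Each annotated interval is matched to the first asserted-positive window
    whose start lies in ``[onset - pre_tolerance_s, offset)``; the delay is
    that window's start minus the onset (so with the default tolerance 0 the
    delay is never negative). Intervals with no such window become ``missed``.
    At most one TP is produced per interval; further positive windows inside a
    matched interval's extended span are neither TPs nor FPs. Positive windows
    outside every extended interval are grouped into consecutive runs, one
    ``FP_event`` per run, stamped with the run's first window start.
    """
    asserted = _asserted_positive(decisions, smoothing_k)
    starts = np.array([d.start_s for d in decisions])
    events: list[DetectionEvent] = []
    in_extended = np.zeros(len(decisions), dtype=bool)
    for idx, (onset, offset) in enumerate(ann.intervals):
        lo, hi = onset - pre_tolerance_s, offset
        inside = (starts >= lo) & (starts < hi)
        in_extended |= inside
        hit = np.nonzero(inside & asserted)[0]
        if hit.size:
            t = float(starts[hit[0]])
            events.append(DetectionEvent("TP", idx, t, t - onset))
        else:
            events.append(DetectionEvent("missed", idx))
    fp = asserted & ~in_extended
    i = 0
    while i < len(fp):
        if fp[i]:
            j = i
            while j + 1 < len(fp) and fp[j + 1]:
                j += 1
            events.append(DetectionEvent("FP_event", None, float(starts[i])))
            i = j + 1
        else:
            i += 1
    return events


def measure_latency(decisions: list[WindowDecision]) -> dict:
    """Summarize per-window processing time (informational only).

    Returns ``{"n": count, "mean_s": ..., "max_s": ..., "per_window_s": [...]}``;
    empty report (n = 0) when timing instrumentation was not enabled.
    """
    times = [d.elapsed_s for d in decisions if d.elapsed_s is not None]
    if not times:
        return {"n": 0, "mean_s": None, "max_s": None, "per_window_s": []}
    return {
        "n": len(times),
        "mean_s": float(np.mean(times)),
        "max_s": float(np.max(times)),
        "per_window_s": times,
    }
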
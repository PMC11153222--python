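"""Causal streaming detection and event extraction."""

from __future__ import annotations

import numpy as np
import pytest

from ictus.detector import (
    WindowDecision,
    extract_events,
    measure_latency,
    stream_detect,
)
from ictus.features import StftParams, WindowConfig
from ictus.io import Recording, SeizureAnnotation

WCFG = WindowConfig()
P = StftParams()
HOP_S = WCFG.hop_samples / WCFG.fs


def _decisions(flags, start0=0.0):
    return [
        WindowDecision(start0 + i * HOP_S, "seizure-active" if f else "seizure-free",
                       0.9 if f else 0.1)
        for i, f in enumerate(flags)
    ]


def test_stream_detect_counts_and_determinism(small_recording, tiny_model):
    rec, _ = small_recording  # 60 s at 256 Hz
    d1 = stream_detect(tiny_model, rec, WCFG, P)
    # brute-force offset enumeration
    assert len(d1) == len(range(0, rec.n_samples - 345 + 1, 89)) == 169
    d2 = stream_detect(tiny_model, rec, WCFG, P)
    assert d1 == d2


def test_stream_detect_short_recording(tiny_model):
    rec = Recording(np.zeros((6, 200)), fs=256.0,
                    channel_labels=tuple(f"c{i}" for i in range(6)))
    assert stream_detect(tiny_model, rec, WCFG, P) == []


def test_causality_under_truncation(small_recording, tiny_model):
    """Truncating the recording reproduces exactly the prefix of decisions."""
    rec, _ = small_recording
    full = stream_detect(tiny_model, rec, WCFG, P)
    t_cut = 30.0
    cut = Recording(rec.signals[:, : int(t_cut * rec.fs)], fs=rec.fs,
                    channel_labels=rec.channel_labels)
    truncated = stream_detect(tiny_model, cut, WCFG, P)
    expected = [d for d in full if d.start_s + WCFG.window_s <= t_cut]
    assert [(d.start_s, d.label) for d in truncated[: len(expected)]] == [
        (d.start_s, d.label) for d in expected
    ]
    # probabilities agree to float32 batching effects
    assert np.allclose(
        [d.probability for d in truncated[: len(expected)]],
        [d.probability for d in expected],
        atol=1e-5,
    )
    # no decision may use samples beyond the cut
    assert all(d.start_s + WCFG.window_s <= t_cut + 1e-9 for d in truncated)


def test_worked_delay_example():
    """Onset 361 s, first positive window at 367 s -> 6-s delay."""
    n = 200
    flags = [False] * n
    start0 = 361.0 - 20 * HOP_S  # some pre-onset context
    first_pos = 20 + int(round(6.0 / HOP_S))
    start0 += 367.0 - (start0 + first_pos * HOP_S)  # align so that window start == 367.0
    for i in range(first_pos, first_pos + 30):
        flags[i] = True
    decisions = _decisions(flags, start0=start0)
    assert decisions[first_pos].start_s == pytest.approx(367.0)
    events = extract_events(decisions, SeizureAnnotation(((361.0, 413.0),)))
    tp = [e for e in events if e.kind == "TP"]
    assert len(tp) == 1
    assert tp[0].delay_s == pytest.approx(6.0)
    assert tp[0].detection_time_s == pytest.approx(367.0)


def test_detection_at_onset_and_missed():
    ann = SeizureAnnotation(((10.0, 20.0),))
    # positive window exactly at the onset -> delay 0
    d = [WindowDecision(10.0, "seizure-active", 0.9)]
    ev = extract_events(d, ann)
    assert ev[0].kind == "TP" and ev[0].delay_s == 0.0
    # no positive window inside [onset, offset) -> missed
    d = [
        WindowDecision(5.0, "seizure-active", 0.9),
        WindowDecision(6.0, "seizure-free", 0.1),
        WindowDecision(25.0, "seizure-active", 0.9),
    ]
    ev = extract_events(d, ann)
    assert [e.kind for e in ev if e.annotation_index == 0] == ["missed"]
    # ... and the two separated outside positives form two FP runs
    assert sum(e.kind == "FP_event" for e in ev) == 2


def test_pre_tolerance_credits_early_detection():
    ann = SeizureAnnotation(((10.0, 20.0),))
    d = [WindowDecision(8.5, "seizure-active", 0.9)]
    assert extract_events(d, ann)[0].kind == "missed"
    ev = extract_events(d, ann, pre_tolerance_s=2.0)
    assert ev[0].kind == "TP"
    assert ev[0].delay_s == pytest.approx(-1.5)
    assert ev[0].delay_s >= -2.0  # bound: delay >= -pre_tolerance


def test_smoothing_requires_consecutive_positives():
    ann = SeizureAnnotation(((0.0, 100.0),))
    flags = [True, False, True, True, True, False]
    d = _decisions(flags)
    raw = extract_events(d, ann, smoothing_k=1)
    assert raw[0].detection_time_s == pytest.approx(d[0].start_s)
    smoothed = extract_events(d, ann, smoothing_k=3)
    # first run of 3 consecutive positives ends at index 4
    assert smoothed[0].detection_time_s == pytest.approx(d[4].start_s)


from conftest import oracle_events as _oracle_events


def test_event_extraction_matches_oracle_on_random_configs():
    rng = np.random.default_rng(12345)
    for _ in range(500):
        n = int(rng.integers(1, 60))
        flags = rng.random(n) < rng.uniform(0.05, 0.6)
        decisions = _decisions(list(flags))
        horizon = n * HOP_S + 2.0
        intervals = []
        t = 0.0
        while t < horizon and len(intervals) < 4:
            onset = t + float(rng.uniform(0.0, 8.0))
            offset = onset + float(rng.uniform(0.5, 6.0))
            intervals.append((onset, offset))
            t = offset + 0.1
        ann = SeizureAnnotation(tuple(intervals))
        tol = float(rng.choice([0.0, 0.0, 1.0, 3.0]))
        k = int(rng.choice([1, 1, 2, 3]))
        got = extract_events(decisions, ann, pre_tolerance_s=tol, smoothing_k=k)
        want = _oracle_events(decisions, ann, tol, k)
        got_tuples = [(e.kind, e.annotation_index, e.detection_time_s, e.delay_s) for e in got]
        assert got_tuples == want
        for e in got:
            if e.kind == "TP":
                assert e.delay_s >= -tol - 1e-12


def test_measure_latency(small_recording, tiny_model):
    rec, _ = small_recording
    short = Recording(rec.signals[:, : 256 * 5], fs=rec.fs, channel_labels=rec.channel_labels)
    timed = stream_detect(tiny_model, short, WCFG, P, timing=True)
    report = measure_latency(timed)
    assert report["n"] == len(timed) > 0
    assert report["mean_s"] >= 0 and report["max_s"] >= report["mean_s"]
    untimed = stream_detect(tiny_model, short, WCFG, P)
    assert measure_latency(untimed)["n"] == 0
    # timing instrumentation must not change the decisions
    assert [(d.start_s, d.label) for d in timed] == [(d.start_s, d.label) for d in untimed]
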
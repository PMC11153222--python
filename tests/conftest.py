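"""Shared fixtures and oracles: small synthetic recordings, reduced models,
and an independent exhaustive-scan implementation of event matching."""

from __future__ import annotations

import itertools

import pytest

from ictus.model import build_model, default_architecture
from ictus.synth import SeizureSpec, SynthConfig, generate_recording


def oracle_events(decisions, ann, pre_tolerance_s=0.0, smoothing_k=1):
    """Brute-force event matching, independent of ictus.detector.

    Returns (kind, annotation_index, detection_time_s, delay_s) tuples in the
    same order as extract_events: per-interval outcomes, then FP runs.
    """
    pos = [d.label == "seizure-active" for d in decisions]
    asserted = []
    for i in range(len(pos)):
        run, j = 0, i
        while j >= 0 and pos[j]:
            run += 1
            j -= 1
        asserted.append(run >= smoothing_k)
    events = []
    covered = [False] * len(decisions)
    for idx, (onset, offset) in enumerate(ann.intervals):
        hits = []
        for i, d in enumerate(decisions):
            if onset - pre_tolerance_s <= d.start_s < offset:
                covered[i] = True
                if asserted[i]:
                    hits.append(i)
        if hits:
            t = decisions[hits[0]].start_s
            events.append(("TP", idx, t, t - onset))
        else:
            events.append(("missed", idx, None, None))
    fp_idx = [i for i in range(len(decisions)) if asserted[i] and not covered[i]]
    for _, grp in itertools.groupby(enumerate(fp_idx), key=lambda kv: kv[1] - kv[0]):
        first = next(grp)[1]
        events.append(("FP_event", None, decisions[first].start_s, None))
    return events


@pytest.fixture(scope="session")
def small_recording():
    """60-s six-channel recording with one 20-dB seizure at 20-35 s."""
    cfg = SynthConfig(
        duration_s=60.0,
        seizures=(SeizureSpec(onset_s=20.0, duration_s=15.0, band_boost_db=20.0),),
        seed=3,
    )
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def seizure_free_recording():
    """30-s six-channel background-only recording."""
    cfg = SynthConfig(duration_s=30.0, seed=11)
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def tiny_model():
    """Untrained narrow model (width 1/32) for forward-pass plumbing tests."""
    return build_model(default_architecture(width=1 / 32), seed=5)
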
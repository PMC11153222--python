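"""End-to-end orchestration: training data preparation, leave-one-subject-out
evaluation, and the desk-scale synthetic benchmark.

The benchmark generates a small cohort of synthetic subjects with strongly
band-boosted seizures, trains one model per leave-one-subject-out fold on the
peri-onset segments of the training subjects, streams each held-out recording
through the detector, and pools event sensitivity, window FP rate, accuracy
and onset delay across folds. Problem sizes (recording length, seizures per
subject, architecture width, epoch count) are chosen so the whole benchmark
runs on one CPU core in minutes; the detection conditions themselves (20 dB
in-band boost, three subjects, twelve seizures) are fixed.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Mapping, Sequence

import numpy as np

from .config import PipelineConfig
from .detector import DetectionEvent, WindowDecision, extract_events, stream_detect
from .features import recording_to_epochs
from .io import Recording, SeizureAnnotation
from .metrics import CaseResult, EvalReport, aggregate, window_confusion
from .model import (
    TrainedModel,
    build_model,
    default_architecture,
    extract_training_segments,
    loso_folds,
    train,
)
from .preprocess import apply_zero_phase
from .synth import SeizureSpec, SynthConfig, generate_dataset

__all__ = [
    "prepare_training_data",
    "train_on_subjects",
    "evaluate_case",
    "run_loso",
    "default_benchmark_config",
    "loso_benchmark",
]

Dataset = Mapping[str, tuple[Recording, SeizureAnnotation]]


def _clip_annotation(ann: SeizureAnnotation, lo: float, hi: float) -> SeizureAnnotation:
    """Intervals intersected with [lo, hi), re-expressed relative to lo."""
    out = []
    for onset, offset in ann.intervals:
        a, b = max(onset, lo), min(offset, hi)
        if b > a:
            out.append((a - lo, b - lo))
    return SeizureAnnotation(tuple(out))


def prepare_training_data(
    rec: Recording,
    ann: SeizureAnnotation,
    cfg: PipelineConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled training epochs from one recording.

    Applies the zero-phase band-pass, extracts the peri-onset training
    segments (pre/post minutes around each seizure onset, merged), windows
    them on the training grid and transforms each window into a spectrogram
    epoch. Returns ``(epochs, labels)``.
    """
    filtered = apply_zero_phase(rec, cfg.filter_spec())
    segments = extract_training_segments(
        filtered, ann, pre_min=cfg.pre_onset_min, post_min=cfg.post_onset_min
    )
    wcfg = cfg.window_config(training=True)
    p = cfg.stft_params()
    xs, ys = [], []
    for lo, hi in segments:
        i0, i1 = int(math.floor(lo * rec.fs)), int(math.ceil(hi * rec.fs))
        sub = Recording(
            signals=filtered.signals[:, i0:i1],
            fs=rec.fs,
            channel_labels=filtered.channel_labels,
        )
        sub_ann = _clip_annotation(ann, i0 / rec.fs, i1 / rec.fs)
        epochs, labels, _ = recording_to_epochs(sub, wcfg, p, ann=sub_ann)
        if cfg.train_decimate > 1:
            epochs, labels = epochs[:: cfg.train_decimate], labels[:: cfg.train_decimate]
        if len(epochs):
            xs.append(epochs)
            ys.append(labels)
    if not xs:
        h = 6 * len(p.band_bin_indices)
        return np.empty((0, h, p.n_frames(wcfg.window_samples)), np.float32), np.empty(0, np.int8)
    return np.concatenate(xs), np.concatenate(ys)


def train_on_subjects(
    dataset: Dataset,
    subjects: Sequence[str],
    cfg: PipelineConfig,
    seed: int | None = None,
) -> TrainedModel:
    """Train one model on the pooled training epochs of the given subjects."""
    xs, ys = [], []
    for s in subjects:
        rec, ann = dataset[s]
        x, y = prepare_training_data(rec, ann, cfg)
        xs.append(x)
        ys.append(y)
    x = np.concatenate(xs)
    y = np.concatenate(ys).astype(np.int64)
    spec = default_architecture(width=cfg.arch_width)
    tcfg = cfg.train_config(seed=seed)
    model = build_model(spec, seed=tcfg.seed)
    return train(model, x, y, tcfg)


def evaluate_case(
    model: TrainedModel,
    rec: Recording,
    ann: SeizureAnnotation,
    cfg: PipelineConfig,
    case_id: str = "case",
) -> tuple[CaseResult, list[WindowDecision], list[DetectionEvent]]:
    """Stream one recording through the detector and score it."""
    decisions = stream_detect(
        model, rec, cfg.window_config(), cfg.stft_params(), preprocess=cfg.filter_spec()
    )
    events = extract_events(
        decisions, ann, pre_tolerance_s=cfg.pre_tolerance_s, smoothing_k=cfg.smoothing_k
    )
    confusion = window_confusion(decisions, ann, window_s=cfg.window_s)
    result = CaseResult.from_outputs(case_id, events, confusion, ann.n_seizures)
    return result, decisions, events


def run_loso(dataset: Dataset, cfg: PipelineConfig) -> tuple[EvalReport, dict[str, TrainedModel]]:
    """Leave-one-subject-out evaluation: one model per fold, pooled report."""
    cases: list[CaseResult] = []
    models: dict[str, TrainedModel] = {}
    for k, (train_subjects, test_subject) in enumerate(loso_folds(dataset)):
        model = train_on_subjects(dataset, train_subjects, cfg, seed=cfg.seed + k)
        rec, ann = dataset[test_subject]
        case, _, _ = evaluate_case(model, rec, ann, cfg, case_id=test_subject)
        cases.append(case)
        models[test_subject] = model
    return aggregate(cases), models


def default_benchmark_config(seed: int = 0) -> PipelineConfig:
    """Desk-scale pipeline configuration for the synthetic LOSO benchmark.

    Keeps the reference signal chain (window geometry, STFT parameters, band,
    filter) and shrinks only the compute: architecture width 1/16, 8 training
    epochs, training windows on a non-overlapping grid decimated by 2
    (one training window every 2.7 s).
    """
    return PipelineConfig(
        seed=seed,
        arch_width=1.0 / 16.0,
        epochs=8,
        train_overlap_s=0.0,
        train_decimate=2,
    )


def benchmark_dataset(cfg: PipelineConfig) -> Dataset:
    """The synthetic cohort the benchmark trains and tests on."""
    gap = cfg.synth_duration_s / cfg.synth_n_seizures
    seizures = tuple(
        SeizureSpec(
            onset_s=gap * k + (gap - cfg.synth_seizure_duration_s) / 2.0,
            duration_s=cfg.synth_seizure_duration_s,
            spike_rate_hz=cfg.synth_spike_rate_hz,
            band_boost_db=cfg.synth_band_boost_db,
            amplitude_uv=cfg.synth_spike_amplitude_uv,
        )
        for k in range(cfg.synth_n_seizures)
    )
    template = SynthConfig(
        duration_s=cfg.synth_duration_s, fs=cfg.fs, seizures=seizures, seed=cfg.seed
    )
    return generate_dataset(cfg.synth_n_subjects, template)


def loso_benchmark(seed: int = 0, cfg: PipelineConfig | None = None) -> EvalReport:
    """Generate the synthetic cohort, run LOSO, return the pooled report."""
    cfg = replace(cfg, seed=seed) if cfg is not None else default_benchmark_config(seed)
    dataset = benchmark_dataset(cfg)
    report, _ = run_loso(dataset, cfg)
    return report
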
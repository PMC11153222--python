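"""Event-based evaluation metrics: accuracy, sensitivity, FP rate, delay.

Window-level scores come from a confusion matrix of per-window decisions
against ground-truth window labels (a window counts as seizure-active when it
overlaps an annotated interval by at least half its span). Event-level
sensitivity is the fraction of annotated seizures with at least one detection;
the FP rate is the fraction of truly seizure-free windows flagged positive;
the delay is the gap between annotated onset and the first positive window.

Percentages are reported to two decimals with half-up rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .detector import DetectionEvent, WindowDecision
from .features import SEIZURE_ACTIVE, label_window
from .io import SeizureAnnotation

__all__ = [
    "Confusion",
    "CaseResult",
    "EvalReport",
    "window_confusion",
    "accuracy",
    "event_sensitivity",
    "fp_rate",
    "aggregate",
    "round2",
]


def round2(value: float) -> float:
    """Round to two decimals, half up (table formatting convention)."""
    return float(Decimal(repr(float(value))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Confusion:
    """Window-level confusion counts."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def window_confusion(
    decisions: Sequence[WindowDecision],
    ann: SeizureAnnotation,
    window_s: float,
    min_overlap_frac: float = 0.5,
) -> Confusion:
    """Score every window decision against its ground-truth label."""
    tp = tn = fp = fn = 0
    for d in decisions:
        truth_active = (
            label_window((d.start_s, d.start_s + window_s), ann, min_overlap_frac)
            == SEIZURE_ACTIVE
        )
        pred_active = d.label == SEIZURE_ACTIVE
        if truth_active and pred_active:
            tp += 1
        elif truth_active:
            fn += 1
        elif pred_active:
            fp += 1
        else:
            tn += 1
    return Confusion(tp=tp, tn=tn, fp=fp, fn=fn)


def accuracy(c: Confusion) -> float:
    """Percentage of correctly classified windows: 100 (TP+TN)/(TP+TN+FP+FN)."""
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * (c.tp + c.tn) / c.total


def event_sensitivity(n_detected: int, n_seizures: int) -> float:
    """Percentage of annotated seizures detected, to two decimals."""
    if n_seizures <= 0:
        raise ValueError("sensitivity undefined with zero seizures")
    if n_detected > n_seizures:
        raise ValueError("detected count cannot exceed seizure count")
    return round2(100.0 * n_detected / n_seizures)


def fp_rate(c: Confusion) -> float:
    """Percentage of truly seizure-free windows flagged positive: 100 FP/(FP+TN)."""
    if c.fp + c.tn == 0:
        raise ValueError("FP rate undefined without negative windows")
    return 100.0 * c.fp / (c.fp + c.tn)


@dataclass(frozen=True)
class CaseResult:
    """Evaluation of one case (one test recording or subject)."""

    case_id: str
    n_seizures: int
    n_detected: int
    fp_rate_pct: float
    sensitivity_pct: float
    mean_delay_s: float  # NaN when no seizure was detected
    accuracy_pct: float

    @classmethod
    def from_outputs(
        cls,
        case_id: str,
        events: Sequence[DetectionEvent],
        confusion: Confusion,
        n_seizures: int,
    ) -> "CaseResult":
        delays = [e.delay_s for e in events if e.kind == "TP"]
        n_detected = len(delays)
        return cls(
            case_id=case_id,
            n_seizures=n_seizures,
            n_detected=n_detected,
            fp_rate_pct=fp_rate(confusion),
            sensitivity_pct=event_sensitivity(n_detected, n_seizures),
            mean_delay_s=float(np.mean(delays)) if delays else float("nan"),
            accuracy_pct=accuracy(confusion),
        )


@dataclass(frozen=True)
class EvalReport:
    """Per-case rows plus the pooled summary row.

    Pooled sensitivity uses summed counts (100 x total detected / total
    seizures); FP rate, delay and accuracy are means of the per-case values
    (delay averaged over cases that detected at least one seizure).
    """

    cases: tuple[CaseResult, ...]
    total_seizures: int
    total_detected: int
    pooled_sensitivity_pct: float
    mean_fp_rate_pct: float
    mean_delay_s: float
    mean_accuracy_pct: float

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "case": c.case_id,
                "n_seizures": c.n_seizures,
                "true_positive": c.n_detected,
                "fp_rate_pct": round2(c.fp_rate_pct),
                "sensitivity_pct": round2(c.sensitivity_pct),
                "delay_s": round2(c.mean_delay_s) if np.isfinite(c.mean_delay_s) else np.nan,
                "accuracy_pct": round2(c.accuracy_pct),
            }
            for c in self.cases
        ]
        rows.append(
            {
                "case": "pooled",
                "n_seizures": self.total_seizures,
                "true_positive": self.total_detected,
                "fp_rate_pct": round2(self.mean_fp_rate_pct),
                "sensitivity_pct": round2(self.pooled_sensitivity_pct),
                "delay_s": round2(self.mean_delay_s) if np.isfinite(self.mean_delay_s) else np.nan,
                "accuracy_pct": round2(self.mean_accuracy_pct),
            }
        )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        return path

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_dataframe().to_json(path, orient="records", indent=2)
        return path


def aggregate(per_case: Sequence[CaseResult]) -> EvalReport:
    """Pool per-case results into an :class:`EvalReport`."""
    if not per_case:
        raise ValueError("aggregate requires at least one case")
    total_seizures = sum(c.n_seizures for c in per_case)
    total_detected = sum(c.n_detected for c in per_case)
    delays = [c.mean_delay_s for c in per_case if np.isfinite(c.mean_delay_s)]
    return EvalReport(
        cases=tuple(per_case),
        total_seizures=total_seizures,
        total_detected=total_detected,
        pooled_sensitivity_pct=event_sensitivity(total_detected, total_seizures),
        mean_fp_rate_pct=float(np.mean([c.fp_rate_pct for c in per_case])),
        mean_delay_s=float(np.mean(delays)) if delays else float("nan"),
        mean_accuracy_pct=float(np.mean([c.accuracy_pct for c in per_case])),
    )
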
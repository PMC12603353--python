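"""Binary-classification metrics and the fragment-length benchmark harness.

Virulent is the positive class throughout (temperate is negative).  Metrics
with a zero denominator are reported as NaN together with an explicit flag,
never as a silent zero.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .sequence_io import ContigRecord, VIRULENT


@dataclass(frozen=True)
class ConfusionCounts:
    """tp/fp/tn/fn with virulent as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(
        cls, true_labels: Sequence[str], predicted_labels: Sequence[str]
    ) -> "ConfusionCounts":
        if len(true_labels) != len(predicted_labels):
            raise ValueError("label lists differ in length")
        tp = fp = tn = fn = 0
        for t, p in zip(true_labels, predicted_labels):
            if t == VIRULENT:
                tp, fn = tp + (p == VIRULENT), fn + (p != VIRULENT)
            else:
                tn, fp = tn + (p != VIRULENT), fp + (p == VIRULENT)
        return cls(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass
class MetricRow:
    accuracy: float
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    mcc: float
    undefined: tuple[str, ...] = ()
    fragment_length: Optional[int] = None
    holdout_mode: Optional[str] = None
    model: Optional[str] = None

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "holdout_mode": self.holdout_mode,
            "fragment_length": self.fragment_length,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
            "mcc": self.mcc,
        }


def _ratio(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return float("nan")
    return num / den


def metrics(c: ConfusionCounts, **context) -> MetricRow:
    """Standard binary metrics from a confusion matrix.

    Ratios with zero denominators (e.g. sensitivity with no positives) come
    back as NaN and are listed in ``undefined``.
    """
    undef: list[str] = []
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    sens = _ratio(tp, tp + fn, "sensitivity", undef)
    spec = _ratio(tn, tn + fp, "specificity", undef)
    acc = (tp + tn) / c.total
    bal = (sens + spec) / 2.0
    if math.isnan(bal):
        undef.append("balanced_accuracy")
    f1 = _ratio(2 * tp, 2 * tp + fp + fn, "f1", undef)
    mcc_den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        undef.append("mcc")
        mcc = float("nan")
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    return MetricRow(
        accuracy=acc, balanced_accuracy=bal, sensitivity=sens,
        specificity=spec, f1=f1, mcc=mcc, undefined=tuple(undef), **context,
    )


def benchmark(
    predictor: Callable[[ContigRecord], str],
    fragment_sets: dict[int, list[ContigRecord]],
    holdout_mode: str = "standard",
    model_name: Optional[str] = None,
) -> pd.DataFrame:
    """Score a contig-level predictor on simulated fragment sets.

    ``predictor`` maps a ContigRecord to a lifestyle label; fragments carry
    the truth in ``label``.  One MetricRow per fragment length, assembled
    into a tidy DataFrame sorted by length.
    """
    rows = []
    for length in sorted(fragment_sets):
        frags = fragment_sets[length]
        truths = [f.label for f in frags]
        if len(set(truths)) < 2:
            raise ValueError(f"fragment set at {length} bp has a single class")
        preds = [predictor(f) for f in frags]
        counts = ConfusionCounts.from_labels(truths, preds)
        rows.append(
            metrics(counts, fragment_length=length, holdout_mode=holdout_mode,
                    model=model_name).as_dict()
        )
    return pd.DataFrame(rows)


def render_benchmark_table(frame: pd.DataFrame) -> str:
    """Text table: rows = models, column groups = holdout mode, sections per length."""
    lines = []
    for length, sub in frame.groupby("fragment_length"):
        lines.append(f"{length} bp")
        pivot = sub.pivot_table(
            index="model",
            columns="holdout_mode",
            values=["accuracy", "balanced_accuracy", "mcc", "sensitivity", "specificity"],
            sort=False,
        )
        lines.append(pivot.round(3).to_string())
        lines.append("")
    return "\n".join(lines)


@dataclass
class SpeedReport:
    nucleotides_per_second: float
    elapsed_seconds: float
    total_bases: int
    n_records: int
    per_run_speeds: tuple[float, ...] = ()


def inference_speed(
    predictor: Callable[[Sequence[ContigRecord]], object],
    records: Sequence[ContigRecord],
    repeats: int = 1,
) -> SpeedReport:
    """End-to-end classification rate in nucleotides per second.

    The clock spans the whole call (preprocessing, inference, aggregation --
    whatever ``predictor`` does); speed = total input bases / elapsed time,
    counting each contig's bases once regardless of strand augmentation.
    With ``repeats`` > 1 the mean of the per-run speeds is reported.
    """
    if not records:
        raise ValueError("no records to time")
    total_bases = sum(len(r.seq) for r in records)
    speeds = []
    elapsed_total = 0.0
    for _ in range(repeats):
        t0 = time.perf_counter()
        predictor(records)
        elapsed = time.perf_counter() - t0
        if elapsed <= 0:
            raise RuntimeError("elapsed time below clock resolution")
        elapsed_total += elapsed
        speeds.append(total_bases / elapsed)
    return SpeedReport(
        nucleotides_per_second=float(np.mean(speeds)),
        elapsed_seconds=elapsed_total / repeats,
        total_bases=total_bases,
        n_records=len(records),
        per_run_speeds=tuple(speeds),
    )
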
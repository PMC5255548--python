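"""Segment-level diagnostic accuracy for reader studies.

Observers call each prostate segment cancer-positive or -negative; calls
are cross-tabulated against the histopathological gold standard into
TP/FP/FN/TN counts, from which sensitivity, specificity, PPV and NPV are
computed per observer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ContingencyTable",
    "DiagnosticMetrics",
    "SegmentScheme",
    "diagnostic_metrics",
    "metrics_table",
    "segments_from_labels",
    "PROSTATE_READER_STUDY",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 counts of observer calls against the gold standard."""

    tp: int
    fp: int
    fn: int
    tn: int
    observer_id: str = ""

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"{name}={v} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of printed clinical tables;
    Python's builtin ``round`` is half-to-even)."""
    if math.isnan(x):
        return x
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    observer_id: str = ""

    @property
    def rounded(self) -> "DiagnosticMetrics":
        return DiagnosticMetrics(
            sensitivity=round_half_away(self.sensitivity),
            specificity=round_half_away(self.specificity),
            ppv=round_half_away(self.ppv),
            npv=round_half_away(self.npv),
            observer_id=self.observer_id,
        )


def _ratio(num: int, den: int, name: str, observer: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined for observer {observer!r} (zero denominator)")
        return float("nan")
    return num / den


def diagnostic_metrics(ct: ContingencyTable) -> DiagnosticMetrics:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP),
    NPV TN/(TN+FN). Zero denominators yield NaN with a warning."""
    return DiagnosticMetrics(
        sensitivity=_ratio(ct.tp, ct.tp + ct.fn, "sensitivity", ct.observer_id),
        specificity=_ratio(ct.tn, ct.tn + ct.fp, "specificity", ct.observer_id),
        ppv=_ratio(ct.tp, ct.tp + ct.fp, "PPV", ct.observer_id),
        npv=_ratio(ct.tn, ct.tn + ct.fn, "NPV", ct.observer_id),
        observer_id=ct.observer_id,
    )


def metrics_table(cts) -> pd.DataFrame:
    """One row of rounded metrics per observer; CSV-writable."""
    cts = list(cts)
    if not cts:
        raise ValueError("no contingency tables given")
    rows = []
    for ct in cts:
        m = diagnostic_metrics(ct).rounded
        rows.append(
            {
                "observer": ct.observer_id,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "ppv": m.ppv,
                "npv": m.npv,
            }
        )
    return pd.DataFrame(rows)


def segments_from_labels(truth_labels, call_labels, observer_id: str = "") -> ContingencyTable:
    """Cross-tabulate per-segment binary calls against pathology truth."""
    truth = np.asarray(truth_labels).astype(bool)
    calls = np.asarray(call_labels).astype(bool)
    if truth.shape != calls.shape:
        raise ValueError(f"length mismatch: {truth.shape} truth vs {calls.shape} calls")
    return ContingencyTable(
        tp=int(np.sum(truth & calls)),
        fp=int(np.sum(~truth & calls)),
        fn=int(np.sum(truth & ~calls)),
        tn=int(np.sum(~truth & ~calls)),
        observer_id=observer_id,
    )


@dataclass(frozen=True)
class SegmentScheme:
    """Partition of the prostate into transversal planes and sectors.

    The published scheme totals 28 segments over 4 planes; the default
    sector counts below honor that total. Any plane/sector configuration
    is accepted — metric computations never enforce a total.
    """

    sectors_per_plane: tuple = (6, 8, 8, 6)

    @property
    def n_planes(self) -> int:
        return len(self.sectors_per_plane)

    @property
    def total_segments(self) -> int:
        return int(sum(self.sectors_per_plane))


# Per-observer contingency counts from the five-reader prostate study the
# color-fusion method was evaluated in (13 cases, segment-level calls vs
# histopathology). "gray" = conventional grayscale reading by the expert;
# "color" = reading of the fused color images.
PROSTATE_READER_STUDY = (
    ContingencyTable(tp=64, fp=19, fn=116, tn=217, observer_id="expert gray"),
    ContingencyTable(tp=35, fp=20, fn=145, tn=216, observer_id="radiologist 1 color"),
    ContingencyTable(tp=47, fp=24, fn=133, tn=212, observer_id="radiologist 2 color"),
    ContingencyTable(tp=27, fp=12, fn=153, tn=224, observer_id="radiologist 4 color"),
    ContingencyTable(tp=30, fp=10, fn=150, tn=226, observer_id="radiologist 5 color"),
    ContingencyTable(tp=37, fp=12, fn=143, tn=224, observer_id="trainee mean color"),
    ContingencyTable(tp=64, fp=21, fn=116, tn=215, observer_id="expert color"),
)
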
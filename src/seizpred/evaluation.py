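"""Segment-based evaluation: confusion matrices, percentage metrics,
false-prediction rate per interictal hour, and per-patient aggregation."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import Label

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "metrics",
    "fpr_per_hour",
    "aggregate",
]

_POSITIVE = Label.PREICTAL  # positive class for all metrics


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.fn + other.fn,
            self.tn + other.tn,
            self.fp + other.fp,
        )


@dataclass
class MetricsReport:
    """Percentages in [0, 100]; undefined ratios are NaN, never 0."""

    accuracy: float
    sensitivity: float
    specificity: float
    fpr_per_hour: float = math.nan
    patient_id: str = ""
    segment_seconds: float = math.nan
    model_name: str = ""
    transform: str = ""


def _as_positive(labels) -> np.ndarray:
    """Map labels to booleans (True = preictal/positive)."""
    out = np.empty(len(labels), dtype=bool)
    for i, lab in enumerate(labels):
        if isinstance(lab, Label):
            out[i] = lab is _POSITIVE
        elif isinstance(lab, str):
            out[i] = Label(lab) is _POSITIVE
        elif isinstance(lab, (bool, int, np.integer)):
            out[i] = bool(lab)
        else:
            raise TypeError(f"unsupported label type {type(lab)!r}")
    return out


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Tally a confusion matrix with preictal as the positive class.

    Labels may be :class:`~seizpred.segmentation.Label` members, the
    strings ``"preictal"``/``"interictal"``, or 0/1 integers (1 = preictal).
    """
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"length mismatch: {len(true_labels)} true vs "
            f"{len(predicted_labels)} predicted"
        )
    t = _as_positive(true_labels)
    p = _as_positive(predicted_labels)
    return ConfusionMatrix(
        tp=int(np.sum(t & p)),
        fn=int(np.sum(t & ~p)),
        tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)),
    )


def metrics(cm: ConfusionMatrix, **meta) -> MetricsReport:
    """accuracy = 100 (tp+tn)/total, sensitivity = 100 tp/(tp+fn),
    specificity = 100 tn/(tn+fp); empty denominators yield NaN."""
    if cm.total == 0:
        raise ValueError("cannot compute metrics from an all-zero confusion matrix")
    acc = 100.0 * (cm.tp + cm.tn) / cm.total
    sen = 100.0 * cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else math.nan
    spe = 100.0 * cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp else math.nan
    return MetricsReport(accuracy=acc, sensitivity=sen, specificity=spe, **meta)


def fpr_per_hour(fp_count: int, interictal_hours_evaluated: float) -> float:
    """False preictal alarms per interictal hour evaluated (no alarm
    clustering or refractory period)."""
    if fp_count < 0:
        raise ValueError("false-positive count must be non-negative")
    if interictal_hours_evaluated <= 0:
        raise ValueError("interictal hours evaluated must be positive")
    return fp_count / interictal_hours_evaluated


def interictal_hours(n_interictal_segments: int, segment_seconds: float) -> float:
    """Hours of interictal data represented by evaluated segments."""
    return n_interictal_segments * segment_seconds / 3600.0


@dataclass
class Summary:
    """Per-patient table plus an unweighted ``Average`` row and extremes."""

    table: pd.DataFrame  # per-patient rows + final "Average" row
    means: dict[str, float]  # full precision
    extremes: dict[str, dict[str, tuple[float, str]]]  # metric -> min/max

    def mean(self, metric: str) -> float:
        return self.means[metric]


_METRIC_COLS = ("accuracy", "sensitivity", "specificity", "fpr_per_hour")


def aggregate(reports: list[MetricsReport]) -> Summary:
    """Summarize per-patient reports: unweighted arithmetic mean per
    metric (NaNs excluded and counted), min/max with the patient attaining
    each.  Display rounding to two decimals happens only in the table."""
    if not reports:
        raise ValueError("need at least one report")
    seg_lengths = {r.segment_seconds for r in reports if not math.isnan(r.segment_seconds)}
    if len(seg_lengths) > 1:
        raise ValueError(f"mixed segment lengths in one summary: {sorted(seg_lengths)}")

    rows = [
        {
            "patient": r.patient_id,
            **{m: getattr(r, m) for m in _METRIC_COLS},
        }
        for r in reports
    ]
    df = pd.DataFrame(rows)
    means: dict[str, float] = {}
    extremes: dict[str, dict[str, tuple[float, str]]] = {}
    for m in _METRIC_COLS:
        vals = df[m].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        if ok.any():
            means[m] = float(vals[ok].mean())
            imin = int(np.nanargmin(vals))
            imax = int(np.nanargmax(vals))
            extremes[m] = {
                "min": (float(vals[imin]), str(df["patient"][imin])),
                "max": (float(vals[imax]), str(df["patient"][imax])),
            }
        else:
            means[m] = math.nan
            extremes[m] = {"min": (math.nan, ""), "max": (math.nan, "")}

    avg_row = {"patient": "Average", **{m: round(means[m], 2) for m in _METRIC_COLS}}
    display = df.copy()
    display[list(_METRIC_COLS)] = display[list(_METRIC_COLS)].round(2)
    table = pd.concat([display, pd.DataFrame([avg_row])], ignore_index=True)
    return Summary(table=table, means=means, extremes=extremes)
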
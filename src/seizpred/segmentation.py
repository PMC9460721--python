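"""Preictal/interictal period labeling, segment extraction and balancing.

Time conventions: seconds from record start, half-open intervals
``[start, end)``, 0-based sample indices.
"""

from __future__ import annotations

import csv
import enum
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from .eeg_io import EEGRecord, SeizureAnnotation

__all__ = [
    "Label",
    "PeriodInterval",
    "LabeledSegment",
    "label_periods",
    "extract_segments",
    "balance_classes",
    "write_manifest",
    "read_manifest",
]

log = logging.getLogger(__name__)

PREICTAL_MINUTES_DEFAULT = 15.0
INTERICTAL_MARGIN_HOURS_DEFAULT = 4.0


class Label(str, enum.Enum):
    PREICTAL = "preictal"
    INTERICTAL = "interictal"
    ICTAL = "ictal"
    POSTICTAL = "postictal"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class PeriodInterval:
    record_id: str
    start: float
    end: float
    label: Label

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class LabeledSegment:
    """Fixed-length multichannel window carrying its class label."""

    record_id: str
    start: float
    duration: float
    label: Label
    data: np.ndarray  # (n_channels, duration * fs)
    fs: float

    def __post_init__(self) -> None:
        if self.label not in (Label.PREICTAL, Label.INTERICTAL):
            raise ValueError(f"segments must be preictal/interictal, got {self.label}")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration * fs must be an integer sample count")
        if self.data.shape[1] != round(n):
            raise ValueError("data length does not match duration * fs")


def label_periods(
    record_duration: float,
    annotations: list[SeizureAnnotation],
    preictal_minutes: float = PREICTAL_MINUTES_DEFAULT,
    interictal_margin_hours: float = INTERICTAL_MARGIN_HOURS_DEFAULT,
    record_id: str | None = None,
) -> list[PeriodInterval]:
    """Partition ``[0, record_duration)`` into labeled periods.

    Rules, per seizure ``[t0, t1)``:

    * ictal: ``[t0, t1)``;
    * preictal: ``[t0 - 60*preictal_minutes, t0)`` clipped at 0 and
      truncated at any earlier seizure's offset;
    * interictal: every point at least ``interictal_margin_hours`` before
      every onset *and* the same margin after every offset;
    * everything else (postictal included) is excluded.

    When both preictal and interictal would claim a point (only possible
    with a margin shorter than the preictal length), precedence is
    ictal > preictal > interictal.
    """
    if record_duration < 0:
        raise ValueError("record duration must be non-negative")
    anns = sorted(annotations)
    rid = record_id if record_id is not None else (anns[0].record_id if anns else "")
    for a in anns:
        if a.offset > record_duration:
            raise ValueError(
                f"annotation [{a.onset}, {a.offset}) exceeds record duration "
                f"{record_duration}"
            )
    for prev, cur in zip(anns, anns[1:]):
        if cur.onset < prev.offset:
            raise ValueError("overlapping seizure annotations")

    pre_len = 60.0 * preictal_minutes
    margin = 3600.0 * interictal_margin_hours

    ictal = [(a.onset, a.offset) for a in anns]
    preictal = []
    for i, a in enumerate(anns):
        start = max(a.onset - pre_len, 0.0)
        for b in anns[:i]:
            start = max(start, b.offset)
        if start < a.onset:
            preictal.append((start, a.onset))

    # Interictal = complement of the union of margin zones around seizures.
    def is_interictal(lo: float, hi: float) -> bool:
        mid = 0.5 * (lo + hi)
        return all(mid <= a.onset - margin or mid >= a.offset + margin for a in anns)

    cuts = {0.0, record_duration}
    for a in anns:
        for t in (a.onset, a.offset, a.onset - margin, a.offset + margin):
            if 0.0 < t < record_duration:
                cuts.add(t)
    for s, e in preictal:
        for t in (s, e):
            if 0.0 < t < record_duration:
                cuts.add(t)
    bounds = sorted(cuts)

    def classify(lo: float, hi: float) -> Label:
        mid = 0.5 * (lo + hi)
        if any(s <= mid < e for s, e in ictal):
            return Label.ICTAL
        if any(s <= mid < e for s, e in preictal):
            return Label.PREICTAL
        if is_interictal(lo, hi):
            return Label.INTERICTAL
        return Label.EXCLUDED

    out: list[PeriodInterval] = []
    for lo, hi in zip(bounds, bounds[1:]):
        lab = classify(lo, hi)
        if out and out[-1].label is lab and out[-1].end == lo:
            out[-1] = PeriodInterval(rid, out[-1].start, hi, lab)
        else:
            out.append(PeriodInterval(rid, lo, hi, lab))
    return out


def extract_segments(
    record: EEGRecord,
    intervals: list[PeriodInterval],
    segment_seconds: float,
    overlap_seconds: float = 0.0,
) -> list[LabeledSegment]:
    """Tile preictal/interictal intervals into fixed-length segments.

    Windows start at each interval's start and advance by
    ``segment_seconds - overlap_seconds``; a trailing partial window is
    discarded.  Ictal/excluded intervals yield nothing.
    """
    if segment_seconds <= 0:
        raise ValueError("segment length must be positive")
    if not 0 <= overlap_seconds < segment_seconds:
        raise ValueError("overlap must satisfy 0 <= overlap < segment length")
    n_samp = segment_seconds * record.fs
    if abs(n_samp - round(n_samp)) > 1e-9:
        raise ValueError("segment_seconds * fs must be an integer sample count")
    n_samp = int(round(n_samp))
    step = segment_seconds - overlap_seconds

    segments: list[LabeledSegment] = []
    for iv in intervals:
        if iv.label not in (Label.PREICTAL, Label.INTERICTAL):
            continue
        start = iv.start
        while start + segment_seconds <= iv.end + 1e-9:
            i0 = int(round(start * record.fs))
            if i0 + n_samp > record.n_samples:
                break
            segments.append(
                LabeledSegment(
                    record_id=record.record_id,
                    start=start,
                    duration=segment_seconds,
                    label=iv.label,
                    data=record.data[:, i0 : i0 + n_samp],
                    fs=record.fs,
                )
            )
            start += step
    if not segments:
        log.warning(
            "no segments extracted from %d interval(s) at %.3gs window",
            len(intervals),
            segment_seconds,
        )
    return segments


def balance_classes(
    segments: list[LabeledSegment], seed: int
) -> list[LabeledSegment]:
    """Balance to a 1:1 class ratio.

    All preictal segments are kept; interictal segments are subsampled
    uniformly without replacement down to the preictal count.  If there are
    fewer interictal than preictal segments, all are kept and the imbalance
    is logged.  Deterministic for a given ``seed``.
    """
    pre = [s for s in segments if s.label is Label.PREICTAL]
    inter = [s for s in segments if s.label is Label.INTERICTAL]
    if not pre or not inter:
        missing = Label.PREICTAL if not pre else Label.INTERICTAL
        raise ValueError(f"cannot balance: no {missing.value} segments")
    if len(inter) <= len(pre):
        if len(inter) < len(pre):
            log.warning(
                "interictal (%d) < preictal (%d); keeping all interictal",
                len(inter),
                len(pre),
            )
        chosen = inter
    else:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(inter), size=len(pre), replace=False))
        chosen = [inter[i] for i in idx]
    out = pre + chosen
    out.sort(key=lambda s: (s.record_id, s.start, s.label.value))
    return out


def write_manifest(path: str | os.PathLike, segments: list[LabeledSegment]) -> None:
    """Write a segment manifest CSV: ``record_id,start_s,duration_s,label``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "start_s", "duration_s", "label"])
        for s in segments:
            writer.writerow([s.record_id, s.start, s.duration, s.label.value])


def read_manifest(path: str | os.PathLike) -> list[dict]:
    with open(path, newline="") as fh:
        return [
            {
                "record_id": row["record_id"],
                "start": float(row["start_s"]),
                "duration": float(row["duration_s"]),
                "label": Label(row["label"]),
            }
            for row in csv.DictReader(fh)
        ]
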
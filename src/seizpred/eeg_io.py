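"""EEG recording I/O: EDF files, seizure annotations and montage selection."""

from __future__ import annotations

import csv
import os
import re
from dataclasses import dataclass

import numpy as np
import yaml

from . import edf as _edf
from .edf import EDFError

__all__ = [
    "EEGRecord",
    "SeizureAnnotation",
    "MontageSpec",
    "CHBMIT_18",
    "ZJU4H_16",
    "canonicalize_label",
    "read_edf",
    "write_edf",
    "read_annotations",
    "write_annotations",
    "select_montage",
    "load_montage",
    "save_montage",
]

_SUFFIX_RE = re.compile(r"(-0|-REF)$")


def canonicalize_label(label: str) -> str:
    """Canonical channel name: uppercase, no whitespace, common suffixes
    (``-0``, ``-Ref``) removed."""
    lab = re.sub(r"\s+", "", label.upper())
    return _SUFFIX_RE.sub("", lab)


@dataclass
class EEGRecord:
    """One multichannel recording.

    ``data`` is ``(n_channels, n_samples)`` in microvolts; ``start_offset``
    is the record's start time in seconds on the patient timeline (0 when a
    record stands alone).
    """

    record_id: str
    data: np.ndarray
    fs: float
    channel_names: list[str]
    start_offset: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_channels, n_samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[1] < 1:
            raise ValueError("record must contain at least one sample")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_names)} channel names"
            )
        canon = [canonicalize_label(c) for c in self.channel_names]
        if len(set(canon)) != len(canon):
            raise ValueError("channel names are not unique after canonicalization")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs


@dataclass(frozen=True, order=True)
class SeizureAnnotation:
    """Onset/offset of one ictal event, in seconds from record start."""

    record_id: str
    onset: float
    offset: float

    def __post_init__(self) -> None:
        if not (0 <= self.onset < self.offset):
            raise ValueError(
                f"invalid annotation for {self.record_id!r}: "
                f"need 0 <= onset < offset, got [{self.onset}, {self.offset})"
            )


@dataclass(frozen=True)
class MontageSpec:
    """Ordered channel subset used as classifier input."""

    name: str
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        canon = tuple(canonicalize_label(c) for c in self.channels)
        if len(set(canon)) != len(canon):
            raise ValueError(f"montage {self.name!r} has duplicate channels")
        object.__setattr__(self, "channels", canon)

    @property
    def expected_count(self) -> int:
        return len(self.channels)


#: 18-channel bipolar montage shared by all CHB-MIT-style records.
CHBMIT_18 = MontageSpec(
    name="chbmit-18",
    channels=(
        "FP1-F7", "F7-T7", "T7-P7", "P7-O1",
        "FP1-F3", "F3-C3", "C3-P3", "P3-O1",
        "FP2-F4", "F4-C4", "C4-P4", "P4-O2",
        "FP2-F8", "F8-T8", "T8-P8", "P8-O2",
        "FZ-CZ", "CZ-PZ",
    ),
)

#: 16-channel referential montage (labels canonicalized from "Xx-Ref").
ZJU4H_16 = MontageSpec(
    name="zju4h-16",
    channels=(
        "FP1", "FP2", "F3", "F4", "C3", "C4", "P3", "P4",
        "O1", "O2", "F7", "F8", "T3", "T4", "T5", "T6",
    ),
)

_BUILTIN_MONTAGES = {m.name: m for m in (CHBMIT_18, ZJU4H_16)}


def get_montage(name: str) -> MontageSpec:
    try:
        return _BUILTIN_MONTAGES[name]
    except KeyError:
        raise KeyError(
            f"unknown montage {name!r}; available: {sorted(_BUILTIN_MONTAGES)}"
        ) from None


def read_edf(path: str | os.PathLike, record_id: str | None = None) -> EEGRecord:
    """Read an EDF/EDF+ file into an :class:`EEGRecord`.

    Channel labels are canonicalized; duplicate labels (after
    canonicalization) are resolved by keeping the first occurrence.
    """
    raw = _edf.read_edf_raw(path)
    seen: dict[str, int] = {}
    keep: list[int] = []
    names: list[str] = []
    for i, lab in enumerate(raw.labels):
        canon = canonicalize_label(lab)
        if canon in seen:
            continue
        seen[canon] = i
        keep.append(i)
        names.append(canon)
    rid = record_id
    if rid is None:
        rid = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return EEGRecord(
        record_id=rid,
        data=raw.data[keep],
        fs=raw.fs,
        channel_names=names,
    )


def write_edf(path: str | os.PathLike, record: EEGRecord) -> None:
    """Write a record as 16-bit EDF (used for fixtures and round-trips)."""
    _edf.write_edf_raw(
        path,
        record.data,
        record.fs,
        list(record.channel_names),
        recording_id=record.record_id,
    )


def read_annotations(path: str | os.PathLike) -> list[SeizureAnnotation]:
    """Read seizure annotations from a CSV with header
    ``record_id,onset_s,offset_s``; returns them sorted by (record, onset)
    and validated for non-overlap within each record."""
    anns: list[SeizureAnnotation] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or (lineno == 1 and row[0].strip() == "record_id"):
                continue
            if len(row) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(row)}")
            rid = row[0].strip()
            try:
                onset, offset = float(row[1]), float(row[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric onset/offset") from exc
            try:
                anns.append(SeizureAnnotation(rid, onset, offset))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    anns.sort()
    by_record: dict[str, SeizureAnnotation] = {}
    for ann in anns:
        prev = by_record.get(ann.record_id)
        if prev is not None and ann.onset < prev.offset:
            raise ValueError(
                f"overlapping annotations in record {ann.record_id!r}: "
                f"[{prev.onset}, {prev.offset}) and [{ann.onset}, {ann.offset})"
            )
        by_record[ann.record_id] = ann
    return anns


def write_annotations(path: str | os.PathLike, anns: list[SeizureAnnotation]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "onset_s", "offset_s"])
        for ann in sorted(anns):
            writer.writerow([ann.record_id, ann.onset, ann.offset])


def select_montage(record: EEGRecord, montage: MontageSpec) -> EEGRecord:
    """Reorder/subset a record to exactly the montage channels.

    Raises ``KeyError`` listing every missing channel; callers typically
    skip such records upstream.
    """
    index = {name: i for i, name in enumerate(record.channel_names)}
    missing = [c for c in montage.channels if c not in index]
    if missing:
        raise KeyError(
            f"record {record.record_id!r} is missing montage channels: "
            + ", ".join(missing)
        )
    rows = [index[c] for c in montage.channels]
    return EEGRecord(
        record_id=record.record_id,
        data=record.data[rows],
        fs=record.fs,
        channel_names=list(montage.channels),
        start_offset=record.start_offset,
    )


def load_montage(path: str | os.PathLike) -> MontageSpec:
    """Load a montage from a YAML/JSON mapping with ``name`` and ``channels``."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "channels" not in doc:
        raise ValueError(f"{path}: montage config needs 'name' and 'channels'")
    return MontageSpec(
        name=str(doc.get("name", "custom")),
        channels=tuple(str(c) for c in doc["channels"]),
    )


def save_montage(path: str | os.PathLike, montage: MontageSpec) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"name": montage.name, "channels": list(montage.channels)},
            fh,
            sort_keys=False,
        )
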
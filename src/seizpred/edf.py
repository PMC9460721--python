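"""Minimal EDF/EDF+ (continuous) reader and writer.

Only the subset of the format needed for multichannel EEG fixtures is
supported: 16-bit little-endian samples, identical sampling rate for every
signal, and a contiguous recording.  Physical scaling follows the standard
linear mapping between the digital and physical ranges declared in the
per-signal headers.
"""

from __future__ import annotations

import datetime as _dt
import math
import os
from dataclasses import dataclass

import numpy as np

__all__ = ["EDFError", "RawEDF", "read_edf_raw", "write_edf_raw"]

_DIG_MIN = -32768
_DIG_MAX = 32767


class EDFError(Exception):
    """Raised for malformed or unsupported EDF content."""


@dataclass
class RawEDF:
    """Decoded EDF payload before any label canonicalization."""

    labels: list[str]
    data: np.ndarray  # (n_signals, n_samples) float64, physical units
    fs: float  # Hz, common to all signals
    recording_id: str


def _field(raw: bytes, start: int, length: int) -> str:
    return raw[start : start + length].decode("ascii", errors="replace").strip()


def _fmt(value: object, length: int) -> bytes:
    s = str(value)
    if len(s) > length:
        raise EDFError(f"header field {s!r} exceeds {length} bytes")
    return s.ljust(length).encode("ascii")


def _fmt_float(value: float, length: int) -> bytes:
    """Fixed-width ASCII float; EDF allows at most 8 characters."""
    for ndig in range(length - 2, -1, -1):
        s = f"{value:.{ndig}f}"
        if len(s) <= length:
            return s.ljust(length).encode("ascii")
    raise EDFError(f"cannot format {value} in {length} chars")


def read_edf_raw(path: str | os.PathLike) -> RawEDF:
    """Read an EDF file; all signals must share one sampling rate.

    The EDF+ annotation channel (label ``EDF Annotations``), if present, is
    dropped.
    """
    path = os.fspath(path)
    try:
        with open(path, "rb") as fh:
            raw = fh.read()
    except OSError as exc:
        raise IOError(f"cannot read EDF file {path!r}: {exc}") from exc
    if len(raw) < 256:
        raise EDFError(f"{path!r}: truncated EDF header")

    try:
        n_records = int(_field(raw, 236, 8))
        record_dur = float(_field(raw, 244, 8))
        ns = int(_field(raw, 252, 4))
    except ValueError as exc:
        raise EDFError(f"{path!r}: malformed fixed header") from exc
    if ns <= 0:
        raise EDFError(f"{path!r}: EDF file declares no signals")
    recording_id = _field(raw, 88, 80)

    hdr_len = 256 + ns * 256
    if len(raw) < hdr_len:
        raise EDFError(f"{path!r}: truncated signal headers")

    # Per-signal header layout: label 16, transducer 80, dim 8, phys_min 8,
    # phys_max 8, dig_min 8, dig_max 8, prefilter 80, n_samp 8, reserved 32.
    offsets = {
        "label": (0, 16),
        "transducer": (16, 80),
        "dim": (96, 8),
        "phys_min": (104, 8),
        "phys_max": (112, 8),
        "dig_min": (120, 8),
        "dig_max": (128, 8),
        "prefilter": (136, 80),
        "n_samp": (216, 8),
    }

    def column(name: str) -> list[str]:
        off, width = offsets[name]
        base = 256 + off * ns
        return [_field(raw, base + i * width, width) for i in range(ns)]

    labels = column("label")
    phys_min = np.array([float(v) for v in column("phys_min")])
    phys_max = np.array([float(v) for v in column("phys_max")])
    dig_min = np.array([float(v) for v in column("dig_min")])
    dig_max = np.array([float(v) for v in column("dig_max")])
    n_samp = np.array([int(v) for v in column("n_samp")])

    keep = [i for i, lab in enumerate(labels) if lab.upper() != "EDF ANNOTATIONS"]
    if not keep:
        raise EDFError(f"{path!r}: EDF file contains no signal channels")
    if record_dur <= 0:
        raise EDFError(f"{path!r}: non-positive data record duration")
    if len(set(n_samp[keep])) > 1:
        raise EDFError(
            f"{path!r}: signals with differing sampling rates are unsupported"
        )

    spr = int(n_samp[keep[0]])
    fs = spr / record_dur
    payload = np.frombuffer(raw, dtype="<i2", offset=hdr_len)
    rec_len = int(n_samp.sum())
    if n_records < 0:  # -1 means "unknown" per the standard
        n_records = payload.size // rec_len
    if payload.size < n_records * rec_len:
        raise EDFError(f"{path!r}: data section shorter than declared")
    payload = payload[: n_records * rec_len].reshape(n_records, rec_len)

    starts = np.concatenate([[0], np.cumsum(n_samp)]).astype(int)
    data = np.empty((len(keep), n_records * spr), dtype=np.float64)
    for row, i in enumerate(keep):
        dig = payload[:, starts[i] : starts[i + 1]].reshape(-1).astype(np.float64)
        den = dig_max[i] - dig_min[i]
        if den == 0:
            raise EDFError(f"{path!r}: signal {labels[i]!r} has empty digital range")
        gain = (phys_max[i] - phys_min[i]) / den
        data[row] = (dig - dig_min[i]) * gain + phys_min[i]

    return RawEDF(
        labels=[labels[i] for i in keep],
        data=data,
        fs=fs,
        recording_id=recording_id,
    )


def write_edf_raw(
    path: str | os.PathLike,
    data: np.ndarray,
    fs: float,
    labels: list[str],
    recording_id: str = "",
) -> None:
    """Write ``data`` (n_signals x n_samples, physical units) as EDF.

    Uses 1-second data records when ``fs`` divides the sample count evenly,
    otherwise a single data record spanning the whole signal.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise EDFError("data must be a 2-D (n_signals, n_samples) array")
    ns, n_samples = data.shape
    if ns != len(labels):
        raise EDFError("one label per signal is required")
    if ns == 0 or n_samples == 0:
        raise EDFError("cannot write an empty EDF file")
    if not np.isfinite(data).all():
        raise EDFError("non-finite sample values")

    fs_int = fs == int(fs)
    if fs_int and n_samples % int(fs) == 0:
        spr = int(fs)
        n_records = n_samples // spr
        record_dur: float = 1.0
    else:
        spr = n_samples
        n_records = 1
        record_dur = n_samples / fs

    # Per-signal symmetric physical range so that 0 maps near digital 0.
    amax = np.maximum(np.abs(data).max(axis=1), 1e-6)
    phys_min = -amax
    phys_max = amax
    scale = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)
    dig = np.rint((data - phys_min[:, None]) * scale[:, None] + _DIG_MIN)
    dig = np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _fmt("0", 8),
            _fmt("X X X X", 80),
            _fmt(recording_id[:80], 80),
            _fmt(now.strftime("%d.%m.%y"), 8),
            _fmt(now.strftime("%H.%M.%S"), 8),
            _fmt(256 + ns * 256, 8),
            _fmt("", 44),
            _fmt(n_records, 8),
            _fmt_float(record_dur, 8),
            _fmt(ns, 4),
        ]
    )

    def col(values: list[bytes]) -> bytes:
        return b"".join(values)

    sig_header = b"".join(
        [
            col([_fmt(lab[:16], 16) for lab in labels]),
            col([_fmt("", 80)] * ns),
            col([_fmt("uV", 8)] * ns),
            col([_fmt_float(phys_min[i], 8) for i in range(ns)]),
            col([_fmt_float(phys_max[i], 8) for i in range(ns)]),
            col([_fmt(_DIG_MIN, 8)] * ns),
            col([_fmt(_DIG_MAX, 8)] * ns),
            col([_fmt("", 80)] * ns),
            col([_fmt(spr, 8)] * ns),
            col([_fmt("", 32)] * ns),
        ]
    )

    records = dig.reshape(ns, n_records, spr).transpose(1, 0, 2)
    try:
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(sig_header)
            fh.write(records.tobytes())
    except OSError as exc:
        raise IOError(f"cannot write EDF file {os.fspath(path)!r}: {exc}") from exc


def quantization_step(data: np.ndarray) -> np.ndarray:
    """Physical size of one digital step for each signal, as written."""
    amax = np.maximum(np.abs(np.asarray(data, dtype=float)).max(axis=1), 1e-6)
    return 2.0 * amax / (_DIG_MAX - _DIG_MIN)
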
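"""Synthetic annotated EEG: 1/f background plus controllable preictal and
ictal signatures, written as EDF fixtures readable by the regular I/O path.

The preictal signature is an additive low-frequency rhythm (or chirp)
confined to the 15 minutes before each seizure onset, so that the standard
0-50 Hz band limit retains it and a time-frequency classifier can separate
preictal from interictal segments by construction.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .eeg_io import (
    EEGRecord,
    MontageSpec,
    SeizureAnnotation,
    save_montage,
    write_annotations,
    write_edf,
)

__all__ = ["SyntheticSpec", "generate_record", "generate_dataset"]

log = logging.getLogger(__name__)

PREICTAL_SECONDS = 900.0


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic recording."""

    n_channels: int = 4
    fs: float = 256.0
    duration: float = 3600.0  # seconds
    seizure_times: tuple[tuple[float, float], ...] = ()
    beta: float = 1.0  # 1/f^beta background exponent
    sigma_bg: float = 1.0  # background amplitude (uV)
    rhythm_hz: float = 3.0
    amplitude_ratio: float = 4.0  # preictal rhythm amplitude / sigma_bg
    chirp: tuple[float, float] | None = None  # (f_start, f_end) overrides rhythm
    seed: int = 0
    record_id: str = "synth"

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.fs <= 0 or self.duration <= 0:
            raise ValueError("invalid channel count, sampling rate or duration")
        if not 0.5 <= self.beta <= 1.5:
            raise ValueError("beta must lie in [0.5, 1.5]")
        if not self.rhythm_hz < 50:
            raise ValueError("rhythm frequency must be below 50 Hz")
        if self.amplitude_ratio < 1:
            raise ValueError("amplitude ratio must be >= 1")
        times = sorted(self.seizure_times)
        for onset, offset in times:
            if not (0 <= onset < offset <= self.duration):
                raise ValueError(f"seizure [{onset}, {offset}) outside record")
        for (_, off1), (on2, _) in zip(times, times[1:]):
            if on2 < off1:
                raise ValueError("seizure intervals overlap")
        self.seizure_times = tuple(times)

    @property
    def channel_names(self) -> list[str]:
        return [f"CH{i + 1:02d}" for i in range(self.n_channels)]


def _pink_noise(rng: np.random.Generator, n: int, fs: float, beta: float) -> np.ndarray:
    """1/f^beta Gaussian noise with unit standard deviation."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(f)
    nz = f > 0
    shape[nz] = f[nz] ** (-beta / 2.0)
    shape[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_record(spec: SyntheticSpec) -> tuple[EEGRecord, list[SeizureAnnotation]]:
    """Deterministically generate one annotated multichannel record.

    Background: per-channel 1/f^beta noise scaled to ``sigma_bg``.
    Preictal windows ``[onset - 900, onset)`` (clipped at 0, truncated at a
    prior seizure's offset) receive an additive rhythm/chirp of amplitude
    ``amplitude_ratio * sigma_bg`` with random per-channel phase; ictal
    windows receive a stronger 4-12 Hz burst.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    data = np.empty((spec.n_channels, n))
    for ch in range(spec.n_channels):
        data[ch] = spec.sigma_bg * _pink_noise(rng, n, spec.fs, spec.beta)

    amp = spec.amplitude_ratio * spec.sigma_bg
    for i, (onset, offset) in enumerate(spec.seizure_times):
        start = max(onset - PREICTAL_SECONDS, 0.0)
        for prev_onset, prev_offset in spec.seizure_times[:i]:
            if prev_offset > start:
                start = prev_offset
                log.warning(
                    "preictal window before onset %.1f truncated at %.1f",
                    onset,
                    prev_offset,
                )
        i0, i1 = int(round(start * spec.fs)), int(round(onset * spec.fs))
        if i1 > i0:
            tw = t[i0:i1]
            for ch in range(spec.n_channels):
                phase = rng.uniform(0, 2 * np.pi)
                if spec.chirp is not None:
                    f0, f1 = spec.chirp
                    dur = tw[-1] - tw[0] + 1.0 / spec.fs
                    inst = f0 + (f1 - f0) * (tw - tw[0]) / dur
                    arg = 2 * np.pi * np.cumsum(inst) / spec.fs + phase
                else:
                    arg = 2 * np.pi * spec.rhythm_hz * tw + phase
                data[ch, i0:i1] += amp * np.sin(arg)

        j0, j1 = int(round(onset * spec.fs)), int(round(offset * spec.fs))
        for ch in range(spec.n_channels):
            burst_f = rng.uniform(4.0, 12.0)
            phase = rng.uniform(0, 2 * np.pi)
            data[ch, j0:j1] += (
                2.0 * amp * np.sin(2 * np.pi * burst_f * t[j0:j1] + phase)
            )

    record = EEGRecord(
        record_id=spec.record_id,
        data=data,
        fs=spec.fs,
        channel_names=spec.channel_names,
    )
    anns = [
        SeizureAnnotation(spec.record_id, onset, offset)
        for onset, offset in spec.seizure_times
    ]
    return record, anns


def generate_dataset(
    spec: SyntheticSpec,
    n_patients: int,
    out_dir: str | os.PathLike,
) -> dict:
    """Write a fixture tree: one EDF per patient, a shared annotation CSV
    and a montage config.

    Layout: ``<out_dir>/<patient>/<record>.edf``, ``<out_dir>/annotations.csv``,
    ``<out_dir>/montage.yaml``.  Patient seeds derive from ``spec.seed`` so
    distinct patients get distinct data.
    """
    if n_patients < 1:
        raise ValueError("need at least one patient")
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create fixture directory {out}: {exc}") from exc

    all_anns: list[SeizureAnnotation] = []
    patients: list[str] = []
    seeds = np.random.SeedSequence(spec.seed).spawn(n_patients)
    for i, ss in enumerate(seeds):
        patient = f"p{i + 1:02d}"
        record_id = f"{patient}r01"
        pspec = SyntheticSpec(
            n_channels=spec.n_channels,
            fs=spec.fs,
            duration=spec.duration,
            seizure_times=spec.seizure_times,
            beta=spec.beta,
            sigma_bg=spec.sigma_bg,
            rhythm_hz=spec.rhythm_hz,
            amplitude_ratio=spec.amplitude_ratio,
            chirp=spec.chirp,
            seed=int(ss.generate_state(1)[0]),
            record_id=record_id,
        )
        record, anns = generate_record(pspec)
        pdir = out / patient
        pdir.mkdir(exist_ok=True)
        write_edf(pdir / f"{record_id}.edf", record)
        all_anns.extend(anns)
        patients.append(patient)

    write_annotations(out / "annotations.csv", all_anns)
    montage = MontageSpec(name="synthetic", channels=tuple(spec.channel_names))
    save_montage(out / "montage.yaml", montage)
    return {
        "root": out,
        "patients": patients,
        "annotations": out / "annotations.csv",
        "montage": out / "montage.yaml",
    }
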
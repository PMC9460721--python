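"""End-to-end orchestration: read -> montage -> label -> extract ->
balance -> images -> k-fold cross-validation -> metrics, per patient."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import eeg_io, evaluation, mlf_cnn, segmentation, tf_image
from .segmentation import Label

__all__ = ["PipelineConfig", "run", "load_config", "build_patient_images"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    data_dir: str = "fixtures"
    annotations: str = "fixtures/annotations.csv"
    montage: str = "fixtures/montage.yaml"  # path or built-in montage name
    output_dir: str = "results"
    segment_seconds: float = 3.0
    overlap_seconds: float = 0.0
    transform: str = "swt"  # "swt" or "cwt"
    preictal_minutes: float = 15.0
    interictal_margin_hours: float = 4.0
    fmin: float = 0.5
    fmax: float = 50.0
    voices_per_octave: int = 8
    freq_bins: int = 128
    image_size: int = 128
    max_segments_per_class: int | None = None  # cap after balancing
    cv_folds: int = 5
    balance_seed: int = 0
    fold_seed: int = 0
    model: mlf_cnn.ModelConfig = field(default_factory=mlf_cnn.ModelConfig)

    def resolve_montage(self) -> eeg_io.MontageSpec:
        p = Path(self.montage)
        if p.exists():
            return eeg_io.load_montage(p)
        return eeg_io.get_montage(self.montage)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from YAML/JSON; the ``model`` key maps to
    :class:`~seizpred.mlf_cnn.ModelConfig` fields."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    model_doc = doc.pop("model", {})
    if "input_shape" in model_doc:
        model_doc["input_shape"] = tuple(model_doc["input_shape"])
    for key in ("block_convs", "block_widths", "fc_sizes", "dropout_rates"):
        if key in model_doc:
            model_doc[key] = tuple(model_doc[key])
    cfg = PipelineConfig(**doc)
    cfg.model = mlf_cnn.ModelConfig(**model_doc)
    return cfg


def _dump_config(cfg: PipelineConfig) -> dict:
    doc = dataclasses.asdict(cfg)
    doc["model"] = dataclasses.asdict(cfg.model)
    return doc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def discover_patients(data_dir: str | Path) -> dict[str, list[Path]]:
    """Map patient directory name -> sorted list of EDF paths."""
    root = Path(data_dir)
    patients: dict[str, list[Path]] = {}
    for pdir in sorted(p for p in root.iterdir() if p.is_dir()):
        edfs = sorted(pdir.glob("*.edf"))
        if edfs:
            patients[pdir.name] = edfs
    return patients


def build_patient_images(
    edf_paths: list[Path],
    annotations: list[eeg_io.SeizureAnnotation],
    montage: eeg_io.MontageSpec,
    cfg: PipelineConfig,
) -> list[tf_image.TFImage]:
    """Segments and time-frequency images for one patient's records."""
    segments: list[segmentation.LabeledSegment] = []
    for path in edf_paths:
        record = eeg_io.read_edf(path)
        record = eeg_io.select_montage(record, montage)
        anns = [a for a in annotations if a.record_id == record.record_id]
        intervals = segmentation.label_periods(
            record.duration,
            anns,
            preictal_minutes=cfg.preictal_minutes,
            interictal_margin_hours=cfg.interictal_margin_hours,
            record_id=record.record_id,
        )
        segments.extend(
            segmentation.extract_segments(
                record, intervals, cfg.segment_seconds, cfg.overlap_seconds
            )
        )
    if not segments:
        return []
    balanced = segmentation.balance_classes(segments, seed=cfg.balance_seed)
    if cfg.max_segments_per_class is not None:
        rng = np.random.default_rng(cfg.balance_seed + 1)
        out = []
        for lab in (Label.PREICTAL, Label.INTERICTAL):
            group = [s for s in balanced if s.label is lab]
            if len(group) > cfg.max_segments_per_class:
                idx = np.sort(
                    rng.choice(len(group), cfg.max_segments_per_class, replace=False)
                )
                group = [group[i] for i in idx]
            out.extend(group)
        balanced = out

    fs = segments[0].fs
    wavelet = tf_image.WaveletSpec()
    grid = tf_image.make_scale_grid(
        fs, cfg.fmin, cfg.fmax, cfg.voices_per_octave, wavelet=wavelet
    )
    return [
        tf_image.build_image(
            seg,
            wavelet,
            grid,
            cfg.freq_bins,
            transform=cfg.transform,
            fmin=cfg.fmin,
            fmax=cfg.fmax,
            out_size=cfg.image_size,
        )
        for seg in balanced
    ]


def run(cfg: PipelineConfig) -> dict:
    """Run the full pipeline; returns a manifest dict and writes
    ``results.csv`` (per patient + Average), ``folds.csv`` (per fold) and
    ``manifest.json`` under ``cfg.output_dir``.

    A failure in one patient is logged and does not stop the others;
    ``manifest["ok"]`` is True only if every patient completed.
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    montage = cfg.resolve_montage()
    annotations = eeg_io.read_annotations(cfg.annotations)
    patients = discover_patients(cfg.data_dir)
    if not patients:
        raise FileNotFoundError(f"no patient EDF directories under {cfg.data_dir!r}")

    fold_rows, reports, failures = [], [], {}
    input_hashes = {}
    for patient, edfs in patients.items():
        t0 = time.time()
        try:
            for p in edfs:
                input_hashes[str(p)] = _sha256(p)
            images = build_patient_images(edfs, annotations, montage, cfg)
            if not images:
                raise RuntimeError("no usable segments")
            n_ch = images[0].shape[-1]
            model_cfg = dataclasses.replace(
                cfg.model,
                input_shape=(cfg.image_size, cfg.image_size, n_ch),
            )
            folds = mlf_cnn.cross_validate(
                images, k=cfg.cv_folds, config=model_cfg, seed=cfg.fold_seed
            )
            pooled = evaluation.ConfusionMatrix()
            for fr in folds:
                pooled = pooled + fr.confusion
                m = evaluation.metrics(fr.confusion)
                fold_rows.append(
                    {
                        "patient": patient,
                        "fold": fr.fold,
                        "segment_s": cfg.segment_seconds,
                        "transform": cfg.transform,
                        "model": "mlf_cnn",
                        "accuracy": round(m.accuracy, 2),
                        "sensitivity": round(m.sensitivity, 2),
                        "specificity": round(m.specificity, 2),
                        "tp": fr.confusion.tp,
                        "fn": fr.confusion.fn,
                        "tn": fr.confusion.tn,
                        "fp": fr.confusion.fp,
                    }
                )
            hours = evaluation.interictal_hours(
                pooled.tn + pooled.fp, cfg.segment_seconds
            )
            report = evaluation.metrics(
                pooled,
                patient_id=patient,
                segment_seconds=cfg.segment_seconds,
                model_name="mlf_cnn",
                transform=cfg.transform,
            )
            report.fpr_per_hour = evaluation.fpr_per_hour(pooled.fp, hours)
            reports.append(report)
            log.info("patient %s done in %.1fs", patient, time.time() - t0)
        except Exception as exc:  # keep going with remaining patients
            log.error("patient %s failed: %s", patient, exc)
            failures[patient] = str(exc)

    if not reports:
        raise RuntimeError(f"every patient failed: {failures}")
    summary = evaluation.aggregate(reports)
    results = summary.table.copy()
    results.insert(1, "segment_s", cfg.segment_seconds)
    results.insert(2, "transform", cfg.transform)
    results.insert(3, "model", "mlf_cnn")
    results.to_csv(out_dir / "results.csv", index=False)
    pd.DataFrame(fold_rows).to_csv(out_dir / "folds.csv", index=False)

    manifest = {
        "ok": not failures,
        "failures": failures,
        "config": _dump_config(cfg),
        "input_hashes": input_hashes,
        "summary_means": summary.means,
        "results_csv": str(out_dir / "results.csv"),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
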
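"""End-to-end orchestration: normalize -> vesselness -> segment ->
quantify per exam, aggregation into a cohort table, and the two
statistics stages; plus run manifests for provenance.

Configuration defaults reproduce the reference settings of the method:
WM intensity target 110, Frangi alpha = beta = 0.5 and c = 2,
vesselness threshold 0.05, component size window 5-150 voxels.

A config may run in *stats-only* mode by pointing at a table of
precomputed per-exam measurements instead of images.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (
    BinaryMask3D,
    Volume3D,
    read_cohort_table,
    read_mask,
    read_volume,
    write_cohort_table,
    write_mask,
    write_volume,
)
from .normalization import WM_TARGET_DEFAULT, normalize_wm
from .segmentation import PVSMeasurement, SegmentationParams, quantify, segment_pvs
from .stats import (
    age_regression,
    build_paired_deltas,
    fit_full_model,
    flag_outliers,
    group_summaries,
    test_deltas,
)
from .vesselness import FrangiParams, frangi_vesselness

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Full run configuration; serializable to a flat YAML file."""

    norm_target: float = WM_TARGET_DEFAULT
    norm_method: str = "mask_mean"
    frangi: FrangiParams = field(default_factory=FrangiParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    #: per-exam entries: image, wm_mask, patient_id, tp, covariates
    manifest: list[dict] = field(default_factory=list)
    #: path to a precomputed measurement table (stats-only mode)
    measurements_table: str | None = None
    output_dir: str = "pvsq_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.frangi, Mapping):
            self.frangi = FrangiParams(**self.frangi)
        if isinstance(self.segmentation, Mapping):
            self.segmentation = SegmentationParams(**self.segmentation)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path


def process_exam(
    image: Volume3D,
    wm_mask: BinaryMask3D,
    config: PipelineConfig | None = None,
) -> tuple[PVSMeasurement, dict]:
    """Run the in-memory quantification chain on one exam.

    Returns the measurement and a dict with the intermediate artifacts
    (normalized volume, vesselness map, PVS mask, component table).
    """
    config = config or PipelineConfig()
    t0 = time.perf_counter()
    norm = normalize_wm(image, wm_mask, target=config.norm_target, method=config.norm_method)
    vess = frangi_vesselness(norm, config.frangi, roi=wm_mask)
    pvs_mask, components = segment_pvs(vess, wm_mask, config.segmentation)
    measurement = quantify(pvs_mask, wm_mask)
    logger.info(
        "exam processed in %.2fs: %d candidates, %d retained, ratio %.3f permil",
        time.perf_counter() - t0,
        len(components),
        int(components["retained"].sum()) if len(components) else 0,
        measurement.pvs_ratio_permil,
    )
    return measurement, {
        "normalized": norm,
        "vesselness": vess,
        "pvs_mask": pvs_mask,
        "components": components,
    }


def run_exam(config: PipelineConfig, entry: Mapping) -> dict:
    """Process one manifest entry from disk and write all artifacts.

    The entry needs ``image`` and ``wm_mask`` paths plus identifying
    covariates. Returns a one-row measurement record (dict) including
    artifact paths.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    image = read_volume(entry["image"])
    wm_mask = read_mask(entry["wm_mask"])
    measurement, artifacts = process_exam(image, wm_mask, config)
    stem = f"{entry.get('patient_id', 'exam')}_{entry.get('tp', 'NA')}"
    paths = {
        "normalized": out_dir / f"{stem}_norm.nii.gz",
        "vesselness": out_dir / f"{stem}_vesselness.nii.gz",
        "pvs_mask": out_dir / f"{stem}_pvs.nii.gz",
        "components": out_dir / f"{stem}_components.csv",
    }
    write_volume(artifacts["normalized"], paths["normalized"])
    write_volume(artifacts["vesselness"].as_volume(), paths["vesselness"])
    write_mask(artifacts["pvs_mask"], paths["pvs_mask"])
    artifacts["components"].to_csv(paths["components"], index=False)
    record = {
        k: entry.get(k)
        for k in ("patient_id", "tp", "age_years", "sex", "dose", "anesthesia", "shunt")
    }
    record.update(
        pvs_ratio_permil=measurement.pvs_ratio_permil,
        pvs_volume_cm3=measurement.pvs_volume_cm3,
        wm_volume_cm3=measurement.wm_volume_cm3,
        n_components=measurement.n_components,
        **{k: str(v) for k, v in paths.items()},
    )
    return record


def run_stats(table: pd.DataFrame, out_dir: Path) -> dict:
    """Full-model and paired-model reports over a measurement table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reports: dict = {}
    for response in ("pvs_ratio_permil", "pvs_volume_cm3"):
        fit = fit_full_model(table, response=response)
        slope, intercept, r = age_regression(table, response=response)
        reports[response] = {
            "coefficients": fit.coefficients.to_dict(),
            "std_errors": fit.std_errors.to_dict(),
            "p_values": {k: _jsonable(v) for k, v in fit.p_values.items()},
            "contrasts": fit.contrasts.to_dict(orient="records"),
            "random_intercept_variance": fit.random_intercept_variance,
            "residual_variance": fit.residual_variance,
            "n_obs": fit.n_obs,
            "n_patients": fit.n_patients,
            "method": fit.method,
            "age_slope": slope,
            "age_intercept": intercept,
            "age_r": r,
            "group_summaries": {
                by: group_summaries(table, by, response).to_dict(orient="records")
                for by in ("tp", "dose", "shunt", "anesthesia", "sex")
            },
        }
    deltas = build_paired_deltas(table)
    deltas.to_csv(out_dir / "paired_deltas.csv", index=False)
    tests = pd.concat(
        [
            test_deltas(deltas, response=resp).assign(response=resp)
            for resp in ("delta_ratio_permil", "delta_volume_cm3")
        ],
        ignore_index=True,
    ) if len(deltas) else pd.DataFrame()
    tests.to_csv(out_dir / "paired_tests.csv", index=False)
    with open(out_dir / "full_model.json", "w") as fh:
        json.dump(_jsonable(reports), fh, indent=2)
    reports["paired_deltas"] = deltas
    reports["paired_tests"] = tests
    return reports


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_cohort(config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """Process a whole manifest (or a precomputed table) and run the
    statistics stages.

    Per-exam failures are logged and skipped; the batch continues. QC
    outliers of the measured ratios are written to a review list, never
    silently dropped. Returns the cohort table and the stats reports.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.measurements_table:
        table = read_cohort_table(config.measurements_table)
    else:
        if not config.manifest:
            raise ValueError("manifest is empty and no measurements table was given")
        records = []
        failures = []
        for entry in config.manifest:
            try:
                records.append(run_exam(config, entry))
            except Exception as exc:  # noqa: BLE001 - batch keeps going
                failures.append({"entry": dict(entry), "error": str(exc)})
                logger.error("exam failed: %s (%s)", entry.get("image"), exc)
        if not records:
            raise RuntimeError(
                f"all {len(failures)} exams failed; first error: "
                f"{failures[0]['error'] if failures else 'n/a'}"
            )
        table = pd.DataFrame(records)
        if failures:
            with open(out_dir / "failures.json", "w") as fh:
                json.dump(failures, fh, indent=2)

    write_cohort_table(
        table[[c for c in table.columns if not str(c).endswith((".nii.gz", ".csv"))]],
        out_dir / "cohort_measurements.csv",
    )

    ratios = table["pvs_ratio_permil"].dropna().to_numpy(dtype=float)
    qc = flag_outliers(ratios, k=2.0, seed=config.seed) if len(ratios) >= 2 else None
    if qc is not None:
        with open(out_dir / "qc_review.json", "w") as fh:
            json.dump(
                {
                    "flagged_rows": qc.flagged,
                    "review_sample_rows": qc.review_sample,
                    "mean": qc.mean,
                    "sd": qc.sd,
                },
                fh,
                indent=2,
            )

    reports = run_stats(table, out_dir)

    manifest = {
        "pvsq_version": __version__,
        "config": _jsonable(config.to_dict()),
        "n_exams": int(len(table)),
        "outputs": sorted(str(p.name) for p in out_dir.iterdir() if p.is_file()),
    }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return table, reports
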
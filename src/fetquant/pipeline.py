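"""Per-patient and cohort orchestration.

`run_patient` composes the full quantification chain for one case —
background estimation, threshold segmentation, TBR metrics, optional
dynamic kinetics and optional PET–MRI Dice — into a
:class:`~fetquant.cohort_stats.PatientRecord` plus a provenance-carrying
JSON report (config hash, input checksums, package version).

`run_cohort` maps it over a manifest with continue-on-error semantics (a
corrupt input produces a per-patient failure entry, never aborts the batch)
and then runs the cohort statistics layer with per-analysis denominators.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_stats import (
    ContingencyTable,
    PatientRecord,
    chi_square,
    kruskal_wallis,
    mann_whitney_u,
    records_to_frame,
    summarize,
)
from .dynamic_kinetics import (
    KineticConfig,
    classify_tumour_kinetics,
    extract_slice_tacs,
    extract_tac,
    isocontour_roi,
)
from .imaging_io import FrameSchedule, read_dynamic, read_mask, read_volume
from .spatial_overlap import overlap_panel
from .static_quant import (
    SegmentationConfig,
    compute_uptake_metrics,
    estimate_background,
    segment_lesion,
    summation_image,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PatientEntry:
    """Input manifest entry for one patient (paths, pre-registered)."""

    patient_id: str
    histology: str
    who_grade: int
    background_mask: str
    pet: Optional[str] = None  # static SUV volume (20-40 min summation)
    dynamic: Optional[str] = None  # 4-D series
    schedule: Optional[str] = None  # frame schedule JSON/YAML
    flair: Optional[str] = None
    ce: Optional[str] = None
    seed_point: Optional[tuple[int, int, int]] = None


@dataclass
class RunConfig:
    """Batch configuration: manifest, analysis parameters and toggles."""

    patients: list[PatientEntry]
    output_dir: str = "fetquant_out"
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    kinetics: KineticConfig = field(default_factory=KineticConfig)
    run_static: bool = True
    run_dynamic: bool = True
    run_dice: bool = True
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        patients = [
            PatientEntry(
                **{
                    **p,
                    "seed_point": tuple(p["seed_point"]) if p.get("seed_point") else None,
                }
            )
            for p in raw.pop("patients")
        ]
        seg = SegmentationConfig(**raw.pop("segmentation", {}))
        kin = KineticConfig(**raw.pop("kinetics", {}))
        return cls(patients=patients, segmentation=seg, kinetics=kin, **raw)

    def to_dict(self) -> dict:
        return {
            "patients": [asdict(p) for p in self.patients],
            "output_dir": self.output_dir,
            "segmentation": asdict(self.segmentation),
            "kinetics": asdict(self.kinetics),
            "run_static": self.run_static,
            "run_dynamic": self.run_dynamic,
            "run_dice": self.run_dice,
            "seed": self.seed,
            "log_level": self.log_level,
        }

    def validate_paths(self) -> None:
        for p in self.patients:
            for attr in ("pet", "dynamic", "schedule", "flair", "ce", "background_mask"):
                v = getattr(p, attr)
                if v is not None and not Path(v).exists():
                    raise FileNotFoundError(f"{p.patient_id}: missing {attr} file {v}")

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_patient(config: RunConfig, entry: PatientEntry) -> tuple[PatientRecord, dict]:
    """Run all enabled stages for one patient.

    Returns the assembled record and a JSON-serializable report with
    per-stage outputs and provenance. Raises on any stage error; batch-level
    error isolation lives in :func:`run_cohort`.
    """
    report: dict = {
        "patient_id": entry.patient_id,
        "version": __version__,
        "config_hash": config.config_hash(),
        "inputs": {},
    }
    for attr in ("pet", "dynamic", "schedule", "flair", "ce", "background_mask"):
        v = getattr(entry, attr)
        if v is not None:
            report["inputs"][attr] = {"path": str(v), "sha256": _sha256(v)}

    schedule = FrameSchedule.from_file(entry.schedule) if entry.schedule else None
    series = read_dynamic(entry.dynamic, schedule) if entry.dynamic else None

    if entry.pet is not None:
        pet = read_volume(entry.pet)
    elif series is not None:
        pet = summation_image(series, 20, 40)
        report["pet_source"] = "summation 20-40 min of dynamic series"
    else:
        raise ValueError(f"{entry.patient_id}: neither static PET nor dynamic series given")

    bg_mask = read_mask(entry.background_mask, reference=pet, label="background_roi")
    background = estimate_background(pet, bg_mask)
    seg_cfg = config.segmentation
    if entry.seed_point is not None:
        seg_cfg = SegmentationConfig(
            threshold_factor=seg_cfg.threshold_factor,
            connectivity=seg_cfg.connectivity,
            min_component_ml=seg_cfg.min_component_ml,
            seed_point=entry.seed_point,
        )
    segmentation, threshold = segment_lesion(pet, background, seg_cfg)
    metrics = compute_uptake_metrics(
        pet, segmentation, background, threshold_suv=threshold
    )
    report["background"] = asdict(background)
    report["uptake"] = metrics.to_dict()

    curve_class = None
    ttp = None
    if config.run_dynamic and series is not None:
        summ_10_30 = summation_image(series, 10, 30)
        search = segmentation if not segmentation.is_empty else None
        roi = isocontour_roi(summ_10_30, config.kinetics.isocontour_fraction, search)
        whole = extract_tac(series, roi)
        slices = extract_slice_tacs(series, roi, config.kinetics.min_slice_voxels)
        if slices:
            kin = classify_tumour_kinetics(slices, whole, config.kinetics)
            curve_class = kin.curve_class
            ttp = kin.ttp_min
            report["kinetics"] = kin.to_dict()
        else:
            report["kinetics"] = {"skipped": "no slice has enough ROI voxels"}

    dice_flair = None
    dice_ce = None
    ce_present = entry.ce is not None
    if config.run_dice and entry.flair is not None:
        flair = read_mask(entry.flair, reference=pet, label="flair")
        ce = read_mask(entry.ce, reference=pet, label="ce") if entry.ce else None
        panel = overlap_panel(segmentation, flair, ce)
        dice_flair = panel["flair"].dice if panel["flair"].evaluable else None
        dice_ce = panel["ce"].dice if panel["ce"].evaluable else None
        report["dice"] = {k: v.to_dict() for k, v in panel.items()}

    record = PatientRecord(
        patient_id=entry.patient_id,
        histology=entry.histology,
        who_grade=int(entry.who_grade),
        ce_present=ce_present,
        pet_positive=metrics.pet_positive,
        tbr_max=max(1.0, metrics.tbr_max),
        tbr_mean=metrics.tbr_mean,
        pet_volume_ml=metrics.pet_volume_ml,
        curve_class=curve_class,
        ttp_min=ttp,
        dice_flair=dice_flair,
        dice_ce=dice_ce,
    )
    report["record"] = asdict(record)
    return record, report


def run_cohort(config: RunConfig) -> dict:
    """Run every patient, then the cohort statistics layer.

    Per-patient failures are collected in a failure ledger and never abort
    the batch; the statistics run on all successful records with explicit
    per-analysis denominators. Writes per-patient reports, summary CSVs and
    a JSON of all test results under ``config.output_dir``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    records: list[PatientRecord] = []
    failures: list[dict] = []
    for entry in config.patients:
        try:
            record, report = run_patient(config, entry)
        except Exception as exc:  # noqa: BLE001 — failure isolation by design
            log.error("patient %s failed: %s", entry.patient_id, exc)
            failures.append({"patient_id": entry.patient_id, "error": str(exc)})
            continue
        records.append(record)
        (outdir / f"{entry.patient_id}.json").write_text(json.dumps(report, indent=2))

    if not records:
        raise RuntimeError("no patient completed successfully")

    result = analyze_cohort(records)
    result["failures"] = failures
    df = records_to_frame(records)
    df.to_csv(outdir / "records.csv", index=False)
    for name, table in result["tables"].items():
        table.to_csv(outdir / f"table_{name}.csv", index=False)
    (outdir / "tests.json").write_text(
        json.dumps(
            {
                "tests": {k: v for k, v in result["tests"].items()},
                "skipped_tests": result["skipped_tests"],
                "failures": failures,
            },
            indent=2,
        )
    )
    result["records"] = records
    return result


def analyze_cohort(records: Sequence[PatientRecord]) -> dict:
    """Summary tables and the hypothesis-test battery over patient records.

    Tests that lack the data they need (a single stratum, no dynamic data)
    are skipped with a reason instead of erroring, so small cohorts still
    produce the summaries.
    """
    df = records_to_frame(records)
    tables = {
        "demographics": summarize(records, "histology", strata=("histology", "who_grade")),
        "tbr_max": summarize(records, "tbr_max"),
        "dice_ce": summarize(records, "dice_ce"),
        "dice_flair": summarize(records, "dice_flair"),
        "kinetics": summarize(records, "curve_class"),
        "ttp_min": summarize(records, "ttp_min"),
    }

    tests: dict[str, dict] = {}
    skipped: dict[str, str] = {}
    dyn = df.dropna(subset=["curve_class"])

    def _try(name, fn, reason_if_empty):
        try:
            tests[name] = fn().to_dict()
        except Exception as exc:  # degenerate table/sample
            skipped[name] = f"{reason_if_empty}: {exc}"

    if dyn["who_grade"].nunique() >= 2 and len(dyn) >= 4:
        _try(
            "kinetics_by_grade_chi2",
            lambda: chi_square(
                ContingencyTable.from_arrays(
                    dyn["who_grade"], dyn["curve_class"],
                    col_order=[c for c in ("increasing", "stable", "decreasing")
                               if c in set(dyn["curve_class"])],
                )
            ),
            "kinetics-by-grade chi-square not computable",
        )
    else:
        skipped["kinetics_by_grade_chi2"] = "needs dynamic data in >= 2 grades"

    if dyn["histology"].nunique() >= 2 and len(dyn) >= 4:
        _try(
            "kinetics_by_histology_chi2",
            lambda: chi_square(
                ContingencyTable.from_arrays(
                    dyn["histology"], dyn["curve_class"],
                    col_order=[c for c in ("increasing", "stable", "decreasing")
                               if c in set(dyn["curve_class"])],
                )
            ),
            "kinetics-by-histology chi-square not computable",
        )
    else:
        skipped["kinetics_by_histology_chi2"] = "needs dynamic data in both histologies"

    astro = df[(df.histology == "astrocytoma")]["tbr_max"].dropna()
    oligo = df[(df.histology == "oligodendroglioma")]["tbr_max"].dropna()
    if len(astro) >= 2 and len(oligo) >= 2:
        _try(
            "tbr_max_by_histology_mwu",
            lambda: mann_whitney_u(astro.to_numpy(), oligo.to_numpy()),
            "TBR_max Mann-Whitney not computable",
        )
    else:
        skipped["tbr_max_by_histology_mwu"] = "needs TBR_max in both histologies"

    ttp_astro = df[df.histology == "astrocytoma"].dropna(subset=["ttp_min"])
    groups = [g["ttp_min"].to_numpy() for _, g in ttp_astro.groupby("who_grade") if len(g) >= 2]
    if len(groups) >= 2:
        _try(
            "ttp_min_astro_by_grade_kw",
            lambda: kruskal_wallis(groups),
            "TTP_min Kruskal-Wallis not computable",
        )
    else:
        skipped["ttp_min_astro_by_grade_kw"] = "needs TTP_min in >= 2 astrocytoma grades"

    denominators = {
        "n_total": len(df),
        "n_pet_positive": int(df.pet_positive.sum()),
        "n_dynamic": int(df.curve_class.notna().sum()),
        "n_dice_flair": int(df.dice_flair.notna().sum()),
        "n_dice_ce": int(df.dice_ce.notna().sum()),
    }
    return {
        "tables": tables,
        "tests": tests,
        "skipped_tests": skipped,
        "denominators": denominators,
    }
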
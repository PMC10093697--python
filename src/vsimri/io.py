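"""File I/O, study configuration and the multi-subject pipeline runner.

Volumes travel as NIfTI-1 (4D series, 3D maps, uint8 masks) with a JSON
sidecar for the acquisition timing; summaries and statistics are CSV;
study configuration is YAML. ``run_subject`` persists one subject's maps
and ROI summary; ``run_study`` aggregates subjects and runs the per-
parameter group comparison across the three glioma subtypes.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .model import PipelineConfig, VesselSizeModel
from .preprocess import DualEchoSeries
from .stats import compare_groups

__all__ = [
    "SUBTYPES",
    "SubjectSpec",
    "StudyConfig",
    "save_volume",
    "load_volume",
    "save_series",
    "load_series",
    "save_phantom",
    "run_subject",
    "run_study",
]

logger = logging.getLogger("vsimri")

SUBTYPES = ("Oligo", "Astro", "GBM")

DEFAULT_AFFINE = np.diag([1.9, 1.9, 4.0, 1.0])  # voxel size in mm


def save_volume(path, data, affine=None, dtype=None) -> None:
    affine = DEFAULT_AFFINE if affine is None else affine
    arr = np.asarray(data)
    if dtype is not None:
        arr = arr.astype(dtype)
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_series(directory, series: DualEchoSeries, prefix: str = "") -> None:
    """Write both echoes plus a JSON timing sidecar into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_volume(directory / f"{prefix}gre.nii.gz", series.gre_signal)
    save_volume(directory / f"{prefix}se.nii.gz", series.se_signal)
    meta = {
        "tr": series.tr,
        "te_gre": series.te_gre,
        "te_se": series.te_se,
        "injection_index": series.injection_index,
    }
    (directory / f"{prefix}meta.json").write_text(json.dumps(meta, indent=2))


def load_series(gre_path, se_path, meta_path) -> DualEchoSeries:
    meta = json.loads(Path(meta_path).read_text())
    return DualEchoSeries(
        gre_signal=load_volume(gre_path),
        se_signal=load_volume(se_path),
        tr=float(meta["tr"]),
        te_gre=float(meta["te_gre"]),
        te_se=float(meta["te_se"]),
        injection_index=int(meta["injection_index"]),
    )


def save_phantom(directory, phantom) -> None:
    """Persist a phantom as the same file layout a subject uses."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_series(directory, DualEchoSeries.from_phantom(phantom))
    save_volume(directory / "adc.nii.gz", phantom.adc_map)
    save_volume(directory / "tumor_mask.nii.gz", phantom.tumor_mask, dtype=np.uint8)
    save_volume(directory / "nawm_mask.nii.gz", phantom.nawm_mask, dtype=np.uint8)
    for name, vol in phantom.truth_maps.items():
        save_volume(directory / f"truth_{name}.nii.gz", vol)
    phantom.truth_table().to_csv(directory / "truth_classes.csv", index=False)


@dataclass
class SubjectSpec:
    """Paths and subtype label for one subject."""

    subject_id: str
    subtype: str
    gre: str
    se: str
    meta: str
    adc: str
    tumor_mask: str
    nawm_mask: str

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise ValueError(
                f"subtype '{self.subtype}' not in {SUBTYPES}"
            )


@dataclass
class StudyConfig:
    """Study-level configuration: subjects, constants, seed."""

    subjects: list[SubjectSpec]
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        subjects = []
        for entry in raw.get("subjects", []):
            entry = dict(entry)
            for key in ("gre", "se", "meta", "adc", "tumor_mask", "nawm_mask"):
                entry[key] = str((base / entry[key]).resolve())
            subjects.append(SubjectSpec(**entry))
        pipeline = PipelineConfig(**raw.get("pipeline", {}))
        return cls(subjects=subjects, pipeline=pipeline, seed=int(raw.get("seed", 0)))


def run_subject(config: StudyConfig, subject: SubjectSpec, out_dir) -> pd.DataFrame:
    """Fit one subject and persist maps plus the ROI summary row.

    Writes CBV/uCBV/vessel-size/scaled-CBV NIfTI maps, the validity mask and
    ``roi_summary.csv``. Deterministic given the inputs; grid mismatches are
    hard errors raised before any output is written.
    """
    series = load_series(subject.gre, subject.se, subject.meta)
    model = VesselSizeModel(
        series=series,
        adc=load_volume(subject.adc),
        tumor_mask=load_volume(subject.tumor_mask) > 0,
        nawm_mask=load_volume(subject.nawm_mask) > 0,
        config=config.pipeline,
    )
    results = model.fit()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, vol in results.maps.as_dict().items():
        save_volume(out_dir / f"{name}.nii.gz", vol)
    save_volume(out_dir / "validity.nii.gz", results.validity.valid, dtype=np.uint8)
    save_volume(out_dir / "reason.nii.gz", results.validity.reason, dtype=np.uint8)
    roi = results.roi_summary().copy()
    roi.insert(0, "subject_id", subject.subject_id)
    roi.insert(1, "subtype", subject.subtype)
    roi.to_csv(out_dir / "roi_summary.csv", index=False)
    counts = results.validity.exclusion_counts()
    logger.info(
        "subject %s: window [%d, %d], valid voxels %d, exclusions %s",
        subject.subject_id,
        results.window.t0,
        results.window.t1,
        results.validity.n_valid,
        counts,
    )
    return roi


def run_study(config: StudyConfig, out_dir) -> pd.DataFrame:
    """Fit every subject, then compare subtypes per parameter and statistic.

    Writes per-subject outputs under ``out_dir/<subject_id>/``, the pooled
    summary table, and a group-statistics report shaped as
    parameter x statistic rows with the omnibus test, p-value and any
    significant pairwise results.
    """
    out_dir = Path(out_dir)
    summaries = [
        run_subject(config, subject, out_dir / subject.subject_id)
        for subject in config.subjects
    ]
    pooled = pd.concat(summaries, ignore_index=True)
    pooled.to_csv(out_dir / "subject_summaries.csv", index=False)

    counts = pooled.groupby("subtype")["subject_id"].nunique()
    if any(counts.get(s, 0) < 3 for s in SUBTYPES):
        warnings.warn(
            "fewer than 3 subjects in some subtype; group statistics skipped"
        )
        logger.warning("group statistics skipped: subtype counts %s", dict(counts))
        return pooled

    rows = []
    for parameter in pooled["parameter"].unique():
        for statistic in ("mean", "median", "hotspot"):
            sub = pooled[pooled["parameter"] == parameter]
            groups = {
                s: sub.loc[sub["subtype"] == s, statistic].to_numpy()
                for s in SUBTYPES
            }
            comparison = compare_groups(
                groups, alpha=config.pipeline.alpha, parameter=f"{parameter}:{statistic}"
            )
            row = {
                "parameter": parameter,
                "statistic": statistic,
                "omnibus_test": comparison.omnibus_test,
                "omnibus_statistic": comparison.statistic,
                "p_value": comparison.pvalue,
                "significant": comparison.significant,
            }
            for pw in comparison.pairwise:
                row[f"p_{pw.pair[0]}_vs_{pw.pair[1]}"] = pw.p_adjusted
            rows.append(row)
    report = pd.DataFrame(rows)
    report.to_csv(out_dir / "group_statistics.csv", index=False)
    return report
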
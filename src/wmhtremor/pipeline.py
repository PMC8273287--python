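"""End-to-end pipeline: simulate → segment → quantify → tremor → stats.

Each stage is a thin orchestration over the library modules; every run
writes a manifest (config, seed, package version) sufficient to reproduce
all outputs byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .segmentation import correct_bias_field, gm_intensity_stats, segment_wmh, wmh_threshold
from .stats import run_model_ledger
from .synthetic import SyntheticCohortConfig, SyntheticSubject, generate_cohort
from .tremor import DEFAULT_BAND_HZ, TremorRecording, tremor_measures
from .volumes import IntensityVolume, LabeledVolume, TissueLabels, write_volume
from .volumetry import (
    FazekasParams,
    assign_lesions_to_rois,
    fazekas_scores,
    merge_bilateral,
    roi_volumes,
)

log = logging.getLogger("wmhtremor")

__all__ = ["PipelineConfig", "run_all", "write_cohort", "load_recording", "write_recording"]


@dataclass
class PipelineConfig:
    """Knobs for the full pipeline (all defaults embedded in the manifest)."""

    seed: int = 0
    cohort: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)
    gm_quantile: float = 0.75
    min_cluster_voxels: int = 0
    bias_poly_order: int = 3
    tremor_band_hz: tuple[float, float] = DEFAULT_BAND_HZ
    tremor_window_s: float = 4.0
    tremor_overlap: float = 0.5
    alpha: float = 0.05
    t_variant: str = "pooled"
    roi_models_with_covariates: bool = False
    write_volumes: bool = False

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_kwargs = raw.pop("cohort", {})
        for key in ("grid_shape", "voxel_dims_mm"):
            if key in cohort_kwargs:
                cohort_kwargs[key] = tuple(cohort_kwargs[key])
        if "tremor_band_hz" in raw:
            raw["tremor_band_hz"] = tuple(raw["tremor_band_hz"])
        cfg = cls(**raw, cohort=SyntheticCohortConfig(**cohort_kwargs))
        if seed is not None:
            cfg = dataclasses.replace(
                cfg, seed=seed, cohort=dataclasses.replace(cfg.cohort, seed=seed)
            )
        return cfg

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["software_version"] = __version__
        return d


# ---------------------------------------------------------------------------
# recording / cohort file I/O


def write_recording(rec: TremorRecording, csv_path) -> None:
    """One column per channel, header row; sampling rate in a sidecar JSON."""
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rec.channels).to_csv(csv_path, index=False, float_format="%.6g")
    csv_path.with_suffix(".json").write_text(json.dumps({"fs_hz": rec.fs}, sort_keys=True))


def load_recording(csv_path) -> TremorRecording:
    csv_path = Path(csv_path)
    sidecar = csv_path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sampling-rate sidecar {sidecar}")
    fs = float(json.loads(sidecar.read_text())["fs_hz"])
    df = pd.read_csv(csv_path)
    return TremorRecording(channels={c: df[c].to_numpy() for c in df.columns}, fs=fs)


def write_cohort(subjects: list[SyntheticSubject], table: pd.DataFrame, out_dir) -> None:
    """Persist a simulated cohort: NIfTI volumes, recording CSVs, clinical CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "clinical.csv", index=False, float_format="%.6g")
    atlas_written = False
    for s in subjects:
        if s.intensity is not None:
            sdir = out / "volumes" / s.subject_id
            write_volume(s.intensity, sdir / "flair.nii.gz")
            write_volume(s.tissue, sdir / "tissue.nii.gz")
            write_volume(
                LabeledVolume(s.true_lesion_mask.astype(np.uint8), s.intensity.voxel_dims_mm),
                sdir / "lesions_truth.nii.gz",
            )
            if not atlas_written and s.atlas is not None:
                write_volume(s.atlas.volume, out / "atlas.nii.gz")
                s.atlas.write_meta(out / "atlas.json")
                atlas_written = True
        if s.recording is not None:
            write_recording(s.recording, out / "recordings" / f"{s.subject_id}.csv")


# ---------------------------------------------------------------------------
# full pipeline


def _measure_subject(subject: SyntheticSubject, config: PipelineConfig) -> dict:
    """Segment one subject's volume and quantify ROI volumes + Fazekas grades."""
    tissue = subject.tissue
    vol = subject.intensity
    # fit the field over normal-appearing WM; sigma-clipping drops lesions
    fit_mask = tissue.labels == TissueLabels.WM
    corrected = correct_bias_field(vol, fit_mask, poly_order=config.bias_poly_order)
    stats = gm_intensity_stats(corrected, tissue, quantile=config.gm_quantile)
    thr = wmh_threshold(stats)
    mask = segment_wmh(corrected, tissue, thr, min_cluster_voxels=config.min_cluster_voxels)

    counts = assign_lesions_to_rois(mask, subject.atlas)
    unassigned = counts.pop(0, 0)
    merged = merge_bilateral(counts, subject.atlas)
    vols = roi_volumes(merged, vol.voxel_dims_mm, unassigned_voxels=unassigned)
    fz = fazekas_scores(
        mask, tissue.labels == TissueLabels.VENTRICLE, vol.voxel_dims_mm, FazekasParams()
    )
    out = {
        "total_wmh_mm3": vols.total_wmh,
        "unassigned_wmh_mm3": vols.unassigned,
        "fazekas_pv": fz.periventricular_grade,
        "fazekas_dwm": fz.deep_grade,
    }
    for name, v in vols.per_roi.items():
        out[f"wmh_{name.replace(' ', '_')}_mm3"] = v
    return out


def run_all(config: PipelineConfig | None = None, out_dir=None) -> dict:
    """Run the whole study pipeline on a synthetic cohort.

    Stages: simulate → bias-correct → segment → quantify → Fazekas →
    tremor → stats.  Returns a report dict with the measured cohort table
    and the regression ledger; if ``out_dir`` is given, writes
    ``measured_cohort.csv``, ``ledger.csv``, ``ledger.json`` and
    ``manifest.json`` there.
    """
    config = config or PipelineConfig()
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)

    stage = "simulate"
    try:
        subjects, truth_table = generate_cohort(cohort_cfg)
        log.info("simulate: %d subjects", len(subjects))

        stage = "segment/quantify"
        rows = []
        for s in subjects:
            row = {
                "subject_id": s.subject_id,
                "group": s.group,
                "age": s.age,
                "disease_duration": s.disease_duration if s.disease_duration is not None else np.nan,
                "vascular_burden": s.vascular_burden,
                "moca": s.moca,
                "tetras_part2": s.tetras_part2 if s.tetras_part2 is not None else np.nan,
            }
            if s.intensity is not None:
                row.update(_measure_subject(s, config))
                row["true_wmh_mm3"] = s.true_lesion_volume_mm3
            else:
                truth_row = truth_table.loc[truth_table.subject_id == s.subject_id].iloc[0]
                for c in truth_table.columns:
                    if c.endswith("_mm3") or c.startswith("fazekas"):
                        row[c] = truth_row[c]

            if s.recording is not None:
                stage = "tremor"
                m = tremor_measures(
                    s.recording,
                    band_hz=config.tremor_band_hz,
                    window_s=config.tremor_window_s,
                    overlap=config.tremor_overlap,
                )
                row["mean_frequency"] = m.mean_frequency
                row["log_total_power"] = m.mean_log_total_power
                stage = "segment/quantify"
            else:
                row["mean_frequency"] = np.nan
                row["log_total_power"] = np.nan
            rows.append(row)
        measured = pd.DataFrame(rows)

        stage = "stats"
        outcomes = ["tetras_part2"]
        if measured.loc[measured.group == "ET", "mean_frequency"].notna().any():
            outcomes.append("mean_frequency")
        else:
            warnings.warn("no tremor recordings: frequency outcome omitted from the ledger")
        ledger = run_model_ledger(
            measured,
            alpha=config.alpha,
            outcomes=tuple(outcomes),
            include_covariates_in_roi_models=config.roi_models_with_covariates,
        )
        log.info(
            "stats: %d models per outcome, Bonferroni level %.4g",
            2 + ledger.n_rois,
            ledger.bonferroni_level,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc

    report = {
        "measured_cohort": measured,
        "ledger": ledger,
        "manifest": config.to_manifest(),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if config.write_volumes:
            write_cohort(subjects, truth_table, out / "cohort")
        measured.to_csv(out / "measured_cohort.csv", index=False, float_format="%.8g")
        ledger.table.to_csv(out / "ledger.csv", index=False, float_format="%.8g")
        (out / "ledger.json").write_text(
            json.dumps(
                {
                    "alpha": ledger.alpha,
                    "bonferroni_level": ledger.bonferroni_level,
                    "n_rois": ledger.n_rois,
                    "models": ledger.table.to_dict(orient="records"),
                },
                indent=2,
                sort_keys=True,
                default=float,
            )
        )
        (out / "manifest.json").write_text(
            json.dumps(config.to_manifest(), indent=2, sort_keys=True, default=str)
        )
    return report
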
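"""Atlas ROI lesion volumetry and a rule-based Fazekas surrogate.

Lesion voxels are assigned to discrete atlas labels (max-probability-map
style: each voxel carries one label), bilateral labels are merged into one
ROI per tract, and volumes are reported in mm³.  Lesion voxels falling on
atlas label 0 stay in the total and are reported as *unassigned* — the
whole-brain total is defined on the full mask, not on atlas coverage, so
per-ROI volumes plus the unassigned remainder always sum to the total
exactly.

The Fazekas scale (0–3 for periventricular and for deep white matter) is a
visual rating; :func:`fazekas_scores` is a deterministic *surrogate* that
encodes the scale's anatomy — caps/lining near the ventricles, punctate
versus confluent deep foci — as explicit distance and size cutoffs.  It is
not calibrated against human raters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure

from .volumes import LabeledVolume

__all__ = [
    "AtlasVolume",
    "ROIVolumeTable",
    "FazekasParams",
    "FazekasResult",
    "assign_lesions_to_rois",
    "merge_bilateral",
    "roi_volumes",
    "fazekas_scores",
]


@dataclass
class AtlasVolume:
    """Discrete label volume plus label metadata.

    ``laterality`` maps every nonzero id to ``"left"``, ``"right"`` or
    ``"midline"``; ``pairing`` maps each left id to its right homologue
    (a bijection on the left/right ids).
    """

    volume: LabeledVolume
    label_names: dict[int, str]
    laterality: dict[int, str]
    pairing: dict[int, int]

    def __post_init__(self) -> None:
        ids = set(np.unique(self.volume.labels)) - {0}
        for i in ids:
            if int(i) not in self.label_names:
                raise ValueError(f"atlas label {i} has no name")
            if int(i) not in self.laterality:
                raise ValueError(f"atlas label {i} has no laterality")
        lefts = {i for i, s in self.laterality.items() if s == "left"}
        rights = {i for i, s in self.laterality.items() if s == "right"}
        if set(self.pairing.keys()) != lefts or set(self.pairing.values()) != rights:
            raise ValueError("pairing must be a bijection between left and right ids")
        if len(set(self.pairing.values())) != len(self.pairing):
            raise ValueError("pairing must be a bijection between left and right ids")

    def merged_name(self, label_id: int) -> str:
        """ROI name with the laterality token stripped (for merged tables)."""
        name = self.label_names[label_id]
        tokens = [t for t in name.split() if t.lower() not in {"left", "right", "l", "r"}]
        return " ".join(tokens) if tokens else name

    @property
    def merged_roi_names(self) -> list[str]:
        """Merged ROI names: one per bilateral pair plus each midline label."""
        names: list[str] = []
        for left_id in sorted(self.pairing):
            names.append(self.merged_name(left_id))
        for i in sorted(self.laterality):
            if self.laterality[i] == "midline":
                names.append(self.label_names[i])
        return names

    @classmethod
    def from_files(cls, labels_path, meta_path) -> "AtlasVolume":
        """Load a NIfTI label volume with its sidecar JSON metadata."""
        from .volumes import read_volume

        vol = read_volume(labels_path, kind="labels")
        meta = json.loads(Path(meta_path).read_text())
        return cls(
            volume=vol,
            label_names={int(k): v for k, v in meta["label_names"].items()},
            laterality={int(k): v for k, v in meta["laterality"].items()},
            pairing={int(k): int(v) for k, v in meta["pairing"].items()},
        )

    def write_meta(self, meta_path) -> None:
        meta = {
            "label_names": {str(k): v for k, v in self.label_names.items()},
            "laterality": {str(k): v for k, v in self.laterality.items()},
            "pairing": {str(k): int(v) for k, v in self.pairing.items()},
        }
        Path(meta_path).write_text(json.dumps(meta, indent=2))


def assign_lesions_to_rois(mask: np.ndarray, atlas: AtlasVolume) -> dict[int, int]:
    """Per-label lesion voxel counts; key 0 counts unassigned lesion voxels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != atlas.volume.grid_shape:
        raise ValueError("lesion mask and atlas grids are not aligned")
    counts = {0: 0}
    counts.update({int(i): 0 for i in atlas.label_names})
    labels_at_lesions = atlas.volume.labels[mask]
    ids, n = np.unique(labels_at_lesions, return_counts=True)
    for i, c in zip(ids, n):
        counts[int(i)] = int(c)
    return counts


def merge_bilateral(counts, atlas: AtlasVolume) -> dict[str, int]:
    """Sum left+right counts into one merged ROI; midline labels pass through.

    Idempotent: a table already keyed by merged ROI names is returned as-is.
    """
    if all(isinstance(k, str) for k in counts):
        return dict(counts)
    merged: dict[str, int] = {}
    for left_id in sorted(atlas.pairing):
        right_id = atlas.pairing[left_id]
        merged[atlas.merged_name(left_id)] = int(counts.get(left_id, 0)) + int(
            counts.get(right_id, 0)
        )
    for i in sorted(atlas.laterality):
        if atlas.laterality[i] == "midline":
            merged[atlas.label_names[i]] = int(counts.get(i, 0))
    for i in counts:
        if i != 0 and int(i) not in atlas.laterality:
            raise KeyError(f"label {i} present in counts but missing from laterality map")
    return merged


@dataclass
class ROIVolumeTable:
    """Merged per-ROI WMH volumes in mm³ plus the unassigned remainder.

    Invariant (exact, not approximate): ``sum(per_roi.values()) + unassigned
    == total_wmh`` — the total is defined as that sum.
    """

    per_roi: dict[str, float]
    unassigned: float
    total_wmh: float = field(init=False)

    def __post_init__(self) -> None:
        if self.unassigned < 0 or any(v < 0 for v in self.per_roi.values()):
            raise ValueError("volumes must be non-negative")
        self.total_wmh = sum(self.per_roi.values()) + self.unassigned


def roi_volumes(
    merged_counts: dict[str, int],
    voxel_dims_mm,
    unassigned_voxels: int = 0,
) -> ROIVolumeTable:
    """Convert merged voxel counts into mm³ volumes (count × voxel volume)."""
    dx, dy, dz = (float(d) for d in voxel_dims_mm)
    if dx <= 0 or dy <= 0 or dz <= 0:
        raise ValueError("voxel dimensions must be positive")
    vv = dx * dy * dz
    per_roi = {name: count * vv for name, count in merged_counts.items()}
    return ROIVolumeTable(per_roi=per_roi, unassigned=unassigned_voxels * vv)


@dataclass(frozen=True)
class FazekasParams:
    """Cutoffs for the deterministic Fazekas surrogate.

    ``pv_distance_mm``: lesion voxels within this Euclidean distance of the
    ventricles count as periventricular (default 3 mm).  PV grade thresholds
    are volumes in mm³ (caps vs halo vs confluent); deep-grade thresholds are
    component sizes in voxels (punctate vs early-confluent vs confluent).
    """

    pv_distance_mm: float = 3.0
    v_cap_mm3: float = 200.0
    v_halo_mm3: float = 1000.0
    c_punctate_voxels: int = 50
    c_confluent_voxels: int = 500


@dataclass(frozen=True)
class FazekasResult:
    periventricular_grade: int
    deep_grade: int

    def __post_init__(self) -> None:
        for g in (self.periventricular_grade, self.deep_grade):
            if g not in (0, 1, 2, 3):
                raise ValueError("Fazekas grades lie in {0,1,2,3}")


def fazekas_scores(
    mask: np.ndarray,
    ventricle_mask: np.ndarray,
    voxel_dims_mm,
    params: FazekasParams | None = None,
) -> FazekasResult:
    """Rule-based periventricular / deep white-matter grades (0–3 each).

    Lesion voxels within ``pv_distance_mm`` of the ventricle mask (Euclidean
    distance transform with physical voxel spacing) are periventricular; the
    rest are deep.  The voxel-wise partition makes both grades monotone
    non-decreasing under lesion dilation.  PV grade from total PV volume
    (0 none, 1 ≤ caps, 2 ≤ halo, 3 confluent); deep grade from the largest
    26-connected deep component (0 none, 1 punctate, 2 early confluent,
    3 confluent).
    """
    params = params or FazekasParams()
    mask = np.asarray(mask, dtype=bool)
    vent = np.asarray(ventricle_mask, dtype=bool)
    if mask.shape != vent.shape:
        raise ValueError("lesion and ventricle masks are not aligned")
    if not vent.any():
        raise ValueError("empty ventricle mask: periventricular/deep partition undefined")

    dx, dy, dz = (float(d) for d in voxel_dims_mm)
    vv = dx * dy * dz
    dist = ndimage.distance_transform_edt(~vent, sampling=(dx, dy, dz))
    pv_zone = dist <= params.pv_distance_mm

    pv_voxels = mask & pv_zone
    deep_voxels = mask & ~pv_zone

    pv_volume = pv_voxels.sum() * vv
    if pv_volume == 0:
        pv_grade = 0
    elif pv_volume <= params.v_cap_mm3:
        pv_grade = 1
    elif pv_volume <= params.v_halo_mm3:
        pv_grade = 2
    else:
        pv_grade = 3

    if not deep_voxels.any():
        deep_grade = 0
    else:
        comp = measure.label(deep_voxels, connectivity=3)
        largest = int(np.bincount(comp.ravel())[1:].max())
        if largest < params.c_punctate_voxels:
            deep_grade = 1
        elif largest < params.c_confluent_voxels:
            deep_grade = 2
        else:
            deep_grade = 3

    return FazekasResult(periventricular_grade=pv_grade, deep_grade=deep_grade)
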
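"""Core volume containers and NIfTI-1 input/output.

All grids in this package are plain 3D numpy arrays indexed ``[i, j, k]``
(0-based voxel indices).  Physical quantities are derived exclusively from
``voxel_dims_mm``; affines are carried through untouched because inputs are
co-registered by contract — no resampling happens anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "IntensityVolume",
    "LabeledVolume",
    "TissueLabels",
    "read_volume",
    "write_volume",
]


class TissueLabels:
    """Integer codes used by the synthetic tissue segmentation."""

    BACKGROUND = 0
    CSF = 1
    GM = 2
    WM = 3
    VENTRICLE = 4


def _check_dims(voxel_dims_mm) -> tuple[float, float, float]:
    dims = tuple(float(d) for d in voxel_dims_mm)
    if len(dims) != 3 or any(d <= 0 for d in dims):
        raise ValueError(f"voxel_dims_mm must be 3 positive reals, got {voxel_dims_mm!r}")
    return dims


@dataclass
class IntensityVolume:
    """A 3D real-valued grid (FLAIR-like intensities) with voxel size in mm."""

    values: np.ndarray
    voxel_dims_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensity volume contains non-finite voxels")
        self.voxel_dims_mm = _check_dims(self.voxel_dims_mm)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_dims_mm
        return dx * dy * dz


@dataclass
class LabeledVolume:
    """A 3D integer label grid (tissue classes or atlas regions)."""

    labels: np.ndarray
    voxel_dims_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            as_float = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(as_float)) or not np.all(as_float == np.round(as_float)):
                raise ValueError("label volume contains non-integer values")
            arr = as_float.astype(np.int32)
        self.labels = arr
        self.voxel_dims_mm = _check_dims(self.voxel_dims_mm)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_dims_mm
        return dx * dy * dz

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


def read_volume(path, kind: str = "intensity"):
    """Read a 3D NIfTI-1 volume.

    Parameters
    ----------
    path : str or Path
        NIfTI file (.nii or .nii.gz).
    kind : {"intensity", "labels"}
        Container to return.  ``"labels"`` requires integer-valued voxels.

    Voxel dimensions are taken from the header zooms; the affine is carried
    through for round-tripping but never used for resampling.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D data")
    dims = tuple(float(z) for z in img.header.get_zooms()[:3])
    if kind == "intensity":
        return IntensityVolume(np.asarray(data, dtype=float), dims, affine=img.affine)
    if kind == "labels":
        return LabeledVolume(data, dims, affine=img.affine)
    raise ValueError(f"unknown kind {kind!r}")


def write_volume(vol, path) -> None:
    """Write an :class:`IntensityVolume` or :class:`LabeledVolume` as NIfTI-1."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(vol, IntensityVolume):
        data = np.asarray(vol.values, dtype=np.float64)
    elif isinstance(vol, LabeledVolume):
        data = np.asarray(vol.labels, dtype=np.int32)
    else:
        raise TypeError(f"cannot write {type(vol).__name__}")
    affine = vol.affine
    if affine is None:
        affine = np.diag(list(vol.voxel_dims_mm) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(vol.voxel_dims_mm)
    nib.save(img, str(path))
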
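"""FLAIR-like WMH segmentation by gray-matter quantile thresholding.

White-matter hyperintensities (WMH) appear brighter than gray matter on
FLAIR.  The automated detector implemented here (1) removes a smooth
multiplicative bias field, (2) summarizes the gray-matter intensity
distribution, (3) takes the upper quartile (the "first upper quantile") of
gray-matter intensities as the lesion threshold, and (4) marks every
white-matter voxel strictly above that threshold, optionally discarding
small 26-connected clusters.

Conventions (documented because they change results at the margin):

* percentile: linear interpolation between order statistics
  (``numpy.percentile`` default);
* SD: population convention (``ddof=0``);
* mask membership: strict inequality ``intensity > threshold`` — tie voxels
  are excluded;
* connectivity for cluster filtering: 26-neighborhood.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .volumes import IntensityVolume, LabeledVolume, TissueLabels

__all__ = [
    "GMIntensityStats",
    "correct_bias_field",
    "gm_intensity_stats",
    "wmh_threshold",
    "segment_wmh",
]


@dataclass(frozen=True)
class GMIntensityStats:
    """Summary of FLAIR intensities at gray-matter voxels."""

    mean: float
    sd: float
    q3: float  # 75th percentile, linear interpolation
    n_voxels: int

    def __post_init__(self) -> None:
        if self.n_voxels <= 0:
            raise ValueError("GM statistics require at least one voxel")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def _poly_design(coords: np.ndarray, order: int) -> np.ndarray:
    """Monomial design matrix of total degree <= order on [-1, 1]^3 coords."""
    cols = []
    x, y, z = coords.T
    for i, j, k in itertools.product(range(order + 1), repeat=3):
        if i + j + k <= order:
            cols.append((x**i) * (y**j) * (z**k))
    return np.column_stack(cols)


def correct_bias_field(
    vol: IntensityVolume,
    brain_mask: np.ndarray,
    poly_order: int = 3,
    robust_iters: int = 3,
    clip_sigma: float = 2.0,
) -> IntensityVolume:
    """Divide out a smooth multiplicative bias field.

    A polynomial of total degree ``poly_order`` is least-squares fitted to
    the log-intensities inside ``brain_mask`` and exponentiated into a
    multiplicative field; the volume is divided by it and rescaled so the
    mean intensity within the mask is unchanged.  ``robust_iters`` rounds of
    one-sided sigma-clipping (residuals more than ``clip_sigma`` SDs *above*
    the fit are dropped) keep bright lesions from bending the field toward
    themselves; hyperintensities only ever push residuals up, so the lower
    tail is left alone.

    The fit cannot distinguish bias from the smooth component of true
    anatomy, so the mask should cover tissue of roughly uniform intensity —
    the pipeline fits over normal-appearing WM and lets the clipping drop
    hyperintense voxels.  A degenerate fit (constant intensities in the
    mask) returns the input unchanged with a warning.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if mask.shape != vol.grid_shape:
        raise ValueError("brain_mask shape does not match volume")
    if not mask.any():
        raise ValueError("brain_mask is empty")
    if poly_order < 0:
        raise ValueError("poly_order must be >= 0")

    values = vol.values
    inside = values[mask]
    if np.min(inside) <= 0:
        raise ValueError("bias correction requires positive intensities in the mask")
    log_in = np.log(inside)
    if np.ptp(log_in) < 1e-12:
        warnings.warn("degenerate bias fit (constant intensities); returning input unchanged")
        return IntensityVolume(values.copy(), vol.voxel_dims_mm, affine=vol.affine)

    shape = vol.grid_shape
    axes = [np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(n) for n in shape]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)  # (nx,ny,nz,3)
    coords_in = grid[mask]
    design_in = _poly_design(coords_in, poly_order)
    keep = np.ones(log_in.size, dtype=bool)
    coef, *_ = np.linalg.lstsq(design_in, log_in, rcond=None)
    for _ in range(max(robust_iters, 0)):
        resid = log_in - design_in @ coef
        sd = resid[keep].std()
        if sd < 1e-12:
            break
        new_keep = (resid - resid[keep].mean()) <= clip_sigma * sd
        if new_keep.sum() < design_in.shape[1]:
            break
        keep = new_keep
        coef, *_ = np.linalg.lstsq(design_in[keep], log_in[keep], rcond=None)

    design_all = _poly_design(grid.reshape(-1, 3), poly_order)
    log_field = (design_all @ coef).reshape(shape)
    log_field -= log_field[mask].mean()  # unit geometric mean within mask
    field = np.exp(log_field)

    corrected = values / field
    corrected *= inside.mean() / corrected[mask].mean()
    return IntensityVolume(corrected, vol.voxel_dims_mm, affine=vol.affine)


def gm_intensity_stats(
    vol: IntensityVolume,
    tissue: LabeledVolume,
    gm_label: int = TissueLabels.GM,
    quantile: float = 0.75,
) -> GMIntensityStats:
    """Mean, population SD and upper quantile of GM-labeled intensities.

    Raises if no voxel carries ``gm_label`` — that signals a segmentation or
    registration failure upstream, not an empty result.
    """
    if vol.grid_shape != tissue.grid_shape:
        raise ValueError("intensity and tissue grids are not aligned")
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    gm = vol.values[tissue.labels == gm_label]
    if gm.size == 0:
        raise ValueError(f"no voxels labeled {gm_label} (GM) — upstream segmentation failure")
    return GMIntensityStats(
        mean=float(gm.mean()),
        sd=float(gm.std(ddof=0)),
        q3=float(np.percentile(gm, 100.0 * quantile)),
        n_voxels=int(gm.size),
    )


def wmh_threshold(stats: GMIntensityStats) -> float:
    """Lesion intensity threshold: the upper quartile of GM intensities."""
    return stats.q3


def segment_wmh(
    vol: IntensityVolume,
    tissue: LabeledVolume,
    threshold: float,
    min_cluster_voxels: int = 0,
    wm_label: int = TissueLabels.WM,
) -> np.ndarray:
    """Binary lesion mask: WM voxels strictly above ``threshold``.

    26-connected components smaller than ``min_cluster_voxels`` are removed.
    The mask is a subset of the WM label region by construction.
    """
    if vol.grid_shape != tissue.grid_shape:
        raise ValueError("intensity and tissue grids are not aligned")
    wm = tissue.labels == wm_label
    if not wm.any():
        raise ValueError(f"no voxels labeled {wm_label} (WM)")
    mask = wm & (vol.values > threshold)
    if min_cluster_voxels > 1 and mask.any():
        comp = measure.label(mask, connectivity=3)  # 26-neighborhood in 3D
        keep = np.zeros(comp.max() + 1, dtype=bool)
        ids, counts = np.unique(comp[comp > 0], return_counts=True)
        keep[ids[counts >= min_cluster_voxels]] = True
        mask = keep[comp]
    return mask
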
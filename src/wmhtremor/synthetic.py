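"""Synthetic study cohort: volumes, tremor recordings, clinical table.

The generator emulates the structure of an elderly essential-tremor (ET)
imaging study — 47 ET patients and 39 age-matched controls by default —
so that every downstream stage (segmentation, volumetry, polygraphy,
statistics) can be exercised end to end without any external data.

What is planted
---------------
Cross-subject correlations are realized through a joint latent Gaussian
(copula) construction over (age, WMH burden, tremor severity, tremor
frequency): defaults age–WMH r = 0.33, WMH–TETRAS r = 0.48, WMH–frequency
r = −0.37.  Age and disease duration are generated independently.  The
brain model is a concentric-ellipsoid phantom (background / CSF / GM / WM /
ventricle) with white-matter lesions planted as random ellipsoidal blobs
clipped to WM and trimmed to the target volume exactly; intensities are
tissue means times a smooth multiplicative bias field plus Gaussian noise.
Tremor recordings are a sinusoid plus noise on the accelerometer channels
and a burst-modulated broadband carrier on the EMG channels.

None of this is real MR physics or real tremor dynamics; distributional
choices are calibrated to the cohort's published summary statistics, and
passing tests demonstrate pipeline correctness, not clinical validity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .tremor import TremorRecording
from .volumes import IntensityVolume, LabeledVolume, TissueLabels
from .volumetry import AtlasVolume, FazekasParams

__all__ = [
    "CohortConfigError",
    "SyntheticCohortConfig",
    "SyntheticSubject",
    "generate_cohort",
    "generate_tissue_volume",
    "generate_atlas",
    "generate_brain_volume",
    "plant_lesions",
    "generate_tremor_recording",
]

RISK_FACTORS = ("hypertension", "hyperlipidemia", "diabetes", "coronary", "cerebrovascular")


class CohortConfigError(ValueError):
    """Raised for impossible cohort configurations."""


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study conditions for the synthetic cohort.

    Correlations are planted on the latent Gaussian scale; with the default
    near-linear margins the observed Pearson correlations match the targets
    in expectation.  ``render_volumes`` / ``render_recordings`` switch off
    rasterization for table-only calibration runs (hundreds of replicate
    cohorts); ground-truth lesion volumes and ROI shares are still drawn.
    """

    n_patients: int = 47
    n_controls: int = 39
    grid_shape: tuple[int, int, int] = (64, 64, 32)
    voxel_dims_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    age_mean_sd: tuple[float, float] = (72.0, 7.0)
    wmh_age_corr: float = 0.33
    wmh_tetras_corr: float = 0.48
    wmh_freq_corr: float = -0.37
    wmh_volume_mean_sd: tuple[float, float] = (2500.0, 800.0)
    tetras_mean_sd: tuple[float, float] = (19.67, 4.06)
    frequency_mean_sd: tuple[float, float] = (6.0, 1.0)
    duration_shape_scale: tuple[float, float] = (2.0, 10.0)
    log_power_mean_sd: tuple[float, float] = (0.3, 0.5)
    moca_et_mean_sd: tuple[float, float] = (24.28, 2.84)
    moca_control_mean_sd: tuple[float, float] = (26.02, 2.70)
    risk_factor_prevalence: tuple[float, ...] = (0.55, 0.45, 0.15, 0.15, 0.05)
    gm_intensity_mean_sd: tuple[float, float] = (100.0, 0.0)
    wm_intensity_mean_sd: tuple[float, float] = (80.0, 0.0)
    csf_intensity_mean: float = 30.0
    lesion_intensity_offset: float = 40.0
    noise_sd: float = 5.0
    bias_field_amplitude: float = 0.1
    recording_fs_hz: float = 800.0
    recording_duration_s: float = 30.0
    acc_noise_sd: float = 0.05
    render_volumes: bool = True
    render_recordings: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_controls <= 0:
            raise CohortConfigError("group sizes must be positive")
        for r in (self.wmh_age_corr, self.wmh_tetras_corr, self.wmh_freq_corr):
            if not abs(r) < 1.0:
                raise CohortConfigError(f"|target correlation| must be < 1, got {r}")
        if any(d <= 0 for d in self.voxel_dims_mm):
            raise CohortConfigError("voxel dimensions must be positive")
        if len(self.risk_factor_prevalence) != len(RISK_FACTORS):
            raise CohortConfigError("need one prevalence per vascular component")
        gm_mean, _ = self.gm_intensity_mean_sd
        wm_mean, _ = self.wm_intensity_mean_sd
        # lesions must land above the GM upper quartile, else undetectable
        q3_margin = gm_mean + 0.6745 * self.noise_sd
        if wm_mean + self.lesion_intensity_offset <= q3_margin:
            raise CohortConfigError(
                "lesion_intensity_offset too small: lesions would not exceed the GM Q3 margin"
            )
        self._latent_cholesky()  # fail fast on a non-PD correlation target

    def _latent_correlation(self) -> np.ndarray:
        # order: age, wmh, tetras, frequency
        R = np.eye(4)
        R[0, 1] = R[1, 0] = self.wmh_age_corr
        R[1, 2] = R[2, 1] = self.wmh_tetras_corr
        R[1, 3] = R[3, 1] = self.wmh_freq_corr
        return R

    def _latent_cholesky(self) -> np.ndarray:
        try:
            return np.linalg.cholesky(self._latent_correlation())
        except np.linalg.LinAlgError as exc:
            raise CohortConfigError(
                "target correlation matrix is not positive-definite"
            ) from exc


@dataclass
class SyntheticSubject:
    """One generated study participant with ground truth attached."""

    subject_id: str
    group: str  # "ET" or "control"
    age: float
    vascular_burden: int
    risk_factors: dict[str, int]
    moca: float
    disease_duration: float | None = None  # ET only
    tetras_part2: float | None = None
    tremor_frequency_hz: float | None = None
    log_total_power: float | None = None
    true_lesion_volume_mm3: float = 0.0
    tissue: LabeledVolume | None = None
    atlas: AtlasVolume | None = None
    intensity: IntensityVolume | None = None
    true_lesion_mask: np.ndarray | None = field(default=None, repr=False)
    recording: TremorRecording | None = None

    def __post_init__(self) -> None:
        if self.group not in ("ET", "control"):
            raise ValueError("group must be 'ET' or 'control'")
        if not 0 <= self.vascular_burden <= 5:
            raise ValueError("vascular burden lies in 0..5")
        if self.disease_duration is not None and self.disease_duration < 0:
            raise ValueError("disease duration must be >= 0")


# ---------------------------------------------------------------------------
# phantom geometry


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return r2 <= 1.0


def generate_tissue_volume(config: SyntheticCohortConfig) -> LabeledVolume:
    """Concentric-ellipsoid tissue phantom: CSF rim, GM shell, WM core, ventricle."""
    shape = tuple(config.grid_shape)
    if min(shape) < 16:
        raise CohortConfigError(f"grid {shape} too small to contain all tissue shells")
    half = np.array(shape) / 2.0
    center = (np.array(shape) - 1) / 2.0
    labels = np.zeros(shape, dtype=np.int16)
    labels[_ellipsoid(shape, center, half * 0.875)] = TissueLabels.CSF
    labels[_ellipsoid(shape, center, half * 0.8125)] = TissueLabels.GM
    labels[_ellipsoid(shape, center, half * 0.656)] = TissueLabels.WM
    labels[_ellipsoid(shape, center, half * 0.1875)] = TissueLabels.VENTRICLE
    return LabeledVolume(labels, config.voxel_dims_mm)


def generate_atlas(tissue: LabeledVolume) -> AtlasVolume:
    """Six-label WM atlas: two bilateral pairs plus two midline labels.

    Mirrors the bilateral/midline structure of discrete white-matter label
    atlases at desk scale: anterior/posterior tracts split left/right
    around the midline, and two commissural midline labels on the central
    sagittal slab.
    """
    wm = tissue.labels == TissueLabels.WM
    shape = tissue.grid_shape
    ci, cj = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    ii, jj, _ = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    labels = np.zeros(shape, dtype=np.int16)
    midline = np.abs(ii - ci) <= 1.5
    anterior = jj < cj
    left = ii < ci
    labels[wm & midline & anterior] = 5
    labels[wm & midline & ~anterior] = 6
    labels[wm & ~midline & left & anterior] = 1
    labels[wm & ~midline & ~left & anterior] = 2
    labels[wm & ~midline & left & ~anterior] = 3
    labels[wm & ~midline & ~left & ~anterior] = 4
    return AtlasVolume(
        volume=LabeledVolume(labels, tissue.voxel_dims_mm),
        label_names={
            1: "left anterior tract",
            2: "right anterior tract",
            3: "left posterior tract",
            4: "right posterior tract",
            5: "anterior commissural bundle",
            6: "posterior commissural bundle",
        },
        laterality={1: "left", 2: "right", 3: "left", 4: "right", 5: "midline", 6: "midline"},
        pairing={1: 2, 3: 4},
    )


def plant_lesions(
    wm_mask: np.ndarray,
    target_volume_mm3: float,
    voxel_dims_mm,
    rng: np.random.Generator,
    radius_range_mm: tuple[float, float] = (1.5, 4.0),
) -> np.ndarray:
    """Plant random ellipsoidal lesion blobs clipped to WM.

    Blobs are accumulated until the mask reaches the target voxel count
    (``round(target / voxel_volume)``), then the final blob is greedily
    trimmed so the achieved volume is exact.  Raises if the target exceeds
    the available WM volume.
    """
    wm_mask = np.asarray(wm_mask, dtype=bool)
    dims = np.asarray(voxel_dims_mm, dtype=float)
    vv = float(np.prod(dims))
    if target_volume_mm3 < 0:
        raise ValueError("target volume must be >= 0")
    target_voxels = int(round(target_volume_mm3 / vv))
    capacity = int(wm_mask.sum())
    if target_voxels > capacity:
        raise ValueError(
            f"target {target_volume_mm3} mm³ exceeds WM capacity {capacity * vv} mm³"
        )
    mask = np.zeros_like(wm_mask)
    if target_voxels == 0:
        return mask
    if target_voxels == capacity:
        return wm_mask.copy()

    wm_idx = np.argwhere(wm_mask)
    shape = wm_mask.shape
    guard = 0
    while mask.sum() < target_voxels:
        guard += 1
        if guard > 10000:  # pathological geometry; cannot normally trigger
            raise RuntimeError("lesion planting failed to converge")
        center = wm_idx[rng.integers(len(wm_idx))]
        radii_mm = rng.uniform(*radius_range_mm, size=3)
        radii_vox = np.maximum(radii_mm / dims, 0.5)
        lo = np.maximum(np.floor(center - radii_vox).astype(int), 0)
        hi = np.minimum(np.ceil(center + radii_vox).astype(int) + 1, shape)
        sub = tuple(slice(a, b) for a, b in zip(lo, hi))
        grids = np.ogrid[sub]
        r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii_vox))
        blob = (r2 <= 1.0) & wm_mask[sub] & ~mask[sub]
        overshoot = int(mask.sum() + blob.sum()) - target_voxels
        if overshoot > 0:
            blob_idx = np.argwhere(blob)
            drop = blob_idx[rng.choice(len(blob_idx), size=overshoot, replace=False)]
            blob[tuple(drop.T)] = False
        mask[sub] |= blob
    return mask


def generate_brain_volume(
    config: SyntheticCohortConfig,
    rng: np.random.Generator,
    lesion_mask: np.ndarray | None = None,
    tissue: LabeledVolume | None = None,
) -> tuple[LabeledVolume, IntensityVolume]:
    """Render the FLAIR-like intensity volume for one subject.

    Intensity = tissue mean × smooth multiplicative bias field + Gaussian
    noise; lesion voxels get ``lesion_intensity_offset`` added before the
    bias field is applied.
    """
    if tissue is None:
        tissue = generate_tissue_volume(config)
    shape = tissue.grid_shape
    gm_mean, gm_sd = config.gm_intensity_mean_sd
    wm_mean, wm_sd = config.wm_intensity_mean_sd
    means = np.array([5.0, config.csf_intensity_mean, gm_mean, wm_mean, config.csf_intensity_mean])
    base = means[tissue.labels]
    if lesion_mask is not None:
        base = base + np.asarray(lesion_mask, dtype=float) * config.lesion_intensity_offset

    # per-tissue voxel heterogeneity (default 0) plus global scanner noise
    sds = np.array([0.0, 0.0, gm_sd, wm_sd, 0.0])
    tissue_sd = sds[tissue.labels]
    noise = rng.standard_normal(shape) * np.sqrt(tissue_sd**2 + config.noise_sd**2)

    if config.bias_field_amplitude > 0:
        axes = [np.linspace(-1.0, 1.0, n) for n in shape]
        x, y, z = np.meshgrid(*axes, indexing="ij")
        coefs = rng.normal(size=9)
        q = (
            coefs[0] * x + coefs[1] * y + coefs[2] * z
            + coefs[3] * x * y + coefs[4] * x * z + coefs[5] * y * z
            + coefs[6] * x**2 + coefs[7] * y**2 + coefs[8] * z**2
        )
        q /= max(np.abs(q).max(), 1e-12)
        bias = np.exp(config.bias_field_amplitude * q)
    else:
        bias = 1.0

    values = base * bias + noise
    np.maximum(values, 0.1, out=values)  # keep intensities positive for log-domain fits
    return tissue, IntensityVolume(values, config.voxel_dims_mm)


# ---------------------------------------------------------------------------
# tremor recordings


def generate_tremor_recording(
    freq_hz: float,
    amplitude: float,
    rng: np.random.Generator,
    fs: float = 800.0,
    duration_s: float = 30.0,
    noise_sd: float = 0.05,
) -> TremorRecording:
    """Synthetic polygraphy recording at the study's sampling protocol.

    Accelerometer channels: sinusoid at ``freq_hz`` (random phase per side)
    plus white noise.  EMG channels: broadband 50–350 Hz carrier noise
    burst-modulated at the tremor frequency plus wideband noise.
    """
    if not 0 < freq_hz < fs / 2:
        raise ValueError(f"tremor frequency must lie in (0, Nyquist={fs / 2}) Hz")
    n = int(round(fs * duration_s))
    t = np.arange(n) / fs
    sos = sps.butter(4, [50.0, 350.0], btype="bandpass", fs=fs, output="sos")
    channels: dict[str, np.ndarray] = {}
    for side in ("left", "right"):
        phase = rng.uniform(0, 2 * np.pi)
        acc = amplitude * np.sin(2 * np.pi * freq_hz * t + phase)
        acc = acc + rng.normal(0.0, noise_sd, n)
        channels[f"acc_{side}"] = acc
        envelope = 0.5 * (1.0 + np.sin(2 * np.pi * freq_hz * t + phase))
        for muscle in ("flex", "ext"):
            carrier = sps.sosfilt(sos, rng.standard_normal(n))
            emg = envelope * carrier * max(amplitude, 0.2) + rng.normal(0.0, 0.05, n)
            channels[f"emg_{muscle}_{side}"] = emg
    return TremorRecording(channels=channels, fs=fs)


# ---------------------------------------------------------------------------
# cohort assembly


def _surrogate_fazekas(total_mm3: float, params: FazekasParams | None = None) -> tuple[int, int]:
    """Coarse grade pair from total burden, for table-only cohorts."""
    params = params or FazekasParams()
    pv = 0.5 * total_mm3
    if pv <= 0:
        g_pv = 0
    elif pv <= params.v_cap_mm3:
        g_pv = 1
    elif pv <= params.v_halo_mm3:
        g_pv = 2
    else:
        g_pv = 3
    deep = 0.5 * total_mm3
    if deep <= 0:
        g_deep = 0
    elif deep < params.c_punctate_voxels:
        g_deep = 1
    elif deep < 10 * params.c_punctate_voxels:
        g_deep = 2
    else:
        g_deep = 3
    return g_pv, g_deep


def generate_cohort(
    config: SyntheticCohortConfig | None = None,
) -> tuple[list[SyntheticSubject], pd.DataFrame]:
    """Generate the full synthetic study.

    Returns the subject list (with ground truth, volumes and recordings if
    rendered) and the per-subject clinical table.  Identical config and
    seed give bit-identical output.
    """
    config = config or SyntheticCohortConfig()
    rng = np.random.default_rng(config.seed)
    chol = config._latent_cholesky()

    n_et, n_ctrl = config.n_patients, config.n_controls
    z = rng.standard_normal((n_et + n_ctrl, 4)) @ chol.T

    age_mean, age_sd = config.age_mean_sd
    wmh_mean, wmh_sd = config.wmh_volume_mean_sd
    tet_mean, tet_sd = config.tetras_mean_sd
    f_mean, f_sd = config.frequency_mean_sd
    ltp_mean, ltp_sd = config.log_power_mean_sd

    tissue = atlas = None
    wm_mask = None
    wm_capacity_mm3 = np.inf
    vv = float(np.prod(config.voxel_dims_mm))
    if config.render_volumes:
        tissue = generate_tissue_volume(config)
        atlas = generate_atlas(tissue)
        wm_mask = tissue.labels == TissueLabels.WM
        wm_capacity_mm3 = wm_mask.sum() * vv

    roi_names = (
        atlas.merged_roi_names
        if atlas is not None
        else ["anterior tract", "posterior tract",
              "anterior commissural bundle", "posterior commissural bundle"]
    )

    subjects: list[SyntheticSubject] = []
    rows: list[dict] = []
    for k in range(n_et + n_ctrl):
        is_et = k < n_et
        group = "ET" if is_et else "control"
        sid = f"{'ET' if is_et else 'HC'}{(k if is_et else k - n_et) + 1:03d}"
        age = age_mean + age_sd * z[k, 0]
        wmh_target = float(np.clip(wmh_mean + wmh_sd * z[k, 1], 10.0, wm_capacity_mm3 * 0.8))

        moca_mean, moca_sd = (
            config.moca_et_mean_sd if is_et else config.moca_control_mean_sd
        )
        moca = float(np.clip(np.round(rng.normal(moca_mean, moca_sd)), 0, 30))
        risks = {
            name: int(rng.random() < p)
            for name, p in zip(RISK_FACTORS, config.risk_factor_prevalence)
        }
        burden = sum(risks.values())

        duration = tetras = freq = ltp = None
        if is_et:
            shape_, scale_ = config.duration_shape_scale
            duration = float(rng.gamma(shape_, scale_))
            tetras = float(max(tet_mean + tet_sd * z[k, 2], 0.0))
            freq = float(np.clip(f_mean + f_sd * z[k, 3], 2.5, 11.5))
            ltp = float(rng.normal(ltp_mean, ltp_sd))

        subject = SyntheticSubject(
            subject_id=sid,
            group=group,
            age=float(age),
            vascular_burden=burden,
            risk_factors=risks,
            moca=moca,
            disease_duration=duration,
            tetras_part2=tetras,
            tremor_frequency_hz=freq,
            log_total_power=ltp,
        )

        if config.render_volumes:
            lesions = plant_lesions(wm_mask, wmh_target, config.voxel_dims_mm, rng)
            subject.true_lesion_mask = lesions
            subject.true_lesion_volume_mm3 = float(lesions.sum()) * vv
            subject.tissue, subject.intensity = generate_brain_volume(
                config, rng, lesion_mask=lesions, tissue=tissue
            )
            subject.atlas = atlas
            counts = {
                int(i): int(c)
                for i, c in zip(*np.unique(atlas.volume.labels[lesions], return_counts=True))
            }
            roi_mm3 = {}
            for left_id in sorted(atlas.pairing):
                right_id = atlas.pairing[left_id]
                roi_mm3[atlas.merged_name(left_id)] = (
                    counts.get(left_id, 0) + counts.get(right_id, 0)
                ) * vv
            for i in sorted(atlas.laterality):
                if atlas.laterality[i] == "midline":
                    roi_mm3[atlas.label_names[i]] = counts.get(i, 0) * vv
            total_mm3 = subject.true_lesion_volume_mm3
        else:
            shares = rng.dirichlet(np.array([2.0, 2.0, 1.0, 1.0]))
            total_mm3 = wmh_target
            roi_mm3 = {name: float(s * total_mm3) for name, s in zip(roi_names, shares)}

        if is_et and config.render_recordings:
            amplitude = float(np.sqrt(2.0 * 10.0**ltp))
            subject.recording = generate_tremor_recording(
                freq,
                amplitude,
                rng,
                fs=config.recording_fs_hz,
                duration_s=config.recording_duration_s,
                noise_sd=config.acc_noise_sd,
            )

        g_pv, g_deep = _surrogate_fazekas(total_mm3)
        row = {
            "subject_id": sid,
            "group": group,
            "age": subject.age,
            "disease_duration": duration if duration is not None else np.nan,
            "vascular_burden": burden,
            **{f"risk_{k_}": v for k_, v in risks.items()},
            "moca": moca,
            "tetras_part2": tetras if tetras is not None else np.nan,
            "mean_frequency": freq if freq is not None else np.nan,
            "log_total_power": ltp if ltp is not None else np.nan,
            "total_wmh_mm3": total_mm3,
            "fazekas_pv": g_pv,
            "fazekas_dwm": g_deep,
        }
        for name, v in roi_mm3.items():
            row[f"wmh_{name.replace(' ', '_')}_mm3"] = v
        rows.append(row)
        subjects.append(subject)

    table = pd.DataFrame(rows)
    return subjects, table


def with_seed(config: SyntheticCohortConfig, seed: int) -> SyntheticCohortConfig:
    """Convenience: a copy of the config with a different seed."""
    return replace(config, seed=seed)
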
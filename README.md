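# wmhtremor

Analysis pipeline for studying the relation between cerebral **white-matter
hyperintensities (WMH)** and **essential tremor (ET)** severity in elderly
cohorts: automated WMH segmentation on FLAIR-like MR volumes, atlas-based
lesion volumetry, polygraphic tremor spectral measures, and the cohort
regression ledger — all exercisable end to end on a fully synthetic study
cohort, so no patient data are required to run or test anything.

It is written for movement-disorder and neuroimaging researchers who want a
small, fully tested, reproducible reference implementation of this analysis
chain rather than a clinical tool.

## What the pipeline computes

**Segmentation.** After dividing out a smooth multiplicative bias field
(log-domain polynomial fit with one-sided sigma-clipping so hyperintense
lesions do not bend the field), the lesion threshold is the upper quartile
of the gray-matter FLAIR intensity distribution,

```
θ = Q₇₅(I_FLAIR | GM),        WMH = { v ∈ WM : I(v) > θ },
```

optionally followed by removal of 26-connected clusters below a minimum
size.

**Volumetry.** Detected lesion voxels are assigned to a discrete
(max-probability-map style) white-matter atlas; left/right homologues are
merged into one ROI per tract and volumes are reported in mm³
(count × dx·dy·dz), with exact conservation: Σ ROI + unassigned = total.
A deterministic rule-based surrogate reproduces the Fazekas 0–3
periventricular / deep grading from distance-to-ventricle and
component-size cutoffs.

**Tremor polygraphy.** From 30 s bilateral accelerometer + EMG recordings
sampled at 800 Hz: EMG is bandpass filtered 50–350 Hz and full-wave
rectified; accelerometer spectra are Welch periodograms (4 s Hann windows,
50 % overlap, 0.25 Hz resolution). The tremor frequency is the greatest
spectral peak in the 2–12 Hz band, and tremor amplitude is summarized as
log₁₀ of the band-integrated power; left/right are averaged.

**Statistics.** Group comparisons (pooled t, Mann–Whitney U, Pearson χ²),
Pearson/Spearman correlations, and a regression cascade on the patient
subset for each outcome (TETRAS part 2 severity; mean tremor frequency):

* Model 1: outcome ~ age + disease duration,
* Model 2: Model 1 + age-adjusted total WMH volume (linear residualization),
* Models 3.x: per merged ROI, the ROI volume adjusted for total WMH,
  with Bonferroni correction α/m across the ROI family.

**Synthetic cohort.** A latent Gaussian (copula) construction plants the
cross-subject correlation structure (age–WMH r = 0.33, WMH–severity
r = 0.48, WMH–frequency r = −0.37 by default, 47 patients / 39 controls),
lesions are random blobs planted in the WM compartment of a
concentric-ellipsoid phantom with exact volume targeting, and recordings
are sinusoid-plus-noise at the planted tremor frequency.

## Worked example

```python
from wmhtremor import SyntheticCohortConfig
from wmhtremor.pipeline import PipelineConfig, run_all

config = PipelineConfig(
    seed=42,
    cohort=SyntheticCohortConfig(
        n_patients=20, n_controls=12,
        grid_shape=(48, 48, 24),
        wmh_volume_mean_sd=(900.0, 300.0),
        seed=42,
    ),
)
report = run_all(config)
ledger = report["ledger"]
t = ledger.table
print(t[t.outcome == "tetras_part2"]
      [["model", "predictors", "r_squared", "model_p", "wmh_beta"]]
      .round(3).to_string(index=False))
print(f"Bonferroni level for the ROI family: {ledger.bonferroni_level:.4f}")
```

prints (measured, not planted, quantities — every volume comes from
segmenting the rendered FLAIR-like images):

```
model                           predictors  r_squared  model_p  wmh_beta
    1               age + disease_duration      0.030    0.771       NaN
    2     model 1 + age-adjusted total WMH      0.123    0.541     0.316
  3.1  wmh_anterior_commissural_bundle_mm3      0.037    0.419     0.191
  3.2               wmh_anterior_tract_mm3      0.077    0.235     0.278
  3.3 wmh_posterior_commissural_bundle_mm3      0.012    0.643    -0.110
  3.4              wmh_posterior_tract_mm3      0.062    0.288    -0.250
Bonferroni level for the ROI family: 0.0125
```

Each row is one regression: `r_squared` and `model_p` describe the whole
model, `wmh_beta` is the standardized coefficient of the WMH predictor
added at that step. At this small desk scale (n = 20 patients) the planted
WMH→severity effect is visible in Model 2's R² gain but not significant —
power, not correctness.

The same stages are available from the shell:

```bash
wmhtremor simulate --out cohort/ --seed 3
wmhtremor segment --flair cohort/volumes/ET001/flair.nii.gz \
                  --tissue cohort/volumes/ET001/tissue.nii.gz --out mask.nii.gz
wmhtremor quantify --mask mask.nii.gz --atlas cohort/atlas.nii.gz \
                   --atlas-meta cohort/atlas.json --out rois.csv
wmhtremor tremor --recording cohort/recordings/ET001.csv --out tremor.csv
wmhtremor stats --cohort cohort/clinical.csv --out stats/
wmhtremor run-all --out report/ --seed 3
```

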
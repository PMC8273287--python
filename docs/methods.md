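# Methods

This note documents the models, conventions and defaults behind
`wmhtremor`, what the synthetic cohort does and does not emulate, and the
design choices made where the procedure was genuinely open.

## WMH segmentation

The detector assumes co-registered inputs: a FLAIR-like intensity volume
and a tissue label volume on the same grid (registration is an input
contract, not a pipeline stage). Candidate lesion voxels are restricted to
the white-matter label — the construct being measured is *white matter*
hyperintensity, and the restriction prevents cortical/CSF false positives.

**Bias field.** MR coils impose a smooth multiplicative intensity field.
We fit a polynomial of total degree 3 (default) to log-intensities inside a
fitting mask by least squares, exponentiate it into a field with unit
geometric mean over the mask, divide, and rescale so the mask mean is
unchanged. Two caveats are inherent to this class of correction:

* the fit cannot distinguish bias from the smooth component of anatomy, so
  the fitting mask should cover tissue of near-uniform intensity. The
  pipeline fits over normal-appearing WM;
* bright lesions are upward outliers to that fit, so the fit iterates
  one-sided sigma-clipping (3 rounds, residuals > 2 SD above the surface
  dropped). Clipping only the upper tail is deliberate: hyperintensities
  can only push residuals up, and symmetric clipping under-corrects
  high-lesion-load subjects.

The correction is defined up to one global scalar (the preserved mean is
the *observed* mask mean); this does not affect thresholding, which is
recomputed from the corrected volume itself.

**Threshold.** The lesion threshold is the upper quartile (75th
percentile) of gray-matter intensities on the corrected volume. The
quantile is configurable. Conventions that change results at the margin
and are therefore fixed and tested:

* percentile by linear interpolation between order statistics
  (`numpy.percentile` default), verified against a brute-force oracle;
* gray-matter SD reported with the population convention (ddof = 0);
* mask membership is *strict* inequality (intensity > θ); tie voxels are
  excluded;
* optional minimum cluster size uses 26-connectivity (the standard 3D
  lesion-mask neighborhood); the default is 0 — a pure threshold.

The threshold construction makes the mask invariant under any positive
affine intensity transform, which is tested as a property.

## Atlas volumetry and the Fazekas surrogate

Lesion voxels are assigned to a discrete label atlas (each voxel one
label, max-probability-map style; no soft assignment). Left/right
homologous labels are merged into one ROI; midline labels pass through.
Volumes are voxel count × voxel volume, in mm³. Lesion voxels on atlas
label 0 stay in the total and are reported as *unassigned*: the total is
defined on the whole mask, so per-ROI + unassigned = total holds exactly
(by construction, equality of floating-point sums computed the same way),
and is asserted, not approximated.

The Fazekas scale is a human visual rating (0–3 periventricular, 0–3 deep
white matter). The surrogate implemented here encodes the scale's anatomy
as explicit cutoffs, all configurable:

| parameter | default | meaning |
|---|---|---|
| `pv_distance_mm` | 3 mm | lesion voxels within this Euclidean distance of the ventricles are periventricular |
| `v_cap_mm3` | 200 mm³ | PV volume ≤ cap → grade 1 (caps/pencil lining) |
| `v_halo_mm3` | 1000 mm³ | PV volume ≤ halo → grade 2; above → grade 3 |
| `c_punctate_voxels` | 50 | largest deep component below this → grade 1 (punctate) |
| `c_confluent_voxels` | 500 | largest deep component at/above this → grade 3 (confluent) |

The periventricular/deep split is **voxel-wise** by distance (computed with
a physical-spacing Euclidean distance transform), not component-wise. This
was a deliberate choice: with a voxel-wise partition both grades are
provably monotone non-decreasing under lesion dilation (dilation can only
add voxels to either compartment), which is the invariant a severity grade
should satisfy and which the tests check on random masks. A component-wise
rule can *demote* the deep grade when a growing deep lesion touches the
periventricular band. The surrogate is deterministic and mask-only; it is
not calibrated against human raters and is labeled a surrogate wherever it
appears.

## Tremor polygraphy

Recordings follow the clinical polygraphy protocol: 30 s at 800 Hz,
bilateral hand accelerometer plus wrist flexor/extensor surface EMG. EMG
preprocessing is a zero-phase 4th-order Butterworth bandpass 50–350 Hz
followed by full-wave rectification. Spectra are Welch-averaged
periodograms with 4 s Hann windows and 50 % overlap — 0.25 Hz resolution,
verified to satisfy Parseval within 5 % on white noise. The analysis band
is 2–12 Hz for both the peak search and the total power (postural tremor
in the elderly lies well inside it); band and window are configurable.

* Tremor frequency = frequency of the greatest spectral peak in the band;
  ties break toward the lower frequency (deterministic argmax).
* Tremor amplitude = log₁₀ of the band-integrated accelerometer power
  (Σ power × Δf). Base 10 makes the scaling law transparent: a ×10
  amplitude change shifts the measure by exactly +2.
* Bilateral measures are the arithmetic mean of the sides. Headline
  measures come from the accelerometer only; EMG processing is provided
  but never feeds them (channel isolation is tested).

## Cohort statistics

* Group comparisons: two-sample t-test, pooled (Student) by default with
  Welch behind a flag; both a summary-statistics and a raw-data path,
  which agree to 1e-12 when summaries derive from the data.
* Mann–Whitney U reports x-wins (pairs x > y plus half-ties); the exact
  null distribution is used when there are no ties and n₁·n₂ ≤ 400,
  otherwise the tie-corrected normal approximation. All p two-sided.
* Pearson χ² without continuity correction; zero marginals are an error.
* Covariate adjustment is linear residualization: the adjusted variable is
  the residual of a simple least-squares fit on the covariate. This is
  what lets age and age-adjusted WMH coexist in one model; the
  Frisch–Waugh–Lovell equivalence with the joint fit is tested.
* OLS reports coefficients, post-hoc standardized β (b·sd(x)/sd(y)), R²,
  adjusted R², overall F/p and per-coefficient p; rank-deficient designs
  raise naming the collinear columns.
* The ledger fits, per outcome (TETRAS part 2; mean frequency) on the
  patient subset with listwise deletion per model: Model 1
  (age + duration), Model 2 (+ age-adjusted total WMH), and one Model 3.x
  per merged ROI with the total-WMH-adjusted ROI volume as the only
  predictor (a flag adds the Model 1 covariates). The Bonferroni level
  α/m applies to the 3.x family, m = number of merged ROIs.

One upstream report of this analysis lists F degrees of freedom implying
one more subject than the stated patient count; the ledger always reports
df from its own per-model n.

## The synthetic cohort

The generator defines the study conditions; it is calibrated once to the
cohort's published summary structure and is not adjusted per experiment.

* Group sizes 47 / 39; age ~ N(72, 7²) years in both groups.
* Correlation planting via one latent Gaussian vector per subject over
  (age, WMH, severity, frequency) with the three target pairwise
  correlations (0.33, 0.48, −0.37) and zeros elsewhere; a non-positive-
  definite target matrix is a configuration error. Margins are near-linear
  transforms (clipping is ≥3σ rare), so observed Pearson correlations
  match the targets in expectation — verified to within 0.05 over 200
  replicate cohorts. The severity–frequency correlation is not planted and
  arises only as the product path through WMH (≈ −0.18).
* Disease duration ~ Gamma(2, 10) years (mean 20, right-skewed),
  independent of age by construction. Vascular burden is the sum of five
  Bernoulli indicators (prevalences 0.55, 0.45, 0.15, 0.15, 0.05 — typical
  elderly-cohort figures giving median 1). TETRAS part 2 ~ N(19.67,
  4.06²); tremor frequency ~ N(6, 1²) Hz clipped to [2.5, 11.5];
  MoCA ~ N(24.28, 2.84²) patients / N(26.02, 2.70²) controls, rounded and
  clipped to 0–30.
* Total WMH volume ~ N(2500, 800²) mm³ floored at 10 mm³ (the upstream
  study reports no per-group volume distributions, so the scale is set by
  the correlation structure and a WM capacity that comfortably holds 3 SD
  at the default 64×64×32 grid; small-grid test configurations scale it
  down).
* Brain phantom: concentric ellipsoids (CSF rim, GM shell, WM core,
  central ventricle) on a 64×64×32 grid of 1 mm isotropic voxels by
  default (the scanner-resolution 0.43×0.43×2.0 mm grid is supported via
  config). Default intensities GM 100, WM 80, CSF 30 arbitrary units,
  lesion offset +40, noise SD 5, bias amplitude ±10 % (exp of a random
  quadratic). Configurations whose lesion offset cannot clear the GM
  upper-quartile margin are rejected at construction.
* Lesions: random ellipsoidal blobs (radii 1.5–4 mm) clipped to WM,
  accumulated and greedily trimmed to the target voxel count exactly, so
  ground-truth volume = voxel count × voxel volume with no slack.
* Recordings: accelerometer = sinusoid at the planted frequency with
  amplitude √(2·10^L) (so the band power is 10^L for planted log-power L)
  plus white noise (SD 0.05); EMG = 50–350 Hz filtered noise carrier,
  burst-modulated at the tremor frequency.
* Determinism: one `numpy` Generator seeded from the config; identical
  config ⇒ bit-identical cohort, tested at the CSV byte level.
* `render_volumes=False` / `render_recordings=False` skip rasterization
  while still drawing all ground-truth quantities — used for the
  replicate-heavy calibration suites (hundreds of cohorts).

**What the generator does not emulate** — and hence what passing tests do
not show: real MR physics (partial volume, gyral anatomy, Rician noise,
non-polynomial coil profiles), real lesion morphology and spatial
preference, registration error (inputs are generated co-registered),
non-sinusoidal tremor dynamics (waxing/waning amplitude, frequency drift,
motor-unit entrainment), and rater behavior on the Fazekas scale. Green
tests demonstrate that the pipeline measures what was planted under its
stated assumptions, not clinical validity on patient data.

## Problem sizes and numerical tolerances

Test and acceptance problem sizes were chosen so the full suite runs
comfortably on one CPU: rendered cohorts use 40–48-voxel grids with lesion
burden scaled to the smaller WM compartment; replicate suites use
table-only cohorts (200 replicates for correlation/effect recovery, 500
for familywise error); segmentation recovery uses 5 noisy phantoms at
lesion-contrast-to-noise 10; frequency recovery uses 500 recordings.
Key tolerances: exact equality for volume conservation and voxel-count
ground truth; 1e-8 relative for OLS against the normal-equations oracle;
one spectral bin (0.25 Hz) for frequency recovery; ±0.05 for mean planted
correlations and ±0.07 for the mean recovered standardized effect across
replicates (Monte-Carlo error budgets at those replicate counts).

## Known limitations

* The quantile threshold is global; no spatial regularization or
  periventricular exclusion is applied (the default reproduces the pure
  threshold rule; a cluster-size filter is available but off).
* The polynomial bias model cannot represent non-smooth or high-order
  fields, and contrast compression appears if the fitting mask spans
  strongly contrasting tissue.
* The Fazekas surrogate's cutoffs are plausible encodings of the scale's
  anatomy, not fitted to rater data.
* The exact Mann–Whitney path requires tie-free data; with ties the
  normal approximation with tie correction is used regardless of n.
* The ledger treats ROI models independently per outcome; no cross-outcome
  multiplicity correction is applied beyond the per-family Bonferroni.
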
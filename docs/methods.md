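# Methods

This note documents the models, numerical choices and limitations behind
`canopyspec`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Problem setting

Millimetre-resolution imaging spectroscopy of a rice canopy resolves
individual organs under their actual illumination. Four component classes
matter: sunlit leaf (SL), shaded leaf (SHL), sunlit panicle (SP), shaded
panicle (SHP). Two physical effects distinguish shaded from sunlit tissue:

1. **Amplitude** — shaded pixels receive mostly diffuse irradiance, so
   their reflectance is lower at every band.
2. **Absorption** — multiple scattering inside the canopy lengthens the
   optical path, so pigment absorption features are *deeper* after
   continuum removal.

Panicles are roughly an order of magnitude poorer in chlorophyll than
leaves, brighter across the visible, and carotenoid-dominated, which shows
up as a double-peak continuum-removed absorption feature in the blue.

The pipeline exploits these contrasts: the photochemical reflectance index
(PRI) separates leaves from panicles, and TCARI — the only index of the
four that scales linearly with amplitude — separates sunlit from shaded
pixels within each organ.

## Preprocessing

* **Calibration.** `Ref = (DN − DN_noise)/(DN_panel − DN_noise) × Ref_panel`
  per band, applied per cube. Output is not clipped above 1 (specular
  pixels legitimately exceed the white panel); negative values arising
  from dark-current fluctuation are clipped to 0 to keep reflectance
  physical.
* **MNF smoothing.** The classic construction: noise covariance from
  along-row first differences divided by √2 (adjacent pixels share signal,
  so differences are noise-dominated), noise-whitening, eigendecomposition
  of the whitened data covariance, reconstruction from the top *k*
  components. Default *k* keeps components with noise-whitened eigenvalue
  above 1. The covariance is regularized by `1e-10 × trace` on the
  diagonal when near-singular. Forward+inverse reconstruction is used, so
  output stays in reflectance space.
* **Band subsetting** to 400–900 nm (sensor edges are noise-dominated),
  then an EVI mask with a strict `> 0.45` vegetation threshold. The EVI
  uses the standard MODIS coefficients (2.5, 6, 7.5, 1) with anchors at
  800/670/470 nm.

## Spectral primitives

* **Band lookup.** Index formulas name nominal wavelengths; on a ~2.8 nm
  grid the nearest band within twice the grid step is used, ties broken
  toward the shorter wavelength. Resolved indices are recorded in every
  `VIResult` for auditability.
* **Continuum removal.** Upper convex hull via Andrew's monotone chain on
  the in-window points, evaluated by linear interpolation between hull
  vertices, then pointwise division. The hull passes through the first and
  last in-window bands, so the continuum-removed spectrum is exactly 1 at
  the window endpoints and lies in (0, 1]. Windows are closed intervals:
  blue 400–550 nm (carotenoid feature), red 550–750 nm (chlorophyll
  feature). Correctness is checked against an O(n³) chord-maximum oracle.
* **Band depth** is `1 − min` of a continuum-removed spectrum; it is the
  package's scalar summary of absorption strength, used in property tests.

## Classification

* **SAM** — arccos of the normalized inner product (cosine clamped to
  [−1, 1]); amplitude-invariant by construction.
* **SID** — symmetrized relative entropy of the spectra normalized to
  probability vectors, natural log; values ≤ 0 floored at 1e-6 before
  normalization so calibrated zeros stay in-domain.
* **Matching space.** "Continuum-removed" matching concatenates the blue-
  and red-window CR segments. Class references are season-pooled mean
  spectra (a per-stage option exists).
* **Decision tree.** `PRI ≥ pri_split` → leaf branch, then
  `TCARI ≥ tcari_leaf_split` → SL else SHL; otherwise panicle branch with
  its own TCARI split. Boundary equality goes to the leaf/sunlit side.
  Thresholds are midpoints of class means, where each class mean averages
  its per-stage means over the season (stage-mean weighting; pooled
  averaging is a flag). Cross-validation is stratified per class, with
  thresholds re-derived on each training fold — the statistically honest
  reading of "ten-fold cross-validation".

## Chlorophyll statistics

* `LCC = 1.4498 × SPAD − 22.014` (µg/cm²); the plant-level SPAD value is
  the mean of three per-leaf means (3 × 3 protocol).
* `CCC = LCC × LAI × 0.01` (g/m²); the 0.01 is the µg/cm² → g/m² unit
  factor.
* Spearman correlations are reported as squared rho with the large-sample
  t-approximation p-value; regression r² is the coefficient of
  determination on the original scale. These are distinct statistics and
  are labeled distinctly.
* Exponential models `y = a·e^{bx}` are fitted by nonlinear least squares
  initialized from the log-linear fit; z-scored predictors may be
  negative, only y must be positive. For constant y reproduced exactly,
  r² is reported as 1 (degenerate perfect fit).
* The group comparison aggregates per-scene mean VI over the classified SL
  and SHL pixels (plot-level regression), z-scores each group separately,
  and fits linear and exponential models per group and pooled.
* The paired t-test for sunlit-vs-shaded TCARI pairs class means per
  scene × stage.

## Synthetic scene generator

No field imagery is distributed with the package, so a parametric
generator defines the study conditions. A component spectrum is

    R(λ) = shade · plateau(λ) · Π(1 − dᵢ · boost · Gᵢ(λ)) · noise

with `plateau` a visible baseline rising through a logistic red-edge ramp
to a NIR plateau, and `Gᵢ` Gaussian absorption bands.

Defaults (chosen once to encode the qualitative contrasts described above;
no numeric reflectance values exist to copy, so amplitudes are the
package's own calibration):

| parameter | value | rationale |
|---|---|---|
| grid | 400–900 nm, 2.8 nm step | sensor sampling after band subsetting |
| leaf bands | 445/30 nm, 668/50 nm | chlorophyll+carotenoid blue, chlorophyll red |
| leaf depth curves | 0.78(1−e^(−LCC/10)), 0.72(1−e^(−LCC/6)) | hard saturation: sunlit absorption is chlorophyll-insensitive at field LCC |
| leaf NIR plateau | 0.46→0.54 rising to heading, then 0.49 | seasonal canopy development |
| leaf red-edge center | 710 nm | high-chlorophyll red edge |
| panicle bands | 450/14, 488/14 (carotenoid pair), 660/45 | double-peak blue feature; weak chlorophyll |
| panicle visible slope | +0.003/nm | senescent tissue brightens toward the red |
| shade_factor | 0.5 | shaded amplitude roughly half of sunlit |
| absorption boost | 1.10 + 0.008(LCC−30) | multiple-scattering deepening, stronger at high chlorophyll |
| pixel noise | 2% multiplicative log-normal per band | keeps reflectance positive |
| amplitude jitter | 6% per pixel | within-class illumination variability |
| NIR tilt | sd 0.10 per pixel | leaf-angle/structure variability of the plateau |
| class fractions | ET: SL-heavy open canopy; later: SHL-heavy closed canopy | canopy closure |
| stage LCC | 36, 40, 38, 44, 46, 39 µg/cm² | rise–fall, peak at heading, local minimum at jointing |
| stage LAI | 0.7…4.2…2.7 m²/m², peak at booting | CCC = LCC×LAI peaks at booting |
| N-rate effects | LCC offset −5…+3.5; LAI factor 0.6…1.25 | four fertilization levels |

Three generator choices deserve explanation:

* **depth × boost < 1 is validated.** When red-band absorption approaches
  totality, the R700/R670 ratio in TCARI blows up and shaded TCARI can
  overtake sunlit TCARI, inverting the classifier's premise; the validator
  rejects such configurations.
* **The LCC-dependent boost is the coupling knob.** Sunlit depth curves
  are saturated, so sunlit TCARI/PRI carry little chlorophyll signal;
  the shaded boost grows with LCC, so shaded indices do. This is what
  makes the shaded-pixel regressions recoverably stronger — the pattern
  the analysis is designed to detect, encoded deliberately.
* **The per-pixel NIR tilt separates the matching baselines.** SAM's
  angle is dominated by the bright NIR bands, so structural NIR
  variability degrades it sharply; SID normalizes to probability vectors
  and keeps reading the proportionally large differences in the dim
  visible bands; the decision tree uses visible/red-edge anchors and is
  barely affected. This yields the tree > SID > SAM accuracy ordering on
  reflectance spectra.

The generator's SPAD readings are drawn first and LCC/CCC recomputed from
their mean, so the SPAD→LCC→CCC chain is exactly self-consistent.

### What the generator does not emulate

Radiative transfer (no PROSAIL), BRDF and row-structure geometry,
illumination-angle dependence, spatial correlation of classes (pixels are
i.i.d. given the class map), mixed pixels at organ boundaries, and sensor
artifacts beyond multiplicative noise. Passing tests therefore demonstrate
the correctness and internal consistency of the *analysis*, not field
performance; the published field accuracies are not reproducible from
synthetic scenes and are not asserted.

## Problem sizes

Tests and the acceptance script use 50 × 50-pixel scenes, four plots (one
per nitrogen rate) over six stages (24 scenes), and 40 ROI spectra per
class per scene (≈ 80 per class × stage, matching a realistic manual-ROI
protocol). The full suite runs in well under a minute; the acceptance
script in seconds.

## Known limitations

* The tree's thresholds are season-constant; at the heading stage the
  shaded-leaf TCARI rises toward the sunlit split, which is where most of
  its residual misclassification (and a heading-stage excess of predicted
  SL pixels) comes from.
* The EVI mask with the strict 0.45 threshold removes a small fraction of
  dim shaded-leaf pixels at early tillering and most shaded-panicle
  pixels; leaf-group statistics are computed on the retained pixels.
* ENVI support is deliberately narrow: BSQ/BIL/BIP read, BSQ write,
  float32/uint16 samples, no georeferencing and no .sli binary libraries.
  Spectral libraries persist as CSV for diffability.
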
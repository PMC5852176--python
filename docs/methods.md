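# Methods

This note documents the models, conventions and design choices behind
`mibgquant`, in the spirit of a statistical-software methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Quantities and conventions

**Counts are mean counts per ROI pixel.**  Heart (`H_E`, `H_L`) and
mediastinal (`M_E`, `M_L`) counts are arithmetic means over the ROI, not
sums, so the heart-to-mediastinum ratio `HMR = H/M` is independent of ROI
area.  Circle membership is decided by the pixel-center test
(`(r−r₀)² + (c−c₀)² ≤ radius²`); rectangles are half-open on their max
edges.  Both conventions make ROI geometry integer-exact and testable.

**Collimator standardization** is the affine map
`HMR_std = (0.88/K_i)(HMR_i − 1) + 1`, with 0.88 the MEGP reference
coefficient (a named constant in exactly one place,
`mibgquant.collimators.MEGP_CONVERSION_COEFFICIENT`).  It fixes
HMR = 1, preserves order, and its algebraic inverse is used by the
simulator so tabular round trips are exact to machine precision.
Institutional ratios below 1 are physically odd but not forbidden by the
equation; they are accepted with a warning.  Early and late ratios are
standardized identically.  A cohort is marked standardized by the
presence of the `hmr_*_std` columns; re-standardizing raises.

**Decay correction** uses `DCF = 0.5^(Δt/13 h)` with Δt the time between
early and late acquisitions, computed from acquisition minutes.  The
conventional half-life of 13 h is kept as the default for fidelity to
standard practice in this quantitation chain; the physical 13.22 h value
for ¹²³I is available via the `half_life_hours` override.

**Washout statistics** are the three standard percent-scale formulas
(background+decay corrected; decay corrected; HMR-based).  The HMR-based
washout is defined on *standardized* ratios only — the `HmrPair`
standardization flag (or the presence of standardized columns, at cohort
level) is enforced.  Whether "heart counts" in the count-based formulas
are means or sums is not fixed by common usage; means per pixel are used,
consistent with the HMR convention.

## 2. The synthetic cohort generator

The generator's defaults state the emulated world; they are fixed, not
tuning knobs.

| Parameter | Default | Why |
|---|---|---|
| sub-cohorts | low-energy n=37, ages 50±19; medium-energy-class n=25, ages 68±13 | published cohort structure |
| age truncation | [20, 84] y | published range; truncated normal per sub-cohort is the simplest model matching the printed moments (the printed overall mean/median are then matched only approximately — independent truncated normals cannot jointly reproduce all of them exactly) |
| late-HMR age model | `3.69 − 0.0071·age` | published regression |
| residual SD | 0.4607 | calibrated so the age model explains r² ≈ 0.078 of a marginal SD 0.48: `sd_res = sqrt(0.48² − (0.0071·19)²)`; helpers `implied_marginal_sd` / `residual_sd_for_r2` expose the algebra |
| early/late offset | late − early = 0.19 | difference of the published early/late means (3.29 − 3.10) |
| early pairing noise SD | 0.19/Φ⁻¹(0.81) ≈ 0.216 | sized so the late ratio exceeds the early one in ~81 % of subjects, the published fraction (50/62) |
| t_early, t_late | 15 min; uniform 180–240 min | published acquisition windows |
| mediastinal scale | 100 counts/pixel (early) | absolute count levels are never published; 100 counts/pixel over a 300-pixel mediastinal ROI gives the ~0.6 % relative noise typical of planar ROI means |
| ground-truth washout | WR_BDC ~ Normal(13 %, 8 %), truncated at 90 % | the published washout scale; the late mediastinal count is solved from the target washout, the DCF and both institutional ratios, so counts are simultaneously consistent with the ratios and the washout |
| WR–age coupling | none | the emulated database reports no washout–age correlation |
| count noise | Gaussian `N(μ, μ/n_px)` on ROI means | the exact distribution of a mean of `n_px` i.i.d. Poisson pixels, to O(1/√n) — the tabular path never draws per-pixel noise |

Ages are drawn per sub-cohort; standardized ground-truth ratios are
drawn from the age model; institutional ratios are obtained by
*inverting* the standardization map with the sub-cohort's `K_i`.  The
far-tail guard (ratios clipped at 1.05) prevents nonphysical draws and
affects far less than 0.01 % of samples.  Conversion coefficients other
than the MEGP 0.88 are not published for specific cameras; the shipped
`LEHR 0.55` and `LMEGP 0.69` are plausible placeholders on the reported
scale of low-energy collimators and are user-replaceable through the
collimator config file.  The medium-energy-class sub-cohort is assigned
the MEGP reference collimator; the essential feature — two sub-cohorts
with different `K_i`, whose pooled institutional ratios are non-Normal
until standardized — is preserved.

### What a green test does and does not establish

The generator reproduces the *structure* of a normal database (cohort
composition, age model, count statistics, collimator mixture), not real
data.  Green parameter-recovery tests establish that the pipeline is
self-consistent and unbiased under the stated model; they cannot
establish the published numeric values themselves, because the raw
62-patient data are not deposited.  Single 62-patient draws scatter as
real cohorts do: per-cohort fitted slopes have SE ≈ 0.004, so individual
seeds produce slopes anywhere from ~0 to ~−0.015.

## 3. The phantom renderer and ROI placement

The phantom is a stylized anterior view: soft-tissue background (50 % of
mediastinal counts), a wide mediastinal band straddling the body midline
(column 128), and a uniform heart disc low and left of the midline whose
disc/band mean ratio *equals* the institutional HMR by construction.
The map is blurred with a Gaussian collimator PSF (σ 3.5–4.5 px by
collimator), mixed with an optional broad septal-penetration tail
(σ 30 px, fraction 0–1 %), and Poisson sampled.  Not simulated: scatter
orders, energy windows, anatomy, attenuation — the renderer emulates
count statistics and first-order collimator response only.

Geometry margins were chosen analytically so quantitation is accurate by
construction rather than by cancellation: the heart ROI (radius 30 px)
sits 10 px (≥2.2 σ) inside the disc (radius 40 px); the mediastinal ROI
(10×30 px, 10 px above the heart circle) sits ≥15 px inside the band
horizontally, and the band extends down behind the disc so the ROI sees
a flat plateau below.  The septal tail compresses the measured ratio
toward 1; the default tail fractions keep the end-to-end bias below
0.02 HMR on both institutional and standardized scales (verified in the
acceptance suite over 100 phantoms).

**Seed refinement.**  The operator's heart-center click is refined by an
iterated (2×) count-weighted centroid over a square window of half-width
`heart_radius + 15` px, with weights thresholded at the window's
half-maximum (isolating the hot cardiac blob from band and background).
A narrow window — e.g. the 21×21 px sometimes used for peak refinement —
provably cannot recenter a flat-topped blob wider than itself: the
centroid of a uniform plateau is the window center, so a 3-px seed error
survives and shifts the whole ROI set; with this phantom that error
reached 0.3 HMR in early development.  The window must see the blob's
edges.  A flat window (no contrast) leaves the seed untouched, so a
uniform image returns the seed unchanged.

**Midline detection.**  The mediastinal rectangle is horizontally
centered on the body midline, estimated as the column about which the
column count profile (summed over the rectangle's rows) is most mirror
symmetric — smallest mean squared left/right mismatch over a ±40 px
mirror half-width.  Only columns within ±40 px of the heart column whose
profile exceeds half-maximum are candidates: flat background is trivially
mirror symmetric and must not compete.  Ties (e.g. a perfectly uniform
image) resolve to the column nearest the heart.

## 4. Statistics layer

* **Quantiles:** linear-interpolation empirical estimator (numpy default,
  "type 7"); selectable.  Coverage property: the fraction of values
  strictly below the 2.5 % limit never exceeds 2.5 % + 1/n.
* **Normality:** Shapiro–Wilk via scipy.  Constant vectors leave the test
  undefined and are flagged with NaN plus a warning, not an exception.
* **Regression:** OLS (statsmodels) of measure on age, two-sided slope
  test, 95 % CI.  Display rule: line and CI band drawn only when
  p < 0.10.  p-values are assumed two-sided throughout.
* **Group split:** older group takes ties (age ≥ threshold, default 63),
  Welch t-test by default (safer under unequal group SDs), Student
  selectable.
* **No multiple-testing correction** is applied across the five measures,
  matching standard practice for descriptive normal-database reports;
  the per-measure p-values should be read accordingly.
* **Reporting precision:** HMR to 2 decimals, washout to 1 decimal,
  slopes to 4 decimals; raw full-precision values are kept alongside the
  display-rounded ones in `report.json`.
* **Determinism:** the full report (CSV + JSON) is byte-identical across
  runs on the same cohort.

## 5. Degenerate inputs and numerical edges

* `M = 0` (empty mediastinum) → explicit degenerate-input error on HMR.
* `H_E ≤ M_E` (no myocardial signal above background) → degenerate-input
  error naming the offending records; WR_BDC undefined.
* Negative inter-acquisition interval or non-positive `K_i` → validation
  errors.
* Standardization round trip `standardize(invert(h, K), K) = h` holds to
  1e−12 across h ∈ [1, 5], K ∈ [0.5, 1.0] (tested).
* DCF is exactly multiplicative in the interval, and DCF(13 h) = 0.5 by
  construction.

## 6. Known limitations

* The renderer's uniform disc is a harder target for centroid refinement
  than a real, center-weighted myocardial count distribution — the
  refinement window requirement above is driven by this worst case.
* Placeholder conversion coefficients are not camera-calibrated; any
  quantitative cross-camera use requires institution-specific `K_i`.
* The tabular noise model treats ROI means as independent Gaussians; it
  ignores the small covariance introduced by blur between neighboring
  ROIs that the image path does capture.
* DICOM ingestion is a thin optional path (requires pydicom) and assumes
  single-frame planar files with standard timing tags.
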
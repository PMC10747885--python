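# Methods

## Stereo geometry and height model

A stereo RGB-depth camera is mounted nadir over a raised plant bed.
For a pixel with disparity *D* (px), depth from the camera centre is
`Z = B·f/D` (similar triangles), and plant height above the bed is
`H = C − Z − r`, where

| symbol | meaning | default | unit |
|---|---|---|---|
| `B` | stereo baseline | 7.5 | cm |
| `f` | focal length on the aligned grid | 880 | px |
| `C` | camera elevation above the soil path | 204.5 | cm |
| `r` | bed rise above the soil path | 17 | cm |
| `min_depth_cm` | near validity limit | 19.6 | cm |
| `max_depth_cm` | far validity limit | `C` | cm |

The defaults model an OAK-D-Lite-class device: its mono cameras have a
horizontal field of view of ≈73°, giving `f ≈ 1280 / (2·tan 36.5°) ≈
880 px` on a 1280-px-wide aligned grid, and the manufacturer's near
limit for the 7.5 cm baseline is ≈19.6 cm. `f` is a calibration
quantity and is config-exposed, as are all other geometry constants.
Depths outside `[min_depth_cm, max_depth_cm]` are excluded and counted
(`n_out_of_range`): tiny disparities otherwise blow up `Z = B·f/D`, and
canopy tips closer than the near limit are physically unmeasurable —
the pipeline surfaces this as a warning rather than folding bad depths
into the estimate. Disparity 0 is the invalid marker (the formula
diverges there), matching stereo-pipeline convention.

## Segmentation

Crop margins → Rec. 601 grayscale → global OTSU → morphological
closing, then one erosion, both with 3×3 square structuring elements
and out-of-image pixels treated as background. Design choices where
the procedure was genuinely open:

* **Grayscale weights.** Rec. 601 (0.299, 0.587, 0.114), rounded to the
  nearest integer; the common default of classical pipelines.
  Config-exposed.
* **Foreground polarity.** The brighter OTSU class is taken as leaf
  (daylight canopies outshine soil); a flag inverts it.
* **Morphology order.** Closing (dilation∘erosion) followed by erosion,
  one pass each; iteration counts are config-exposed. The trailing
  erosion removes isolated speckle at the cost of one boundary ring per
  patch.
* **OTSU ties** break to the smallest threshold; a constant image is a
  degenerate-input error, not a silent threshold.

OTSU is delegated to `skimage.filters.threshold_otsu` fed an explicit
256-bin histogram (so thresholds are integer grey levels); morphology
to `scipy.ndimage` binary operations with `border_value=0` composed
explicitly. Both are verified against brute-force enumeration oracles
in the test suite.

## Percentile height (IPH)

Per-scan heights of all valid foreground pixels form the canopy
distribution (negative values — ground seen below bed level — are kept
in distributions but cannot affect the upper tail). Percentiles use
linear interpolation between order statistics (config-exposed, since
nearest-rank changes small-field results). The IPH defaults to the
98th percentile: the maximum is an extreme-value statistic and inherits
the full upper tail of the disparity noise, while p98 sits inside the
top of the canopy distribution. For noise sd σ_D px the per-pixel
height error scale is `σ_H ≈ Z²σ_D/(B·f)`; on a realistic canopy whose
top tier holds a few percent of the pixels, p98 lands near the middle
of the top tier's noise distribution and its bias is a fraction of
σ_H, whereas on a perfectly flat slab p98 is inflated by ≈2.05·σ_H.
Both behaviours are asserted in the tests.

## Validation metrics

With residuals taken between field plant height (FPH, the maximum of
the manual stem measurements) and IPH:

* `bias = mean(IPH − FPH)`
* `RMSE = sqrt(mean((IPH − FPH)²))` — population (divide-by-*n*) form
* `RMSE_B = sqrt(mean((IPH − FPH − bias)²))` — the population standard
  deviation of residuals, so `RMSE² = RMSE_B² + bias²` exactly
* `R²` — squared Pearson correlation of IPH vs FPH

Scans join the field log by crop and calendar date with a nearest-day
fallback of ≤2 days (weekly campaigns drift); unmatched scans are
listed in the report, never dropped silently.

## Thermal analytics

* **Day boundary:** local midnight-to-midnight; a day counts when it
  holds ≥80% (config-exposed) of the readings its cadence implies.
* **Cadences:** 15 min for air/control stations, 10 min for substrate
  probes. Mixed cadences are never resampled onto a common grid — each
  series is aggregated on its own timestamps, so no interpolated
  readings are invented; comparisons happen at the daily or hourly
  aggregate level.
* **Cooling effect:** per-day `control mean − crop mean`; positive =
  the planted bed ran cooler. **Substrate attenuation:** per-day
  `15 cm air mean − substrate mean`; negative days (dry-soil events
  where the substrate runs warmer) are retained and reported.
* **Box-whisker convention:** Tukey — quartiles by linear
  interpolation, whiskers at the most extreme points within 1.5×IQR,
  the rest listed as outliers.
* **Diurnal profiles** average by local clock hour within one calendar
  month; hours with no readings are flagged, not imputed.

## Synthetic data: what it emulates, what it does not

**Scenes.** Canopies are axis-aligned rectangles at exact heights; the
default profile is five nested tiers at 30/55/75/90/100% of the plant
top whose areas taper so the top tier covers ~8% of the canopy —
chosen to mimic the violin-shaped height distributions of real crowns,
where tips are a small part of the visible canopy. Leaf and ground
intensities are Gaussian around means ≥30 grey levels apart (a bimodal
histogram by construction); a contiguous shadow band multiplies leaf
intensity by a factor drawn uniformly from [0.2, 0.5], reproducing the
shaded-leaf segmentation failure in a controllable way. Disparities
are stored as reals by default, with an integer-quantization mode to
emulate device granularity (this separates algorithmic error from
sensor quantization; the 1-px bound on height error is
`Z²/(B·f)`). Noise (default campaigns use sd 0.5 px on canopy pixels),
occlusion (disparity 0) and all other randomness flow from a single
per-spec seed, so fixtures are bit-reproducible.

Not emulated: photorealistic leaves, perspective projection of plant
sides (every pixel carries its patch height), radiometric effects,
wind-induced matching failure. Passing tests therefore demonstrate the
correctness of the *computation* under controlled degradations, not
field robustness of the camera.

**Sensor suites.** Each station is a diurnal sinusoid
`mean + damping·amplitude·cos(2π(hod − peak − lag)/24) − offset` plus
Gaussian noise (default 0.2 °C, the class accuracy of the modelled
loggers) and optional missing rows. Crop stations carry positive
cooling offsets; the control's is 0; the substrate reuses the 15 cm
form lagged and damped. Because a full-period sinusoid averages to
its mean on any uniform daily grid, daily-mean cooling equals the
offset difference exactly at zero noise — the closed form the thermal
tests check against. Real sensor pathologies (drift, battery
step-changes, burst packet loss) are not modelled.

## Problem sizes and numerical choices

The demo campaign and test suite run at 240×240 px scenes (two crops ×
four weekly scans) and 14–30-day sensor windows — sizes chosen so the
whole suite and the acceptance script each finish in seconds while
every statistic retains its asymptotic behaviour (≥10⁴ foreground
pixels per scene, ≥96 readings per station-day). Noisy-recovery
checks average 10–20 seeds. Checksums in the run manifest are SHA-256
over output bytes; all CSV floats are written with fixed formats so
determinism is byte-level.

## Known limitations

* The generator's shadow/occlusion severities are free parameters, not
  calibrated against any particular farm.
* Segmentation is global-threshold only; heavily shaded canopies lose
  their tops from the foreground (documented, monotone degradation
  test) — local/adaptive thresholding is out of scope.
* IPH reads visible canopy: occluded organs under the crown do not
  contribute, and plants closer than the near depth limit are
  underestimated by construction.
* Thermal summaries assume station roles from the manifest; no
  cross-validation of physical plausibility (e.g. radiation shielding)
  is attempted.
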
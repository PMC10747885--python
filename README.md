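# phenoroof

Nondestructive crop-height monitoring from low-cost RGB-depth scans, and
crop-wise thermal-performance analytics for productive (blue-)green
rooftop farms.

Rooftop farms need frequent phenotyping — plant height above all — but
manual measurement is labour-intensive and disturbs the crop, and the
thermal benefit of a planted roof over bare concrete is invisible
without instrumented comparison. `phenoroof` implements both halves of
an automated monitoring workflow:

1. **Height estimation from stereo RGB-depth scans.** A nadir-mounted
   stereo camera over a raised plant bed yields an RGB frame and an
   aligned disparity matrix. The pipeline crops boundary regions,
   converts to grayscale, segments leaves from soil with a global OTSU
   threshold, cleans the mask with morphological closing + erosion
   (3×3 elements), and converts each foreground disparity *D* to depth
   and height by the similar-triangle rule

   ```
   Z = B·f / D           H = C − Z − r
   ```

   with baseline *B* (7.5 cm for the modelled device), focal length *f*
   (px), camera elevation *C* and bed rise *r*. The representative
   **image plant height (IPH)** is an upper percentile (98th by
   default) of the per-pixel heights — the plain maximum is dominated
   by disparity outliers. Accuracy against manual **field plant
   heights (FPH)** is summarised by bias, RMSE, bias-adjusted RMSE
   (`RMSE² = RMSE_B² + bias²`) and the FPH–IPH R².

2. **Thermal analytics.** From timestamped temperature CSVs (crop beds
   at 15 cm and 60 cm, substrate probes, a concrete control, a met
   station) it computes complete-day daily means, monthly diurnal
   (mean-hourly) profiles, the mean daily cooling effect
   `control − crop` per level, substrate attenuation
   `15 cm air − substrate`, and a monthly climate table.

Because field campaigns rarely publish raw scans, the package ships a
first-class synthetic-data module: tiered canopies with exact
ground-truth heights, controllable disparity noise, occlusion and
shadow, and diurnal sensor suites with known cooling offsets. Every
pipeline stage is tested against these closed forms and against
independent brute-force oracles.

## Worked example

```python
from phenoroof import (CameraGeometry, segment_scan, pixel_heights,
                       summarize_heights)
from phenoroof.synthetic import tiered_scene_spec, generate_scene

g = CameraGeometry()                       # B=7.5 cm, f=880 px, C=204.5 cm, r=17 cm
scan = generate_scene(tiered_scene_spec(75.0, g, seed=1,
                                        disparity_noise_sd_px=0.5))
mask, cropped = segment_scan(scan)
summary = summarize_heights(pixel_heights(cropped, mask))
print(mask.threshold_used, summary.n_pixels)
for p, v in sorted(summary.percentiles.items()):
    print(f"p{p}: {v:.2f}")
```

prints

```
93 13924
p95: 74.78
p96: 75.01
p97: 75.30
p98: 75.63
p99: 76.02
p100: 78.14
```

The scene's true canopy top is 75 cm and the disparity noise is 0.5 px.
OTSU picked grey level 93 to separate leaves from soil; 13 924 leaf
pixels survived cleanup. The 98th percentile reads 75.63 cm (0.6 cm
error) while the maximum reads 78.14 cm (3.1 cm error) — the reason the
IPH is taken from the 98th percentile rather than the top of the
distribution.

The same stack runs from the shell:

```
phenoroof run --demo --seed 1 --out runs/demo
```

executes the full simulate → segment → estimate → validate → thermal
chain on a packaged two-crop, 14-day campaign and writes mask PNGs, PLY
point clouds, a per-scan height CSV, a crop × percentile error report,
cooling/attenuation/climate CSVs and a checksummed `manifest.json`.
Runs are deterministic: the same config and seed reproduce every output
byte-for-byte.

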
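# vitroscan

Multi-sensor data processing for automated phenotyping of plant in vitro
cultures.

Micropropagation and regeneration experiments grow explants in closed,
sterile vessels on gelled media, which makes conventional destructive
measurement impossible and conventional imaging hard: every sensor looks
through the sealing, the medium surface shifts as it dries, and plants
must be measured in place for weeks. `vitroscan` implements the data
side of a low-cost scanning phenotyping platform for exactly this
situation — for tissue-culture labs and phenotyping developers who want
per-vessel, per-timepoint growth traits from top-down RGB images, laser
distance scans, chlorophyll fluorescence spectra and radiometric thermal
frames, without any of the motion-control hardware.

## What it computes

**RGB pipeline.** Histogram stretching, 4x block-mean downscaling
(4054 x 3040 → 1014 x 760), a pixel-wise random forest over a fixed
14-feature bank (RGB + HSV, multi-scale Gaussian, gradient, Laplacian,
difference-of-Gaussians) predicting plant vs background, nearest-neighbour
mask rescaling, connected components, and traits: projected plant area
(px and mm²), perimeter, convex-hull area, solidity = A/A_hull,
stockiness = 4πA/P², degree of coverage. Plant positions for targeted
point measurements come from Otsu's threshold on the hue channel; night
frames are detected from mean intensity.

**Depth pipeline.** For a raw laser raster (100 mm x 100 mm, 1 mm pitch):
zero plane from the four 10 x 10 scan corners; linear raw→mm calibration
(validated to 72 mm); circle Hough transform finds the medium disk on the
day-0 scan; the rim is stripped (r_new = r₁ − 3 px); RANSAC
(distance threshold 1.5 mm, sample size 3, 10,000 iterations) fits the
possibly tilted medium plane; subtracting it segments plant pixels. Derived
parameters: medium height h (plane mean), medium volume as a circular
conical frustum V = ⅓πh(r₁² + r₁r₂ + r₂²) with r₂ = 37 mm, average canopy
height (mean of plant pixels), maximum plant height (mean of the upper
10th percentile) and projected plant area from depth.

**Spectral pipeline.** 288 channels, 340–850 nm: factory-polynomial
wavelength mapping, mean dark-current subtraction, 400–660 nm masking,
and the chlorophyll fluorescence summary F690, F730, F740 and
F690/F740 — a chlorophyll-content estimator.

**Thermal pipeline.** T(°C) = raw/100 − 273.15, exactly invertible on the
14-bit grid; histograms at the 0.05 °C sensitivity; a percentile contrast
index quantifying plant/background separation.

**Optics.** Haze index [%] = (diffuse/total − system scatter) x 100 and
band-mean transmittance for sealing materials.

**Validation statistics.** Pixel confusion statistics (accuracy,
sensitivity, specificity, precision), OLS regression reports with adjusted
R², MAE, RMSE, signed MRE, and repositioning-repeatability MAE.

**Synthetic scenes.** Because no imaging data are deposited, a scene
generator renders all four sensor views of a virtual vessel (medium disk,
plant blobs, depth noise and slope dropout, day/night illumination,
fluorescence peaks, foil-compressed thermal contrast) with exact ground
truth, so every pipeline is validated by parameter recovery.

## Worked example

`examples/03_depth_pipeline.py` renders a scan of a tilted 20 mm medium
carrying four plants and runs the full depth pipeline:

```
dropout: 7.7% of points lost on steep surfaces
medium height: 20.00 mm (truth 20.00)
medium plane tilt: a=+0.0100, b=-0.0050 (truth +0.0100, -0.0050)
medium volume: 83.7 mL-equivalent (frustum model)
average canopy height: 9.39 mm
maximum plant height (upper-decile mean): 13.19 mm
projected plant area from depth: 426 mm^2 (426 px)
```

The RANSAC plane recovers the medium height and tilt despite plants
covering part of the surface; plant heights are then read from the
plane-corrected raster. The projected area from depth undershoots the
true footprint because the time-of-flight sensor drops steeply tilted
leaf flanks — the heights themselves are robust to that loss. The other
examples cover calibration and spot size (`01`), RGB segmentation and
traits (`02`), fluorescence (`04`), thermal and haze (`05`) and the
experiment loop over a directory tree (`06`).

A thin CLI wraps the same functions:

```bash
vitroscan synth /tmp/exp --seed 1 && vitroscan run /tmp/exp
vitroscan spot-size --diameter 23.5
```

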
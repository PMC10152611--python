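# Methods

This note records the models, parameter choices and numerical decisions
behind `vitroscan`, and what the synthetic-scene validation does and does
not demonstrate.

## Coordinate and unit conventions

Scene coordinates are x right, y down, origin at the scan top-left, in
mm; raster index (row, col) = (y, x), 0-based; heights are mm, positive
upward. The renderers sample fields at pixel centres ((i + 0.5) · pitch);
the depth pipeline attributes raster values to (i · pitch), which is
self-consistent (the plane is fitted and evaluated in the same frame) —
only comparisons against analytic scene geometry need the half-pixel
offset. Reported millimetre values round half-up to 2 decimals.

## Calibrations

*Laser distance sensor.* Ordinary least squares maps raw readouts to mm
(robust fitting deliberately not used: the calibration object is
measured under controlled conditions and a simple linear regression is
reported with adjusted R², MAE, RMSE). The zero-plane readout is where
the fitted line crosses 0 mm (nominal 19430 raw); heights above 72 mm
are outside the sensor's validated range and are flagged invalid, not
clipped. Negative heights (readouts beyond the zero plane) are kept but
flagged — medium shrinkage cannot produce them, so they indicate noise.

*Pixel pitch.* The camera is not telecentric, so px/mm depends on object
height. Two pitches are kept as independent `PixelMetric` instances —
37.7 px/mm at the ~20 mm medium surface (trait conversion) and
46.7 px/mm at the 41 mm reference object (repeatability) — and are not
interpolated, because no height-dependent scale model is calibrated.

*Spectrometer spot size.* A uniform circular spot scanned in 1 mm steps
across white squares (sides 30 → 21 mm) yields one peak per square; every
square at least as large as the spot transmits the full spot signal, so
its peak tops out at a shared plateau level — the scan's global maximum.
A square is classified as a plateau when ≥ 2 adjacent positions lie
within the flatness tolerance (default 0.5%, relative) of that level;
the first square (largest to smallest) with a sharp maximum gives the
spot diameter. Referencing flatness to the shared plateau level rather
than to each square's own peak is essential at 1 mm sampling: for a
square only fractionally larger than the spot the true flat top is
narrower than one step, so at most one sample lies on it and a per-peak
rule cannot see the plateau. With the level-based rule the procedure
resolves the diameter to the integer mm below it (floor) for true
diameters whose fractional part is ~0.2–0.8; diameters within ~0.2 mm
of an integer are genuinely unresolvable at this pitch. The simulator
places square centres half a step off the sample grid — the worst-case
phase — so the tests do not rely on lucky alignment.

## RGB pipeline

The histogram stretch maps the 1st/99th per-channel percentiles to
0/255; percentile anchors keep specular highlights from compressing the
range. Downscaling is block-mean with the trailing partial block
averaged over the pixels it has (4054 → 1014 at factor 4), rounded
half-even to 8 bit.

The classifier is a random forest (60 trees, ≤ 40,000 samples per class,
min leaf 2, fixed seed) over an explicitly versioned 14-feature bank:
R, G, B, H, S, V; Gaussian-smoothed intensity at σ = 1, 3.5, 10 px;
gradient magnitude at σ = 1.6, 5 px; Laplacian of Gaussian at
σ = 1.6, 5 px; difference of Gaussians 1.6 − 5 px. The bank is a
documented stand-in for the interactive toolkit's unpublished selection
of 14 features: the count and the multi-scale colour/edge/texture
character match, the exact filters are this package's own choice.

Masks are upscaled by nearest neighbour (preserves binarity); components
use 8-connectivity; components below `min_object_px` (default 64
full-resolution px) are removed as speckle — the analogue of the
connected-component cleanup any production pipeline applies. Perimeter
is the 8-connected boundary chain length with diagonal steps weighted
√2. That estimator overestimates a digital circle's circumference by
~5.5% (a classic digital-geometry result), so the stockiness 4πA/P² of
an ideal disk measures ~0.91, not 1.0; stockiness values are therefore
comparable across objects measured by this package but not directly
against area-based compactness definitions.

Otsu's threshold maximises between-class variance over 256 bins via
cumulative sums; thresholds inside an empty histogram gap are exactly
tied and resolve to the smallest index. The night rule is strict:
mean intensity < threshold (default 30/255) is night; equality is day.

## Depth pipeline

The zero plane is the mean raw readout over the four 10 x 10 corner
squares (bare cultivation surface), excluding dropout points. Medium
detection runs a circle Hough transform on the gradient-magnitude edge
raster (edge threshold 2 mm/px — the ~20 mm rim step dominates), radii
30–45 px bracketing the 37 mm vessel; the circle is detected on each
vessel's first scan and reused, since later canopies occlude the rim.
The rim strip r_new = r₁ − 3 px precedes plane fitting.

RANSAC samples 3 points per iteration (10,000 iterations, seeded,
vectorised), fits the exact plane, counts inliers at |residual| ≤ 1.5
(interpreted as mm — heights are metric after calibration), and refits
the consensus set by least squares. Collinear samples are rejected by a
near-zero normal z-component. The medium/plant split reuses the same
1.5 mm band: corrected heights ≤ 1.5 mm are medium (set to 0), the rest
are plant pixels — self-consistent with the RANSAC inlier definition.
Dropout points are excluded from every statistic, never imputed.

The "upper 10 percentile" for maximum plant height uses the
linear-interpolation percentile and includes values equal to P90.
Average canopy height averages nonzero plant pixels only (medium-level
zeros are excluded; including them would re-express coverage, not
height). Medium volume uses the frustum with r₁ = pitch-converted Hough
radius and r₂ = 37 mm; it reduces exactly to the cylinder at r₁ = r₂ and
the cone at r₁ = 0.

**Error budget for medium height.** The estimate is (mean of the fitted
plane over the disk) referenced to the corner zero level, so its noise
variance is σ²(1/N_inliers + 1/N_corner) with N_corner = 400. The
recovery tests bound the error at 3σ√(1/N_inliers + 1/400); the plane
fit alone (known zero) is held to 3σ/√N.

## Spectral pipeline

Wavelengths come from a 5th-degree polynomial in channel index, rounded
half-up to integer nm. Factory coefficients are device-specific and
unpublished; the shipped default is a linear map 340 + 1.7726 · i
covering 340–849 nm, and monotonicity is checked and flagged rather than
assumed. Dark subtraction clips negatives to zero (counts are physical).
Peak lookup takes the channel nearest 690/730/740 nm without
interpolation — channel spacing (~1.8 nm) is far below the 15 nm optical
resolution, so interpolation would add nothing. Both F730 and F740 are
reported because both conventions are in use for the long-wavelength
chlorophyll band; the ratio uses F690/F740. The local-maximum quality
flag asks whether the maximum within ±10 nm of the nominal wavelength
falls strictly inside that window: a genuine peak does, a shoulder of a
neighbouring peak peaks at the window edge.

## Thermal and optics

raw = 100(T + 273.15) is exact on the integer grid, so conversion
round-trips bit-perfectly for all 14-bit raws. Histograms default to the
sensor's 0.05 °C sensitivity and conserve pixel count. The contrast
index (P95 − P5 of temperature) is this package's diagnostic for
plant/background separability; no thermal segmentation is defined.
Frames caught mid flat-field calibration are all-equal and flagged.

The haze index follows the diffuse/total ratio with the instrument's
relative scattered transmittance exposed as a parameter defaulting to 0
(it is an unpublished device constant), clipped below at 0. Reported
haze values therefore include the instrument's own scatter. Band means
default to VIS 380–780 nm and thermal 8–14 µm.

## Validation statistics

Adjusted R² uses the conventional (Ezekiel) form
1 − (1 − R²)(n − 1)/(n − 2) — the literature on adjustment formulas
surveys many variants; this is the standard one. MRE is the signed mean
of (y − x)/x in percent, so positive MRE means overestimation; the sign
convention is deliberate (absolute relative errors would hide the
direction of bias). MAE ≤ RMSE always (Jensen); the tests enforce it.

## Synthetic scenes: what they do and do not show

The generator emulates the features the pipelines actually key on: a
raised circular medium (radius 37 mm, height ~20 mm, optional tilt up to
±0.02 mm/mm), hemispherical/conical plant blobs on the medium, depth
noise of 0.1 mm (the sensor's linearity), slope dropout above 2.0 mm/mm
(calibrated so typical hemispherical plants lose roughly a third of
their pixels on steep flanks — the dropout rate on real leaves is not
quantified, so this is a modelling choice), RGB noise of 2/255, night
frames at 5% intensity, dark-current spectra with Gaussian emission
peaks at 690/735 nm plus a 375 nm excitation leak, and foil-compressed
thermal contrast. One scene seed drives independent per-sensor
substreams, so all renders are bit-reproducible and re-rendering one
sensor never shifts another.

Deliberately not modelled: physically based rendering, condensation and
total-reflection artefacts, leaf self-occlusion and overlap, colour
variation within a plant, vessel-wall reflections. Consequently the
≥ 0.97 held-out segmentation accuracy demonstrates that the feature
bank, classifier and mask plumbing work end to end in the intended
accuracy regime — not that the classifier would reach that accuracy on
real vessel images, which are harder in exactly the unmodelled ways.
Parameter-recovery results (medium height/tilt, canopy and top heights)
are likewise conditional on the noise model, though these pipelines
depend far less on scene realism.

Desk-scale problem sizes: synthetic RGB scenes render at 2 px/mm
(200 x 200) rather than the camera's native 4054 x 3040 — the pipelines
are resolution-agnostic and the printed 1014 x 760 reduction is covered
by a dedicated shape test; depth scans use the full 100 x 100 grid;
recovery suites use 20 seeded scenes and segmentation validation 12
held-out scenes against 4 training scenes.

## Known limitations

- The feature bank is an explicit stand-in (see above); models trained
  with it are not interchangeable with the original toolkit's models.
- Stockiness carries the ~9% chain-code bias on smooth round objects.
- Per-explant depth traits (per-component heights) are out of scope, as
  is RGB-depth registration.
- The spot-size procedure is resolution-limited to the mm below the true
  diameter and undefined within ~0.2 mm of integer diameters.
- `run_experiment` trains its classifier from fixture truth masks when
  none is supplied; real deployments should pass a classifier trained on
  curated labels.
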
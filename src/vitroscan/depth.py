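"""Depth-scan processing: zero level, medium detection, RANSAC plane
segmentation and the derived growth parameters.

A vessel depth scan is a regular raster of raw laser readouts (nominally
100 mm x 100 mm at 1 mm pitch). Processing establishes the vessel's zero
plane from the four scan corners, converts raw readouts to heights, finds
the circular culture medium by Hough transform on the day-0 scan, strips
the disturbing medium rim (r_new = r1 - 3 px), fits the possibly tilted
medium surface with RANSAC (distance threshold 1.5 mm, sample size 3,
10,000 iterations), and subtracts the plane to segment plant pixels.
Five parameters follow: medium height, medium volume (circular conical
frustum against the fixed 37 mm vessel bottom radius), average canopy
height, maximum plant height (mean of the upper 10th percentile), and
projected plant area from depth data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import hough_circle, hough_circle_peaks

from .calibration import LaserCalibration
from .synth import DepthGrid

__all__ = [
    "MediumModel",
    "DepthTraits",
    "zero_level",
    "heights_from_grid",
    "detect_medium_circle",
    "edge_removed_mask",
    "ransac_plane",
    "correct_and_segment",
    "depth_traits",
    "process_depth_scan",
]

VESSEL_BOTTOM_RADIUS_MM = 37.0
RANSAC_DISTANCE_THRESHOLD_MM = 1.5
RANSAC_SAMPLE_SIZE = 3
RANSAC_ITERATIONS = 10_000


@dataclass
class MediumModel:
    """Detected culture medium: bounding circle and fitted surface plane."""

    circle_center_px: tuple[float, float]  # (row, col)
    circle_radius_px: float
    plane: tuple[float, float, float]  # height = a*x + b*y + c, x=col, y=row (mm)
    inlier_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.circle_radius_px <= 3:
            raise ValueError("circle radius must exceed 3 px so the rim can be removed")
        if not np.all(np.isfinite(self.plane)):
            raise ValueError("plane coefficients must be finite")

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        a, b, c = self.plane
        return a * x + b * y + c


@dataclass
class DepthTraits:
    """The five growth parameters derived from one depth scan."""

    medium_height_mm: float
    medium_volume_mm3: float
    avg_canopy_height_mm: float | None
    max_plant_height_mm: float | None
    projected_area_depth_mm2: float
    n_plant_px: int


def zero_level(grid: DepthGrid, corner_size: int = 10) -> float:
    """Zero-plane raw readout: mean over the four scan-corner squares.

    The corners of the scan area see only the bare cultivation surface,
    never medium or plant. Invalid (dropout) points are excluded; if all
    corner points are invalid the zero level is undefined.
    """
    r, c = grid.raw.shape
    if r < 2 * corner_size or c < 2 * corner_size:
        raise ValueError("grid too small for the requested corner squares")
    k = corner_size
    patches = [
        (slice(0, k), slice(0, k)),
        (slice(0, k), slice(c - k, c)),
        (slice(r - k, r), slice(0, k)),
        (slice(r - k, r), slice(c - k, c)),
    ]
    vals = []
    for sr, sc in patches:
        v = grid.raw[sr, sc][grid.valid[sr, sc]]
        vals.append(v[np.isfinite(v)])
    vals = np.concatenate(vals)
    if vals.size == 0:
        raise ValueError("all corner points invalid; zero level undefined")
    return float(vals.mean())


def heights_from_grid(
    grid: DepthGrid, cal: LaserCalibration, zero_raw: float | None = None
) -> np.ndarray:
    """Convert the raw raster to heights (mm) above the vessel's zero plane.

    When ``zero_raw`` is given (typically from :func:`zero_level`) it
    overrides the calibration's global zero so each vessel is referenced
    to its own cultivation surface. Invalid points become NaN; heights
    beyond the calibrated range are also NaN'd.
    """
    z0 = cal.zero_raw if zero_raw is None else zero_raw
    h = cal.slope * (grid.raw - z0)
    h = np.where(grid.valid & np.isfinite(grid.raw), h, np.nan)
    h = np.where(h <= cal.max_valid_height_mm, h, np.nan)
    return h


def detect_medium_circle(
    height_grid: np.ndarray,
    radius_range: tuple[int, int] = (30, 45),
    edge_threshold_mm_per_px: float = 2.0,
) -> tuple[tuple[float, float], float]:
    """Detect the raised culture-medium disk in a day-0 height raster.

    Edges are pixels whose height-gradient magnitude exceeds the
    threshold (the medium rim is a ~20 mm step); the strongest circle
    over the Hough accumulator within ``radius_range`` wins. Returns
    ``((row, col), radius_px)``.
    """
    h = np.nan_to_num(height_grid, nan=0.0)
    gy, gx = np.gradient(h)
    edges = np.hypot(gx, gy) > edge_threshold_mm_per_px
    if not edges.any():
        raise ValueError("no edges found; no raised medium in the scan")
    radii = np.arange(radius_range[0], radius_range[1] + 1)
    acc = hough_circle(edges, radii)
    accums, cx, cy, rad = hough_circle_peaks(acc, radii, total_num_peaks=1)
    if len(accums) == 0 or accums[0] <= 0:
        raise ValueError("no circle found above the accumulator threshold")
    return (float(cy[0]), float(cx[0])), float(rad[0])


def edge_removed_mask(
    center_rc: tuple[float, float], radius_px: float, shape: tuple[int, int],
    rim_px: float = 3.0,
) -> np.ndarray:
    """Disk mask with the disturbing medium rim stripped: r_new = r1 - rim.

    Raises when the reduced radius is not positive.
    """
    r_new = radius_px - rim_px
    if r_new <= 0:
        raise ValueError("radius too small: rim removal leaves no disk")
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(rr - center_rc[0], cc - center_rc[1]) <= r_new


def ransac_plane(
    heights: np.ndarray,
    mask: np.ndarray,
    distance_threshold: float = RANSAC_DISTANCE_THRESHOLD_MM,
    sample_size: int = RANSAC_SAMPLE_SIZE,
    iterations: int = RANSAC_ITERATIONS,
    seed: int = 0,
    pitch_mm: float = 1.0,
) -> MediumModel:
    """Fit the medium surface plane by RANSAC inside the edge-removed mask.

    Repeatedly samples ``sample_size`` (=3) points, fits the exact plane
    through them, and counts points within ``distance_threshold`` mm of
    vertical residual; the consensus-maximal plane is refit by least
    squares on its inliers. The RNG is seeded, so a fixed seed gives a
    bit-reproducible plane.
    """
    valid = mask & np.isfinite(heights)
    rows, cols = np.nonzero(valid)
    z = heights[rows, cols]
    n = z.size
    if n < sample_size:
        raise ValueError("fewer than sample_size valid points in the mask")
    x = cols.astype(float) * pitch_mm
    y = rows.astype(float) * pitch_mm

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(iterations, sample_size))
    p0, p1, p2 = idx[:, 0], idx[:, 1], idx[:, 2]
    # plane normal from the two triangle edge vectors
    v1 = np.stack([x[p1] - x[p0], y[p1] - y[p0], z[p1] - z[p0]], axis=1)
    v2 = np.stack([x[p2] - x[p0], y[p2] - y[p0], z[p2] - z[p0]], axis=1)
    nrm = np.cross(v1, v2)
    ok = np.abs(nrm[:, 2]) > 1e-12  # reject collinear / vertical-plane samples
    if not ok.any():
        raise ValueError("all RANSAC samples degenerate (collinear points)")
    a = -nrm[ok, 0] / nrm[ok, 2]
    b = -nrm[ok, 1] / nrm[ok, 2]
    c = z[p0[ok]] - a * x[p0[ok]] - b * y[p0[ok]]

    best_count = -1
    best_abc = None
    chunk = max(1, int(2e7) // n)
    for s in range(0, a.size, chunk):
        e = min(s + chunk, a.size)
        resid = np.abs(
            z[None, :] - (a[s:e, None] * x[None, :] + b[s:e, None] * y[None, :] + c[s:e, None])
        )
        counts = (resid <= distance_threshold).sum(axis=1)
        i = int(np.argmax(counts))
        if counts[i] > best_count:
            best_count = int(counts[i])
            best_abc = (a[s + i], b[s + i], c[s + i])

    a0, b0, c0 = best_abc
    inl = np.abs(z - (a0 * x + b0 * y + c0)) <= distance_threshold
    # least-squares refit on the consensus set
    A = np.stack([x[inl], y[inl], np.ones(int(inl.sum()))], axis=1)
    coef, *_ = np.linalg.lstsq(A, z[inl], rcond=None)
    plane = (float(coef[0]), float(coef[1]), float(coef[2]))

    inlier_mask = np.zeros_like(valid)
    final_inl = np.abs(z - (plane[0] * x + plane[1] * y + plane[2])) <= distance_threshold
    inlier_mask[rows[final_inl], cols[final_inl]] = True
    # circle fields describe the fitted region; callers that detected the
    # medium circle overwrite them with the Hough result
    cr, cc_ = float(np.mean(rows)), float(np.mean(cols))
    extent = float(np.max(np.hypot(rows - cr, cols - cc_)))
    return MediumModel(
        circle_center_px=(cr, cc_),
        circle_radius_px=max(extent, 4.0),
        plane=plane,
        inlier_mask=inlier_mask,
    )


def correct_and_segment(
    heights: np.ndarray,
    model: MediumModel,
    mask: np.ndarray,
    distance_threshold: float = RANSAC_DISTANCE_THRESHOLD_MM,
    pitch_mm: float = 1.0,
) -> np.ndarray:
    """Plane-correct heights inside the mask and segment plant pixels.

    corrected = height - plane(x, y); pixels within the RANSAC inlier
    band (corrected <= distance_threshold) are medium and set to 0; the
    remaining nonzero pixels are plants. Outside the mask and at invalid
    points the output is NaN.
    """
    rr, cc = np.mgrid[0 : heights.shape[0], 0 : heights.shape[1]]
    plane = model.evaluate(cc.astype(float) * pitch_mm, rr.astype(float) * pitch_mm)
    corrected = heights - plane
    corrected = np.where(mask & np.isfinite(heights), corrected, np.nan)
    corrected = np.where(corrected <= distance_threshold, 0.0, corrected)
    # NaNs were turned into 0 by the comparison being False? No: NaN<=t is False,
    # so NaNs survive the where; re-impose them explicitly for clarity.
    corrected = np.where(mask & np.isfinite(heights), corrected, np.nan)
    return corrected


def depth_traits(
    model: MediumModel,
    plant_heights: np.ndarray,
    mask: np.ndarray,
    pitch_mm: float = 1.0,
    top_radius_px: float | None = None,
    r2_mm: float = VESSEL_BOTTOM_RADIUS_MM,
) -> DepthTraits:
    """Compute the five depth-derived growth parameters.

    medium height = mean of the fitted plane over the medium mask;
    medium volume = frustum (1/3) pi h (r1^2 + r1 r2 + r2^2) with r1 the
    detected top radius (pitch-converted) and r2 the vessel bottom
    radius; canopy height = mean of nonzero plant pixels; maximum plant
    height = mean of plant values at or above their 90th percentile
    (linear-interpolation percentile); projected area = plant pixel
    count times the pixel footprint.
    """
    rr, cc = np.mgrid[0 : plant_heights.shape[0], 0 : plant_heights.shape[1]]
    plane_vals = model.evaluate(cc.astype(float) * pitch_mm, rr.astype(float) * pitch_mm)
    h_medium = float(np.mean(plane_vals[mask]))

    r1 = (model.circle_radius_px if top_radius_px is None else top_radius_px) * pitch_mm
    volume = (np.pi / 3.0) * h_medium * (r1**2 + r1 * r2_mm + r2_mm**2)

    vals = plant_heights[np.isfinite(plant_heights)]
    plant_vals = vals[vals > 0]
    n_plant = int(plant_vals.size)
    if n_plant == 0:
        canopy = top = None
    else:
        canopy = float(plant_vals.mean())
        p90 = float(np.percentile(plant_vals, 90))
        top = float(plant_vals[plant_vals >= p90].mean())
    area = n_plant * pitch_mm * pitch_mm
    return DepthTraits(
        medium_height_mm=h_medium,
        medium_volume_mm3=float(volume),
        avg_canopy_height_mm=canopy,
        max_plant_height_mm=top,
        projected_area_depth_mm2=float(area),
        n_plant_px=n_plant,
    )


def process_depth_scan(
    grid: DepthGrid,
    cal: LaserCalibration,
    day0_circle: tuple[tuple[float, float], float] | None = None,
    seed: int = 0,
    distance_threshold: float = RANSAC_DISTANCE_THRESHOLD_MM,
    iterations: int = RANSAC_ITERATIONS,
) -> tuple[DepthTraits, MediumModel, np.ndarray]:
    """Run the full depth pipeline on one scan.

    ``day0_circle`` carries the medium circle detected on the day-0 scan
    of the same vessel (the circle is detected once and reused, since
    later canopies occlude the rim); when None it is detected on this
    scan. Returns (traits, medium model, corrected plant-height raster).
    """
    z0 = zero_level(grid)
    heights = heights_from_grid(grid, cal, zero_raw=z0)
    if day0_circle is None:
        day0_circle = detect_medium_circle(heights)
    center, radius = day0_circle
    mask = edge_removed_mask(center, radius, grid.raw.shape)
    model = ransac_plane(
        heights, mask, distance_threshold=distance_threshold,
        iterations=iterations, seed=seed, pitch_mm=grid.x_pitch_mm,
    )
    model.circle_center_px = center
    model.circle_radius_px = radius
    corrected = correct_and_segment(
        heights, model, mask, distance_threshold=distance_threshold,
        pitch_mm=grid.x_pitch_mm,
    )
    traits = depth_traits(
        model, corrected, mask, pitch_mm=grid.x_pitch_mm, top_radius_px=radius
    )
    return traits, model, corrected
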
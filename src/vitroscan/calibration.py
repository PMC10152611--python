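"""Metric calibrations for the vessel-scanning phenotyping platform.

Three independent calibrations tie the sensors to metric units:

* a pixel pitch (px/mm) for the top-down RGB camera, obtained by imaging
  a reference object of known size at a known height;
* a linear raw-to-millimetre conversion for the point-measuring laser
  distance sensor, fitted against caliper-measured staircase heights,
  with a zero-plane readout (the bare cultivation surface) and a maximum
  height above which the sensor readout is unreliable;
* the effective detection-spot diameter of the aperture-limited micro
  spectrometer, determined by scanning the spot across white squares of
  decreasing side length on a black background.

Because the camera is not telecentric, the pixel pitch depends on object
height; two pitches are in routine use (37.7 px/mm at the 20 mm medium
surface, 46.7 px/mm at a 41 mm reference object) and are kept as separate
:class:`PixelMetric` instances rather than interpolated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "PixelMetric",
    "LaserCalibration",
    "SpotScanProfile",
    "fit_laser_calibration",
    "raw_to_height",
    "px_to_mm",
    "area_px_to_mm2",
    "round_mm",
    "determine_spot_size",
    "simulate_spot_scan",
    "save_calibration",
    "load_calibration",
]

#: Pixel pitch at the nominal 20 mm culture-medium surface.
MEDIA_SURFACE_PX_PER_MM = 37.7
#: Pixel pitch at the 41 mm reference object used for repeatability checks.
REFERENCE_OBJECT_PX_PER_MM = 46.7
#: Raw laser readout of the bare cultivation surface (zero plane).
DEFAULT_ZERO_RAW = 19430.0
#: Heights above this are outside the laser sensor's validated range (mm).
DEFAULT_MAX_VALID_HEIGHT_MM = 72.0


@dataclass(frozen=True)
class PixelMetric:
    """Pixel pitch of the RGB camera at a given object height."""

    pixels_per_mm: float
    reference_height_mm: float = 0.0

    def __post_init__(self) -> None:
        if not (self.pixels_per_mm > 0):
            raise ValueError("pixels_per_mm must be positive")


@dataclass(frozen=True)
class LaserCalibration:
    """Linear raw-to-height conversion for the laser distance sensor.

    ``height = slope * (raw - zero_raw)`` so that the cultivation surface
    reads 0 mm. Heights above ``max_valid_height_mm`` are flagged invalid.
    """

    slope: float
    intercept: float
    zero_raw: float = DEFAULT_ZERO_RAW
    max_valid_height_mm: float = DEFAULT_MAX_VALID_HEIGHT_MM
    adj_r2: float | None = None
    mae: float | None = None
    rmse: float | None = None


@dataclass
class SpotScanProfile:
    """1 mm-pitch line scan of the spectrometer spot over sized squares.

    ``readouts`` holds, per scan position, the value of the spectrometer
    channel with the highest signal. ``square_centers_mm`` maps each square
    side length to the x-position of that square's centre along the scan.
    """

    positions_mm: np.ndarray
    readouts: np.ndarray
    square_sides_mm: Sequence[int]
    square_centers_mm: Sequence[float]

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.readouts = np.asarray(self.readouts, dtype=float)
        if self.positions_mm.shape != self.readouts.shape:
            raise ValueError("positions and readouts must be congruent")
        d = np.diff(self.positions_mm)
        if d.size and (np.any(d <= 0) or not np.allclose(d, d[0])):
            raise ValueError("positions must strictly increase at constant pitch")
        if len(self.square_sides_mm) != len(self.square_centers_mm):
            raise ValueError("one centre per square required")


def fit_laser_calibration(
    pairs: Sequence[tuple[float, float]],
    max_valid_height_mm: float = DEFAULT_MAX_VALID_HEIGHT_MM,
) -> LaserCalibration:
    """Fit the raw-to-millimetre line by ordinary least squares.

    Parameters
    ----------
    pairs
        ``(raw readout, reference height mm)`` observations, e.g. from a
        staircase-shaped reference object measured with a caliper.

    Returns
    -------
    LaserCalibration with slope/intercept, the implied zero-plane readout
    (where the fitted line crosses 0 mm), and fit diagnostics.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (raw, height) pairs")
    raw, height = arr[:, 0], arr[:, 1]
    if np.unique(raw).size < 2:
        raise ValueError("calibration unfittable: all raw readouts identical")
    slope, intercept = np.polyfit(raw, height, 1)
    if slope == 0:
        raise ValueError("calibration unfittable: zero slope")
    zero_raw = -intercept / slope

    # diagnostics via the shared validation statistics
    from .metrics import regression_report

    pred = slope * raw + intercept
    rep = regression_report(height, pred) if raw.size >= 3 else None
    resid = height - pred
    return LaserCalibration(
        slope=float(slope),
        intercept=float(intercept),
        zero_raw=float(zero_raw),
        max_valid_height_mm=float(max_valid_height_mm),
        adj_r2=None if rep is None else rep.adj_r2,
        mae=float(np.mean(np.abs(resid))),
        rmse=float(np.sqrt(np.mean(resid**2))),
    )


def raw_to_height(cal: LaserCalibration, raw) -> tuple[np.ndarray, np.ndarray]:
    """Convert raw laser readouts to heights above the cultivation surface.

    Returns ``(height_mm, valid)`` arrays (scalars in, 0-d arrays out).
    Non-finite readouts and heights above the validated range are invalid.
    Negative heights (readouts beyond the zero plane) are kept but callers
    may treat them as noise; medium shrinkage cannot produce them.
    """
    raw = np.asarray(raw, dtype=float)
    height = cal.slope * (raw - cal.zero_raw)
    valid = np.isfinite(raw) & (height <= cal.max_valid_height_mm)
    height = np.where(np.isfinite(raw), height, np.nan)
    return height, valid


def px_to_mm(pm: PixelMetric, length_px: float) -> float:
    """Convert a pixel length to millimetres."""
    if length_px < 0:
        raise ValueError("length must be nonnegative")
    return length_px / pm.pixels_per_mm


def area_px_to_mm2(pm: PixelMetric, area_px: float) -> float:
    """Convert a pixel area to mm**2 (the conversion factor is the pitch squared)."""
    if area_px < 0:
        raise ValueError("area must be nonnegative")
    return area_px / pm.pixels_per_mm**2


def round_mm(value_mm: float, decimals: int = 2) -> float:
    """Round a millimetre value half-up to the reported precision."""
    q = 10.0**decimals
    return math.floor(value_mm * q + 0.5) / q


# ---------------------------------------------------------------------------
# Spectrometer detection-spot size
# ---------------------------------------------------------------------------


def _circle_square_overlap(r: float, cx: float, side: float) -> float:
    # Area of a circle of radius r centred at (cx, 0) intersected with the
    # axis-aligned square [-side/2, side/2]^2; exact via the chord integral.
    from scipy.integrate import quad

    half = side / 2.0
    lo, hi = max(-half, cx - r), min(half, cx + r)
    if lo >= hi:
        return 0.0
    val, _ = quad(
        lambda x: 2.0 * min(half, math.sqrt(max(r * r - (x - cx) ** 2, 0.0))),
        lo,
        hi,
        limit=200,
    )
    return val


def simulate_spot_scan(
    true_diameter_mm: float,
    square_sides_mm: Sequence[int] = tuple(range(30, 20, -1)),
    pitch_mm: float = 1.0,
    spacing_mm: float = 60.0,
    amplitude: float = 1.0,
) -> SpotScanProfile:
    """Simulate the line scan used to determine the detection-spot size.

    A uniform circular spot of the given diameter is moved in ``pitch_mm``
    steps along a row of white squares (sides largest to smallest) on a
    black field; the readout at each position is the spot area overlapping
    white. Square centres are offset half a step from the sample grid —
    the worst-case sampling phase for plateau detection.
    """
    if true_diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    r = true_diameter_mm / 2.0
    centers = [spacing_mm * (i + 1) + 0.5 * pitch_mm for i in range(len(square_sides_mm))]
    positions = np.arange(0.0, spacing_mm * (len(square_sides_mm) + 1) + 0.5 * pitch_mm, pitch_mm)
    readouts = np.zeros_like(positions)
    for c, s in zip(centers, square_sides_mm):
        near = np.abs(positions - c) <= (s + true_diameter_mm) / 2.0 + pitch_mm
        for i in np.nonzero(near)[0]:
            readouts[i] += amplitude * _circle_square_overlap(r, positions[i] - c, s)
    return SpotScanProfile(positions, readouts, tuple(square_sides_mm), tuple(centers))


def determine_spot_size(profile: SpotScanProfile, flatness_tol: float = 0.005) -> int:
    """Determine the detection-spot diameter from a square-scan profile.

    Every square at least as large as the spot transmits the full spot
    signal, producing a flat-topped peak at a common plateau level (the
    profile's global maximum). A square is classified as a plateau when at
    least 2 adjacent scan positions lie within ``flatness_tol`` (relative)
    of that level; otherwise its peak is a sharp maximum. Scanning the
    squares from largest to smallest, the side length of the first
    sharp-maximum square is reported as the spot diameter.

    Raises
    ------
    ValueError
        If every square shows a plateau (spot smaller than resolvable) —
        "spot larger than all squares" is the converse error when the
        profile never reaches a plateau at all.
    """
    ref = float(profile.readouts.max())
    if ref <= 0:
        raise ValueError("profile carries no signal")
    order = np.argsort(profile.square_sides_mm)[::-1]
    half_window = 0.5 * (max(profile.square_sides_mm) + 2.0)
    for i in order:
        side = profile.square_sides_mm[i]
        center = profile.square_centers_mm[i]
        sel = np.abs(profile.positions_mm - center) <= half_window
        vals = profile.readouts[sel]
        ok = vals >= (1.0 - flatness_tol) * ref
        run = best = 0
        for flag in ok:
            run = run + 1 if flag else 0
            best = max(best, run)
        if best < 2:
            return int(side)
    raise ValueError("spot smaller than all squares: every peak shows a plateau")


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def save_calibration(path: str | Path, laser: LaserCalibration, pixel: PixelMetric) -> None:
    payload = {
        "slope": laser.slope,
        "intercept": laser.intercept,
        "zero_raw": laser.zero_raw,
        "max_valid_height_mm": laser.max_valid_height_mm,
        "pixels_per_mm": pixel.pixels_per_mm,
        "reference_height_mm": pixel.reference_height_mm,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_calibration(path: str | Path) -> tuple[LaserCalibration, PixelMetric]:
    payload = json.loads(Path(path).read_text())
    laser = LaserCalibration(
        slope=payload["slope"],
        intercept=payload["intercept"],
        zero_raw=payload["zero_raw"],
        max_valid_height_mm=payload["max_valid_height_mm"],
    )
    pixel = PixelMetric(payload["pixels_per_mm"], payload.get("reference_height_mm", 0.0))
    return laser, pixel
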
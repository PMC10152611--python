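"""Synthetic culture-vessel scenes with known ground truth.

Stands in for the scanning hardware: a flat cultivation surface carrying
a raised, optionally tilted circular medium disk (nominal radius 37 mm,
height ~20 mm) with plant blobs of known footprint and height on top.
From one :class:`SceneTruth` the renderers derive the four sensor views —
a raw laser depth raster, a top-down RGB image with an exact plant mask,
a fluorescence spectrum, and a thermal frame — so every processing
pipeline can be validated by parameter recovery against the truth.

Coordinate convention: x right, y down, origin at the scan top-left;
raster index (row, col) = (y, x); heights are positive upward (mm).
All renders are reproducible: one scene seed drives independent
per-sensor substreams, so re-rendering one sensor never shifts another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .calibration import LaserCalibration, PixelMetric
from .spectral import Spectrum, default_wavelengths, N_CHANNELS

__all__ = [
    "PlantBlob",
    "SceneTruth",
    "DepthGrid",
    "VesselImage",
    "ThermalFrame",
    "render_depth",
    "render_rgb",
    "render_spectrum",
    "render_thermal",
    "default_scene",
    "random_scene",
]

SCAN_EXTENT_MM = 100.0  # nominal square scan pattern
THERMAL_SHAPE = (120, 160)  # rows, cols


@dataclass(frozen=True)
class PlantBlob:
    """A single explant: circular footprint, cone or hemisphere profile."""

    center_xy: tuple[float, float]  # mm, scene coordinates
    radius_mm: float
    max_height_mm: float
    shape: Literal["cone", "hemisphere"] = "hemisphere"
    color: tuple[int, int, int] = (52, 130, 58)

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or self.max_height_mm < 0:
            raise ValueError("blob radius must be positive, height nonnegative")

    def height_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Height of the blob surface above the medium at scene coords (mm)."""
        d = np.hypot(x - self.center_xy[0], y - self.center_xy[1])
        u = np.clip(d / self.radius_mm, 0.0, 1.0)
        if self.shape == "cone":
            prof = 1.0 - u
        else:
            prof = np.sqrt(np.clip(1.0 - u**2, 0.0, None))
        return np.where(d <= self.radius_mm, self.max_height_mm * prof, 0.0)


@dataclass
class SceneTruth:
    """Ground truth of one synthetic vessel scene.

    Defaults reflect the nominal cultivation situation: a 37 mm-radius
    medium disk ~20 mm high centred in a 100 mm x 100 mm scan, depth
    noise 0.1 mm (the laser sensor's linearity), and a slope-dropout
    threshold of 2.0 mm/mm calibrated so that typical hemispherical
    plants lose roughly a third of their pixels on steep flanks.
    """

    medium_center_xy: tuple[float, float] = (50.0, 50.0)
    medium_radius_mm: float = 37.0
    medium_height_mm: float = 20.0
    medium_tilt: tuple[float, float] = (0.0, 0.0)  # (slope_x, slope_y), mm/mm
    plants: list[PlantBlob] = field(default_factory=list)
    noise_sd_mm: float = 0.1
    dropout_slope_threshold: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        cx, cy = self.medium_center_xy
        r = self.medium_radius_mm
        if not (r > 0 and cx - r >= 0 and cy - r >= 0
                and cx + r <= SCAN_EXTENT_MM and cy + r <= SCAN_EXTENT_MM):
            raise ValueError("medium disk must fit inside the scan area")
        for p in self.plants:
            d = np.hypot(p.center_xy[0] - cx, p.center_xy[1] - cy)
            if d + p.radius_mm > r:
                raise ValueError("plant blob must lie within the medium disk")
        if self.noise_sd_mm < 0:
            raise ValueError("noise sd must be nonnegative")

    def rng(self, sensor: str) -> np.random.Generator:
        # independent substream per sensor
        streams = {"depth": 0, "rgb": 1, "spectrum": 2, "thermal": 3}
        return np.random.default_rng([int(self.seed), streams[sensor]])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SceneTruth":
        d = json.loads(Path(path).read_text())
        d["plants"] = [
            PlantBlob(tuple(p["center_xy"]), p["radius_mm"], p["max_height_mm"],
                      p["shape"], tuple(p["color"]))
            for p in d.get("plants", [])
        ]
        d["medium_center_xy"] = tuple(d["medium_center_xy"])
        d["medium_tilt"] = tuple(d["medium_tilt"])
        return cls(**d)


@dataclass
class DepthGrid:
    """Rectangular raster of raw laser readouts on a regular scan grid."""

    raw: np.ndarray
    valid: np.ndarray
    x_pitch_mm: float = 1.0
    y_pitch_mm: float = 1.0

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.raw.shape != self.valid.shape:
            raise ValueError("raw and valid rasters must be congruent")
        if self.x_pitch_mm <= 0 or self.y_pitch_mm <= 0:
            raise ValueError("pitch must be positive")


@dataclass
class VesselImage:
    """Top-down RGB raster of one vessel with acquisition metadata."""

    pixels: np.ndarray  # (rows, cols, 3) uint8
    timestamp: str = ""
    illumination: Literal["day", "night", "unknown"] = "unknown"
    pixel_metric: PixelMetric | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("expected an RGB raster")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must be nonempty")

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]


@dataclass
class ThermalFrame:
    """14-bit radiometric thermal frame (160 x 120)."""

    raw: np.ndarray
    timestamp: str = ""
    foil_present: bool = False

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw)
        if self.raw.ndim != 2:
            raise ValueError("expected a 2-D raster")

    @property
    def overrange(self) -> np.ndarray:
        """Pixels outside the 14-bit range, flagged not discarded."""
        return (self.raw < 0) | (self.raw >= 2**14)


# ---------------------------------------------------------------------------
# Renderers
# ---------------------------------------------------------------------------


def _scene_height_field(scene: SceneTruth, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    cx, cy = scene.medium_center_xy
    inside = np.hypot(x - cx, y - cy) <= scene.medium_radius_mm
    sx, sy = scene.medium_tilt
    medium = scene.medium_height_mm + sx * (x - cx) + sy * (y - cy)
    h = np.where(inside, medium, 0.0)
    for p in scene.plants:
        h = h + np.where(inside, p.height_at(x, y), 0.0)
    return h


def render_depth(
    scene: SceneTruth,
    cal: LaserCalibration,
    pitch_mm: float = 1.0,
    extent_mm: float = SCAN_EXTENT_MM,
) -> DepthGrid:
    """Render the raw laser-scan raster of a scene.

    The noiseless height field (cultivation surface at 0, tilted medium
    plane inside the disk, plant blobs on top) is perturbed with Gaussian
    noise of ``scene.noise_sd_mm`` and inverted through the calibration to
    raw readouts. Points whose local surface slope exceeds
    ``scene.dropout_slope_threshold`` are dropped (invalid): the
    reflection-based sensor fails on steeply tilted surfaces, which in
    practice removes plant flanks and the medium rim.
    """
    n = int(round(extent_mm / pitch_mm))
    coords = (np.arange(n) + 0.5) * pitch_mm
    x, y = np.meshgrid(coords, coords)  # row=y, col=x
    h = _scene_height_field(scene, x, y)

    gy, gx = np.gradient(h, pitch_mm)
    slope = np.hypot(gx, gy)
    valid = slope <= scene.dropout_slope_threshold

    if scene.noise_sd_mm > 0:
        h = h + scene.rng("depth").normal(0.0, scene.noise_sd_mm, size=h.shape)

    raw = h / cal.slope + cal.zero_raw
    raw = np.where(valid, raw, np.nan)
    return DepthGrid(raw=raw, valid=valid, x_pitch_mm=pitch_mm, y_pitch_mm=pitch_mm)


def render_rgb(
    scene: SceneTruth,
    pm: PixelMetric,
    illumination: Literal["day", "night"] = "day",
    rgb_noise_sd: float = 2.0 / 255.0,
    night_scale: float = 0.05,
) -> tuple[VesselImage, np.ndarray]:
    """Render the top-down RGB view and the exact boolean plant mask.

    The medium is an opaque whitish disk (the TiO2-opacified look),
    plants are green blobs, the background is dark. Night frames are the
    day radiance scaled by ``night_scale`` before sensor noise, so mean
    intensity separates day from night cleanly.
    """
    npx = int(round(SCAN_EXTENT_MM * pm.pixels_per_mm))
    coords = (np.arange(npx) + 0.5) / pm.pixels_per_mm
    x, y = np.meshgrid(coords, coords)
    cx, cy = scene.medium_center_xy

    img = np.empty((npx, npx, 3), dtype=float)
    img[..., 0], img[..., 1], img[..., 2] = 28.0, 24.0, 22.0  # dark shelf
    inside = np.hypot(x - cx, y - cy) <= scene.medium_radius_mm
    for c, v in enumerate((228.0, 230.0, 212.0)):  # opaque white-greenish medium
        img[..., c][inside] = v
    # gentle radial illumination falloff of the ring light
    falloff = 1.0 - 0.15 * (np.hypot(x - cx, y - cy) / SCAN_EXTENT_MM) ** 2
    img *= falloff[..., None]

    mask = np.zeros((npx, npx), dtype=bool)
    for p in scene.plants:
        foot = np.hypot(x - p.center_xy[0], y - p.center_xy[1]) <= p.radius_mm
        mask |= foot
        for c in range(3):
            img[..., c][foot] = p.color[c] * falloff[foot]

    if illumination == "night":
        img = img * night_scale

    rng = scene.rng("rgb")
    img = img + rng.normal(0.0, rgb_noise_sd * 255.0, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return VesselImage(pixels, illumination=illumination, pixel_metric=pm), mask


def render_spectrum(
    scene: SceneTruth,
    has_plant_in_spot: bool,
    amplitudes: tuple[float, float] = (320.0, 320.0),
    excitation_amplitude: float = 180.0,
    dark_level: float = 28.0,
    dark_noise_sd: float = 2.0,
) -> Spectrum:
    """Render one fluorescence spectrometer readout.

    Baseline dark current plus a Gaussian excitation leak at 375 nm; when
    a plant sits in the detection spot, the chlorophyll emission doublet
    appears as Gaussians at 690 and 735 nm with the given amplitudes.
    Counts are quantised to the 10-bit ADC range [0, 1023].
    """
    wl = default_wavelengths().astype(float)
    rng = scene.rng("spectrum")
    counts = dark_level + rng.normal(0.0, dark_noise_sd, size=wl.shape)
    counts += excitation_amplitude * np.exp(-0.5 * ((wl - 375.0) / 8.0) ** 2)
    if has_plant_in_spot:
        a690, a735 = amplitudes
        counts += a690 * np.exp(-0.5 * ((wl - 690.0) / 11.0) ** 2)
        counts += a735 * np.exp(-0.5 * ((wl - 735.0) / 13.0) ** 2)
    counts = np.clip(np.rint(counts), 0, 1023)
    return Spectrum(counts, wl.astype(int), integration_time_ms=300.0)


def render_thermal(
    scene: SceneTruth,
    plant_temp_c: float = 24.0,
    background_temp_c: float = 21.5,
    foil: bool = False,
    noise_sd_c: float = 0.0,
    foil_contrast: float = 0.35,
    foil_offset_c: float = 0.8,
) -> ThermalFrame:
    """Render a 160 x 120 radiometric thermal frame of the scene.

    Plant footprints take ``plant_temp_c`` (transpirational cooling keeps
    them below ambient under the lamps), everything else
    ``background_temp_c``. A sealing foil in the optical path compresses
    the contrast toward the scene mean by ``foil_contrast`` and adds a
    radiometric offset, reproducing the weak plant/background separation
    seen through foil-sealed vessels. raw = round(100 * (T + 273.15)).
    """
    rows, cols = THERMAL_SHAPE
    xs = (np.arange(cols) + 0.5) * (SCAN_EXTENT_MM / cols)
    ys = (np.arange(rows) + 0.5) * (SCAN_EXTENT_MM / rows)
    x, y = np.meshgrid(xs, ys)
    t = np.full((rows, cols), background_temp_c, dtype=float)
    for p in scene.plants:
        foot = np.hypot(x - p.center_xy[0], y - p.center_xy[1]) <= p.radius_mm
        t[foot] = plant_temp_c
    if noise_sd_c > 0:
        t = t + scene.rng("thermal").normal(0.0, noise_sd_c, size=t.shape)
    if foil:
        t = t.mean() + foil_contrast * (t - t.mean()) + foil_offset_c
    raw = np.rint(100.0 * (t + 273.15)).astype(np.int64)
    return ThermalFrame(raw=raw, foil_present=foil)


# ---------------------------------------------------------------------------
# Scene factories
# ---------------------------------------------------------------------------


def default_scene(seed: int = 0, n_plants: int = 4) -> SceneTruth:
    """The nominal four-explant vessel scene used throughout the tests."""
    rng = np.random.default_rng([int(seed), 99])
    plants = []
    offsets = [(-15.0, -15.0), (15.0, -15.0), (-15.0, 15.0), (15.0, 15.0)]
    for i in range(n_plants):
        ox, oy = offsets[i % 4]
        jitter = rng.uniform(-4.0, 4.0, size=2)
        plants.append(
            PlantBlob(
                center_xy=(50.0 + ox + jitter[0], 50.0 + oy + jitter[1]),
                radius_mm=float(rng.uniform(6.0, 9.0)),
                max_height_mm=float(rng.uniform(8.0, 14.0)),
                shape="hemisphere",
                color=(
                    int(rng.integers(35, 70)),
                    int(rng.integers(105, 150)),
                    int(rng.integers(40, 75)),
                ),
            )
        )
    return SceneTruth(plants=plants, seed=int(seed))


def random_scene(seed: int) -> SceneTruth:
    """A randomly varied scene: tilted medium, variable height and plants."""
    rng = np.random.default_rng([int(seed), 98])
    scene = default_scene(seed=seed, n_plants=int(rng.integers(2, 5)))
    scene.medium_height_mm = float(rng.uniform(15.0, 24.0))
    scene.medium_tilt = (float(rng.uniform(-0.02, 0.02)), float(rng.uniform(-0.02, 0.02)))
    return scene
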
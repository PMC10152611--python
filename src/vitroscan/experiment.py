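"""Desk-scale analogue of the acquisition loop.

An experiment is a directory tree with one subfolder per culture vessel
holding per-timepoint sensor files (RGB PNG, depth CSV, thermal TIFF,
night fluorescence spectrum CSV) plus a calibration JSON at the root.
:func:`make_fixtures` writes a fully synthetic experiment with ground
truth; :func:`run_experiment` walks the tree the way the acquisition
loop would — night detection, segmentation and traits, depth pipeline
where a scan exists, thermal statistics — and appends tidy trait rows.
Re-running skips rows that already exist.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as vio
from .calibration import (
    DEFAULT_ZERO_RAW,
    LaserCalibration,
    PixelMetric,
    load_calibration,
    save_calibration,
)
from .depth import process_depth_scan
from .metrics import confusion_stats
from .rgb import PixelClassifier, extract_traits, is_night, segment, train_pixel_classifier
from .spectral import fluorescence_summary, mask_band, mean_dark, subtract_dark
from .synth import SceneTruth, default_scene, random_scene, render_depth, render_rgb, render_spectrum, render_thermal
from .thermal import contrast_index, frame_stats

__all__ = ["ExperimentLayout", "make_fixtures", "run_experiment", "train_classifier_from_truth"]

log = logging.getLogger(__name__)

TRAIT_COLUMNS = ["vessel_id", "timestamp", "sensor", "trait", "value", "unit", "quality"]
SCHEMA_VERSION = 1


@dataclasses.dataclass
class ExperimentLayout:
    """Index of an experiment tree: vessels, timepoints, file naming."""

    root: Path
    vessels: list[str]
    timepoints: list[str]

    @classmethod
    def scan(cls, root: str | Path) -> "ExperimentLayout":
        root = Path(root)
        vessels = sorted(p.name for p in root.iterdir() if p.is_dir() and p.name.startswith("vessel_"))
        tps: set[str] = set()
        for v in vessels:
            for f in (root / v).glob("rgb_*.png"):
                tps.add(f.stem.split("_", 1)[1])
        return cls(root=root, vessels=vessels, timepoints=sorted(tps))

    def path(self, vessel: str, sensor: str, timepoint: str) -> Path:
        ext = {"rgb": "png", "truth": "png", "depth": "csv", "thermal": "tif",
               "spectrum": "csv", "scene": "json"}[sensor]
        name = {"truth": "truthmask", "scene": "scene"}.get(sensor, sensor)
        return self.root / vessel / f"{name}_{timepoint}.{ext}"


def _grown_scene(base: SceneTruth, frac: float, seed: int) -> SceneTruth:
    """Scale the base scene's plants to a growth fraction in (0, 1]."""
    plants = [
        dataclasses.replace(
            p,
            radius_mm=p.radius_mm * (0.4 + 0.6 * frac),
            max_height_mm=p.max_height_mm * frac,
        )
        for p in base.plants
    ]
    # media dry down slightly over the run
    return dataclasses.replace(
        base, plants=plants, seed=seed,
        medium_height_mm=base.medium_height_mm * (1.0 - 0.08 * frac),
    )


def make_fixtures(
    root: str | Path,
    seed: int = 0,
    n_vessels: int = 2,
    n_timepoints: int = 3,
    px_per_mm: float = 1.6,
    depth_every: int = 2,
    night_every: int = 3,
) -> ExperimentLayout:
    """Write a synthetic experiment tree with ground truth.

    Each vessel gets a randomised base scene whose plants grow over the
    timepoints; depth scans exist every ``depth_every`` timepoints
    (scanning is slow, so its cadence is lower than imaging) and every
    ``night_every``-th timepoint is a night frame with a fluorescence
    spectrum. Ground-truth masks, scene JSONs and a truth table are
    written alongside. Deterministic in ``seed``: identical trees on
    re-run.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    pm = PixelMetric(px_per_mm, reference_height_mm=20.0)
    cal = LaserCalibration(slope=0.01, intercept=-0.01 * DEFAULT_ZERO_RAW)
    save_calibration(root / "calibration.json", cal, pm)

    truth_rows = []
    vessels, tps = [], []
    for vi in range(n_vessels):
        vessel = f"vessel_{vi:02d}"
        vessels.append(vessel)
        vdir = root / vessel
        vdir.mkdir(exist_ok=True)
        base = random_scene(seed * 1000 + vi)
        for k in range(n_timepoints):
            tp = f"t{k:03d}"
            if vi == 0:
                tps.append(tp)
            frac = (k + 1) / n_timepoints
            scene = _grown_scene(base, frac, seed=seed * 1000 + vi * 100 + k)
            scene.to_json(vdir / f"scene_{tp}.json")
            night = night_every > 0 and (k % night_every == night_every - 1)
            img, mask = render_rgb(scene, pm, "night" if night else "day")
            vio.write_image_png(vdir / f"rgb_{tp}.png", img)
            vio.write_mask_png(vdir / f"truthmask_{tp}.png", mask)
            vio.write_thermal_tiff(
                vdir / f"thermal_{tp}.tif", render_thermal(scene, foil=True)
            )
            if k % depth_every == 0:
                vio.write_depth_csv(vdir / f"depth_{tp}.csv", render_depth(scene, cal))
            if night:
                from .spectral import write_spectrum_csv

                spec = render_spectrum(scene, has_plant_in_spot=len(scene.plants) > 0)
                write_spectrum_csv(vdir / f"spectrum_{tp}.csv", spec)
            truth_rows.append(
                {
                    "vessel_id": vessel,
                    "timestamp": tp,
                    "medium_height_mm": scene.medium_height_mm,
                    "n_plants": len(scene.plants),
                    "plant_area_mm2": float(
                        sum(np.pi * p.radius_mm**2 for p in scene.plants)
                    ),
                    "max_plant_height_mm": max(
                        (p.max_height_mm for p in scene.plants), default=0.0
                    ),
                    "illumination": "night" if night else "day",
                }
            )
    pd.DataFrame(truth_rows).to_csv(root / "truth.csv", index=False)
    return ExperimentLayout(root=root, vessels=vessels, timepoints=sorted(set(t for t in tps)))


def train_classifier_from_truth(
    layout: ExperimentLayout, n_images: int = 2, seed: int = 0
) -> PixelClassifier:
    """Train the pixel classifier from the tree's own truth masks.

    Stands in for the interactive partial labeling step: the first day
    image(s) of each vessel provide fully labeled pixels.
    """
    labeled = []
    for vessel in layout.vessels:
        picked = 0
        for tp in layout.timepoints:
            p = layout.path(vessel, "rgb", tp)
            if not p.exists() or picked >= n_images:
                continue
            img = vio.read_image_png(p)
            if is_night(img):
                continue
            mask = vio.read_mask_png(layout.path(vessel, "truth", tp))
            labeled.append((img, mask.astype(np.int8)))
            picked += 1
    return train_pixel_classifier(labeled, seed=seed)


def _existing_keys(out_csv: Path) -> set[tuple[str, str, str]]:
    if not out_csv.exists():
        return set()
    df = pd.read_csv(out_csv)
    return set(zip(df["vessel_id"], df["timestamp"], df["sensor"]))


def run_experiment(
    root: str | Path,
    classifier: PixelClassifier | None = None,
    out_csv: str | Path | None = None,
    seed: int = 0,
    night_threshold: float = 30.0,
) -> pd.DataFrame:
    """Process every vessel x timepoint of an experiment tree.

    For each timepoint: night detection; RGB segmentation and traits
    (day frames); fluorescence summary where a spectrum exists (night);
    depth pipeline where a scan exists (the medium circle is detected on
    each vessel's first scan and reused); thermal statistics. Appends
    tidy rows to ``out_csv`` and skips (vessel, timepoint, sensor) rows
    already present, so re-running a completed experiment adds nothing.
    Missing sensor files simply produce no rows; corrupted files are
    logged and skipped.
    """
    root = Path(root)
    layout = ExperimentLayout.scan(root)
    out_csv = root / "traits.csv" if out_csv is None else Path(out_csv)
    cal, pm = load_calibration(root / "calibration.json")
    if classifier is None:
        classifier = train_classifier_from_truth(layout, seed=seed)

    done = _existing_keys(out_csv)
    rows: list[dict] = []

    def add(vessel, tp, sensor, trait, value, unit, quality="ok"):
        rows.append(dict(zip(TRAIT_COLUMNS, (vessel, tp, sensor, trait, value, unit, quality))))

    for vessel in layout.vessels:
        day0_circle = None
        for tp in layout.timepoints:
            rgb_path = layout.path(vessel, "rgb", tp)
            if rgb_path.exists() and (vessel, tp, "rgb") not in done:
                try:
                    img = vio.read_image_png(rgb_path)
                    night = is_night(img, night_threshold)
                    add(vessel, tp, "rgb", "is_night", float(night), "bool")
                    if not night:
                        mask = segment(img, classifier)
                        tr = extract_traits(mask, pm)
                        add(vessel, tp, "rgb", "projected_area_px", tr.projected_area_px, "px")
                        add(vessel, tp, "rgb", "projected_area_mm2", tr.projected_area_mm2, "mm2")
                        add(vessel, tp, "rgb", "degree_of_coverage", tr.degree_of_coverage, "1")
                        add(vessel, tp, "rgb", "n_objects", tr.n_objects, "count")
                except Exception as exc:  # corrupted file: log, keep going
                    log.warning("skipping RGB %s/%s: %s", vessel, tp, exc)

            depth_path = layout.path(vessel, "depth", tp)
            if depth_path.exists() and (vessel, tp, "depth") not in done:
                try:
                    grid = vio.read_depth_csv(depth_path)
                    traits, model, _ = process_depth_scan(
                        grid, cal, day0_circle=day0_circle, seed=seed
                    )
                    day0_circle = (model.circle_center_px, model.circle_radius_px)
                    add(vessel, tp, "depth", "medium_height_mm", traits.medium_height_mm, "mm")
                    add(vessel, tp, "depth", "medium_volume_mm3", traits.medium_volume_mm3, "mm3")
                    add(vessel, tp, "depth", "avg_canopy_height_mm", traits.avg_canopy_height_mm, "mm",
                        "ok" if traits.avg_canopy_height_mm is not None else "missing")
                    add(vessel, tp, "depth", "max_plant_height_mm", traits.max_plant_height_mm, "mm",
                        "ok" if traits.max_plant_height_mm is not None else "missing")
                    add(vessel, tp, "depth", "projected_area_depth_mm2", traits.projected_area_depth_mm2, "mm2")
                except Exception as exc:
                    log.warning("skipping depth %s/%s: %s", vessel, tp, exc)

            spec_path = layout.path(vessel, "spectrum", tp)
            if spec_path.exists() and (vessel, tp, "spectrum") not in done:
                try:
                    from .spectral import read_spectrum_csv

                    spec = mask_band(read_spectrum_csv(spec_path))
                    res = fluorescence_summary(spec)
                    add(vessel, tp, "spectrum", "F690", res.F690, "counts")
                    add(vessel, tp, "spectrum", "F730", res.F730, "counts")
                    add(vessel, tp, "spectrum", "F740", res.F740, "counts")
                    add(vessel, tp, "spectrum", "ratio_F690_F740",
                        res.ratio_F690_F740, "1",
                        "ok" if res.ratio_F690_F740 is not None else "missing")
                except Exception as exc:
                    log.warning("skipping spectrum %s/%s: %s", vessel, tp, exc)

            th_path = layout.path(vessel, "thermal", tp)
            if th_path.exists() and (vessel, tp, "thermal") not in done:
                try:
                    frame = vio.read_thermal_tiff(th_path)
                    st = frame_stats(frame)
                    add(vessel, tp, "thermal", "mean_temp_c", st.mean_c, "degC")
                    add(vessel, tp, "thermal", "contrast_index_c", contrast_index(frame), "degC")
                except Exception as exc:
                    log.warning("skipping thermal %s/%s: %s", vessel, tp, exc)

    new = pd.DataFrame(rows, columns=TRAIT_COLUMNS)
    if out_csv.exists():
        if len(new):
            combined = pd.concat([pd.read_csv(out_csv), new], ignore_index=True)
        else:
            combined = pd.read_csv(out_csv)
    else:
        combined = new
    combined.to_csv(out_csv, index=False)
    return new
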
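"""RGB image processing: preprocessing, trainable pixel classification,
mask handling and trait extraction.

The pipeline mirrors routine top-down vessel imaging: histogram-stretch
the image, downscale by an integer factor to cut classification cost,
predict plant/background per pixel with a random forest over a fixed
14-feature bank, rescale the binary mask back to full resolution, then
measure per-object and cumulative traits (projected area, perimeter,
convex-hull area, solidity, stockiness, degree of coverage). Auxiliary
operations locate plant positions via Otsu thresholding of the hue
channel and detect night frames from mean intensity.

The 14-feature bank (documented, versioned) comprises: R, G, B, hue,
saturation, value (6); Gaussian-smoothed intensity at scales 1, 3.5 and
10 px (3); gradient magnitude at scales 1.6 and 5 px (2); Laplacian of
Gaussian at scales 1.6 and 5 px (2); and a difference of Gaussians
between scales 1.6 and 5 px (1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import measure
from sklearn.ensemble import RandomForestClassifier

from .calibration import PixelMetric, area_px_to_mm2
from .synth import VesselImage

__all__ = [
    "PlantMask",
    "TraitRecord",
    "PixelClassifier",
    "stretch_contrast",
    "downscale",
    "compute_features",
    "train_pixel_classifier",
    "segment",
    "extract_traits",
    "find_plant_positions",
    "otsu_threshold",
    "is_night",
    "FEATURE_NAMES",
]

FEATURE_NAMES = (
    "red", "green", "blue", "hue", "saturation", "value",
    "gauss_1.0", "gauss_3.5", "gauss_10.0",
    "grad_1.6", "grad_5.0",
    "laplace_1.6", "laplace_5.0",
    "dog_1.6_5.0",
)


def stretch_contrast(img: VesselImage, p_lo: float = 1.0, p_hi: float = 99.0) -> VesselImage:
    """Automated brightness/contrast adjustment by histogram stretching.

    Per channel, a linear map sends the ``p_lo``/``p_hi`` intensity
    percentiles to 0/255 with clipping; percentile anchors make the
    stretch robust to specular highlights. Constant channels pass through
    unchanged.
    """
    px = img.pixels.astype(float)
    out = px.copy()
    for c in range(3):
        lo, hi = np.percentile(px[..., c], [p_lo, p_hi])
        if hi > lo:
            out[..., c] = (px[..., c] - lo) * (255.0 / (hi - lo))
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return VesselImage(out, img.timestamp, img.illumination, img.pixel_metric)


def downscale(img: VesselImage, factor: int = 4) -> VesselImage:
    """Area-average downscaling by an integer factor.

    Each output pixel is the mean of a factor x factor block; a trailing
    remainder forms one narrower block averaged over the pixels it has,
    so a 4054 px side becomes 1014 px at factor 4. Block means are
    rounded half-even to 8 bit.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    px = img.pixels.astype(float)
    ri = np.arange(0, px.shape[0], factor)
    ci = np.arange(0, px.shape[1], factor)
    sums = np.add.reduceat(np.add.reduceat(px, ri, axis=0), ci, axis=1)
    rcount = np.diff(np.append(ri, px.shape[0]))
    ccount = np.diff(np.append(ci, px.shape[1]))
    counts = np.outer(rcount, ccount)[..., None]
    out = np.clip(np.rint(sums / counts), 0, 255).astype(np.uint8)
    return VesselImage(out, img.timestamp, img.illumination, img.pixel_metric)


def compute_features(pixels: np.ndarray) -> np.ndarray:
    """Per-pixel feature stack (rows, cols, 14) for the pixel classifier."""
    px = np.asarray(pixels, dtype=float) / 255.0
    hsv = skcolor.rgb2hsv(px)
    intensity = px.mean(axis=2)

    feats = [px[..., 0], px[..., 1], px[..., 2],
             hsv[..., 0], hsv[..., 1], hsv[..., 2]]
    for s in (1.0, 3.5, 10.0):
        feats.append(ndimage.gaussian_filter(intensity, s))
    for s in (1.6, 5.0):
        feats.append(ndimage.gaussian_gradient_magnitude(intensity, s))
    for s in (1.6, 5.0):
        feats.append(ndimage.gaussian_laplace(intensity, s))
    feats.append(
        ndimage.gaussian_filter(intensity, 1.6) - ndimage.gaussian_filter(intensity, 5.0)
    )
    return np.stack(feats, axis=-1)


@dataclass
class PixelClassifier:
    """Random-forest plant/background pixel classifier over the 14-feature bank."""

    model: RandomForestClassifier
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def predict_mask(self, pixels: np.ndarray) -> np.ndarray:
        feats = compute_features(pixels)
        flat = feats.reshape(-1, feats.shape[-1])
        pred = self.model.predict(flat)
        return pred.reshape(pixels.shape[:2]).astype(bool)

    def save(self, path: str | Path) -> None:
        """Model to a single binary file plus a JSON sidecar of the bank."""
        path = Path(path)
        joblib.dump(self.model, path)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"feature_bank": list(self.feature_names)}, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PixelClassifier":
        path = Path(path)
        model = joblib.load(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        names = tuple(json.loads(sidecar.read_text())["feature_bank"]) if sidecar.exists() else FEATURE_NAMES
        return cls(model, names)


def train_pixel_classifier(
    labeled: Sequence[tuple[VesselImage, np.ndarray]],
    n_estimators: int = 60,
    max_samples_per_class: int = 40000,
    seed: int = 0,
) -> PixelClassifier:
    """Train the random forest from partially labeled images.

    ``labeled`` pairs an image with an int8 label raster: 1 = plant,
    0 = background, -1 = unlabeled. Labels are pooled across images and
    subsampled per class to bound training cost.
    """
    xs, ys = [], []
    for img, labels in labeled:
        labels = np.asarray(labels)
        if labels.shape != img.pixels.shape[:2]:
            raise ValueError("label raster must be congruent with the image")
        feats = compute_features(img.pixels)
        sel = labels >= 0
        xs.append(feats[sel])
        ys.append(labels[sel])
    X = np.concatenate(xs)
    y = np.concatenate(ys)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both plant and background labels are required")

    rng = np.random.default_rng(seed)
    keep = []
    for c in classes:
        idx = np.nonzero(y == c)[0]
        if idx.size > max_samples_per_class:
            idx = rng.choice(idx, size=max_samples_per_class, replace=False)
        keep.append(idx)
    keep = np.concatenate(keep)
    model = RandomForestClassifier(
        n_estimators=n_estimators, n_jobs=1, random_state=seed, min_samples_leaf=2
    )
    model.fit(X[keep], y[keep])
    return PixelClassifier(model)


@dataclass
class PlantMask:
    """Binary plant mask with 8-connected labeled components."""

    mask: np.ndarray
    labels: np.ndarray
    n_components: int

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "PlantMask":
        mask = np.asarray(mask, dtype=bool)
        labels, n = measure.label(mask, connectivity=2, return_num=True)
        return cls(mask=mask, labels=labels, n_components=n)


def _upscale_nearest(mask: np.ndarray, shape: tuple[int, int], factor: int) -> np.ndarray:
    up = np.kron(mask, np.ones((factor, factor), dtype=bool))
    out = np.zeros(shape, dtype=bool)
    r = min(shape[0], up.shape[0])
    c = min(shape[1], up.shape[1])
    out[:r, :c] = up[:r, :c]
    return out


def segment(
    img: VesselImage, clf: PixelClassifier, factor: int = 4, min_object_px: int = 64
) -> PlantMask:
    """Segment plant pixels: classify at reduced resolution, rescale mask.

    The image is histogram-stretched and block-mean downscaled by
    ``factor``; the classifier predicts at that resolution; the binary
    mask is rescaled to the original size by nearest neighbour
    (preserving binarity) and labeled with 8-connectivity. Components
    below ``min_object_px`` (full-resolution pixels) are speckle from
    isolated misclassified pixels and are removed.
    """
    small = downscale(stretch_contrast(img), factor)
    mask_small = clf.predict_mask(small.pixels)
    mask = _upscale_nearest(mask_small, img.pixels.shape[:2], factor)
    pm = PlantMask.from_mask(mask)
    if min_object_px > 0 and pm.n_components:
        sizes = np.bincount(pm.labels.ravel())
        drop = np.nonzero(sizes < min_object_px)[0]
        if drop.size:
            mask = mask & ~np.isin(pm.labels, drop[drop > 0])
            pm = PlantMask.from_mask(mask)
    return pm


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

_SQRT2 = float(np.sqrt(2.0))
# Moore neighbourhood in clockwise order starting east
_MOORE = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


def _chain_perimeter(component: np.ndarray) -> float:
    """8-connected boundary contour length; diagonal steps weigh sqrt(2).

    Moore-neighbour boundary tracing on a padded crop. Single-pixel and
    single-line objects degenerate to short chains; a lone pixel is
    assigned perimeter 4 (its free edges).
    """
    comp = np.pad(np.asarray(component, dtype=bool), 1)
    pts = np.argwhere(comp)
    if pts.shape[0] == 1:
        return 4.0
    start = tuple(pts[np.lexsort((pts[:, 1], pts[:, 0]))][0])
    length = 0.0
    prev_dir = 6  # came from the north (scan order guarantees nothing above)
    cur = start
    while True:
        # search the Moore neighbourhood clockwise from the backtrack direction
        found = None
        for k in range(8):
            d = (prev_dir + 1 + k) % 8
            nxt = (cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1])
            if comp[nxt]:
                found = (nxt, d)
                break
        if found is None:  # isolated pixel among pts (shouldn't happen per component)
            return 4.0
        nxt, d = found
        length += _SQRT2 if d % 2 else 1.0
        prev_dir = (d + 4 + 1) % 8  # backtrack, advanced by one
        if nxt == start and cur != start:
            break
        cur = nxt
        if length > 8 * comp.size:  # safety against pathological loops
            break
    return length


@dataclass
class TraitRecord:
    """Morphometric traits of one segmented image (per object + cumulative)."""

    projected_area_px: float
    projected_area_mm2: float | None
    perimeter_px: float
    convex_hull_area_px: float
    solidity: float | None
    stockiness: float | None
    degree_of_coverage: float
    n_objects: int
    per_object: list[dict] = field(default_factory=list)


def extract_traits(mask: PlantMask, pm: PixelMetric | None = None) -> TraitRecord:
    """Measure per-object and cumulative traits of a plant mask.

    area = pixel count; perimeter = 8-connected boundary chain length;
    solidity = area / convex hull area; stockiness = 4 pi area /
    perimeter**2 (a compactness index, 1 for an ideal disk); degree of
    coverage = plant pixels / total pixels. Metric areas via the pixel
    pitch when given. An empty mask yields a zeroed record.
    """
    total_px = mask.mask.size
    cum_area = float(np.count_nonzero(mask.mask))
    per_object = []
    cum_perimeter = 0.0
    cum_hull = 0.0
    for region in measure.regionprops(mask.labels):
        area = float(region.area)
        perim = _chain_perimeter(region.image)
        hull = float(region.area_convex)
        per_object.append(
            {
                "object_id": int(region.label),
                "area_px": area,
                "area_mm2": None if pm is None else area_px_to_mm2(pm, area),
                "perimeter_px": perim,
                "convex_hull_area_px": hull,
                "solidity": area / hull if hull > 0 else None,
                "stockiness": (4.0 * np.pi * area / perim**2) if perim > 0 else None,
                "centroid_rc": tuple(float(v) for v in region.centroid),
            }
        )
        cum_perimeter += perim
        cum_hull += hull
    return TraitRecord(
        projected_area_px=cum_area,
        projected_area_mm2=None if pm is None else area_px_to_mm2(pm, cum_area),
        perimeter_px=cum_perimeter,
        convex_hull_area_px=cum_hull,
        solidity=(cum_area / cum_hull) if cum_hull > 0 else None,
        stockiness=(4.0 * np.pi * cum_area / cum_perimeter**2) if cum_perimeter > 0 else None,
        degree_of_coverage=cum_area / total_px,
        n_objects=len(per_object),
        per_object=per_object,
    )


# ---------------------------------------------------------------------------
# Plant positions and night detection
# ---------------------------------------------------------------------------


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> int:
    """Otsu's threshold by exhaustive between-class-variance maximisation.

    ``values`` are integers in [0, n_bins). Returns the bin index t that
    maximises the between-class variance of the split {<= t} / {> t};
    ties resolve to the smallest t.
    """
    hist = np.bincount(np.asarray(values, dtype=np.int64).ravel(), minlength=n_bins)
    p = hist.astype(float) / max(hist.sum(), 1)
    bins = np.arange(n_bins, dtype=float)
    w0 = np.cumsum(p)
    mu = np.cumsum(p * bins)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * w0 - mu) ** 2 / (w0 * (1.0 - w0))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return int(np.argmax(sigma_b))


def find_plant_positions(
    img: VesselImage,
    motion_xy: tuple[float, float],
    pm: PixelMetric,
    max_objects: int = 4,
    min_area_px: int = 16,
) -> list[tuple[float, float]]:
    """Locate up to ``max_objects`` plants for targeted point measurements.

    The image is converted to hue-saturation-value space, the hue channel
    (quantised to 256 bins) is thresholded with Otsu's method, and the
    largest above-threshold components are taken as plants. Positions are
    the gantry position plus the pixel offset of each object centroid
    from the image midpoint, converted to mm (x = columns, y = rows).
    """
    hsv = skcolor.rgb2hsv(img.pixels.astype(float) / 255.0)
    hue = np.clip(np.rint(hsv[..., 0] * 255.0), 0, 255).astype(np.int64)
    t = otsu_threshold(hue)
    fg = hue > t
    labels, _ = measure.label(fg, connectivity=2, return_num=True)
    regions = [r for r in measure.regionprops(labels) if r.area >= min_area_px]
    regions.sort(key=lambda r: r.area, reverse=True)
    mid_r = (img.pixels.shape[0] - 1) / 2.0
    mid_c = (img.pixels.shape[1] - 1) / 2.0
    out = []
    for r in regions[:max_objects]:
        cr, cc = r.centroid
        out.append(
            (
                motion_xy[0] + (cc - mid_c) / pm.pixels_per_mm,
                motion_xy[1] + (cr - mid_r) / pm.pixels_per_mm,
            )
        )
    return out


def is_night(img: VesselImage, threshold: float = 30.0) -> bool:
    """Night when the mean intensity over all channels is strictly below threshold."""
    return bool(img.pixels.astype(float).mean() < threshold)
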
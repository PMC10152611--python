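"""Thermal frame processing.

The radiometric thermal camera delivers 14-bit raw grayscale frames
(160 x 120). Raw counts convert to Celsius by the manufacturer relation
``T = raw / 100 - 273.15``, exactly invertible on the integer raw grid.
Processing is diagnostic only — per-frame statistics, histograms at the
sensor's 0.05 degC thermal sensitivity, a percentile-based contrast index
(sealing foil in the optical path visibly compresses plant/background
separation), and false-color export. No plant/background segmentation is
defined on thermal data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import ThermalFrame

__all__ = [
    "raw_to_celsius",
    "celsius_to_raw",
    "frame_stats",
    "contrast_index",
    "is_flat_field_frame",
    "FrameStats",
]

THERMAL_SENSITIVITY_C = 0.05


def raw_to_celsius(raw) -> np.ndarray:
    """Convert 14-bit raw counts to degrees Celsius: raw/100 - 273.15."""
    return np.asarray(raw, dtype=float) / 100.0 - 273.15


def celsius_to_raw(t_c) -> np.ndarray:
    """Inverse conversion, rounded to the integer raw grid."""
    return np.rint(100.0 * (np.asarray(t_c, dtype=float) + 273.15)).astype(np.int64)


@dataclass(frozen=True)
class FrameStats:
    mean_c: float
    min_c: float
    max_c: float
    bin_edges_c: np.ndarray
    histogram: np.ndarray
    n_implausible: int  # pixels at/below 0 raw or beyond 14 bit


def frame_stats(frame: ThermalFrame, bin_width_c: float = THERMAL_SENSITIVITY_C) -> FrameStats:
    """Per-frame temperature statistics and histogram.

    The histogram uses the stated bin width (default the sensor's
    0.05 degC sensitivity) and conserves mass: its counts sum to the
    pixel count.
    """
    if frame.raw.size == 0:
        raise ValueError("empty frame")
    t = raw_to_celsius(frame.raw)
    if not np.all(np.isfinite(t)):
        raise ValueError("frame contains non-finite values")
    lo = np.floor(t.min() / bin_width_c) * bin_width_c
    hi = np.ceil(t.max() / bin_width_c) * bin_width_c
    nbins = max(int(round((hi - lo) / bin_width_c)), 1)
    hist, edges = np.histogram(t, bins=nbins, range=(lo, lo + nbins * bin_width_c))
    return FrameStats(
        mean_c=float(t.mean()),
        min_c=float(t.min()),
        max_c=float(t.max()),
        bin_edges_c=edges,
        histogram=hist,
        n_implausible=int(np.count_nonzero(frame.overrange | (frame.raw <= 0))),
    )


def contrast_index(frame: ThermalFrame) -> float:
    """Temperature spread between the 95th and 5th percentile pixels (degC).

    Quantifies how well plant and background separate thermally; frames
    taken through a sealing foil score lower than foil-free frames.
    """
    t = raw_to_celsius(frame.raw)
    p5, p95 = np.percentile(t, [5, 95])
    return float(p95 - p5)


def is_flat_field_frame(frame: ThermalFrame) -> bool:
    """Flag frames caught mid flat-field calibration (all pixels equal)."""
    return bool(np.all(frame.raw == frame.raw.flat[0]))
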
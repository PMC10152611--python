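"""Readers and writers for the on-disk sensor formats.

Depth grids travel as long-format CSV (x_mm, y_mm, raw) or 16-bit TIFF;
RGB images and masks as PNG; thermal frames as 16-bit TIFF; traits as a
tidy CSV. Dropout points are NaN in CSV and 0 in integer TIFFs.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .synth import DepthGrid, ThermalFrame, VesselImage

__all__ = [
    "write_depth_csv", "read_depth_csv",
    "write_depth_tiff", "read_depth_tiff",
    "write_image_png", "read_image_png",
    "write_mask_png", "read_mask_png",
    "write_thermal_tiff", "read_thermal_tiff",
]


def write_depth_csv(path: str | Path, grid: DepthGrid) -> None:
    rows, cols = grid.raw.shape
    cc, rr = np.meshgrid(np.arange(cols), np.arange(rows))
    df = pd.DataFrame(
        {
            "x_mm": (cc.ravel() + 0.5) * grid.x_pitch_mm,
            "y_mm": (rr.ravel() + 0.5) * grid.y_pitch_mm,
            "raw": np.where(grid.valid, grid.raw, np.nan).ravel(),
        }
    )
    df.to_csv(path, index=False)


def read_depth_csv(path: str | Path) -> DepthGrid:
    df = pd.read_csv(path)
    xs = np.sort(df["x_mm"].unique())
    ys = np.sort(df["y_mm"].unique())
    x_pitch = float(np.diff(xs).mean()) if xs.size > 1 else 1.0
    y_pitch = float(np.diff(ys).mean()) if ys.size > 1 else 1.0
    raw = (
        df.pivot(index="y_mm", columns="x_mm", values="raw")
        .reindex(index=ys, columns=xs)
        .to_numpy()
    )
    return DepthGrid(raw=raw, valid=np.isfinite(raw), x_pitch_mm=x_pitch, y_pitch_mm=y_pitch)


def write_depth_tiff(path: str | Path, grid: DepthGrid) -> None:
    # dropout encoded as 0; raw readouts are strictly positive in practice
    data = np.where(grid.valid & np.isfinite(grid.raw), grid.raw, 0.0)
    tifffile.imwrite(path, np.clip(np.rint(data), 0, 2**16 - 1).astype(np.uint16))


def read_depth_tiff(path: str | Path, x_pitch_mm: float = 1.0, y_pitch_mm: float = 1.0) -> DepthGrid:
    raw = tifffile.imread(path).astype(float)
    valid = raw > 0
    return DepthGrid(raw=np.where(valid, raw, np.nan), valid=valid,
                     x_pitch_mm=x_pitch_mm, y_pitch_mm=y_pitch_mm)


def write_image_png(path: str | Path, img: VesselImage) -> None:
    iio.imwrite(path, img.pixels)


def read_image_png(path: str | Path) -> VesselImage:
    return VesselImage(iio.imread(path))


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask_png(path: str | Path) -> np.ndarray:
    return iio.imread(path) > 127


def write_thermal_tiff(path: str | Path, frame: ThermalFrame) -> None:
    tifffile.imwrite(path, np.clip(frame.raw, 0, 2**16 - 1).astype(np.uint16))


def read_thermal_tiff(path: str | Path) -> ThermalFrame:
    return ThermalFrame(raw=tifffile.imread(path).astype(np.int64))
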
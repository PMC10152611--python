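"""Optical characterisation of vessel sealing materials.

Imaging through the closed vessel makes the sealing's light scattering a
primary image-quality factor. The haze index (ASTM D1003 style) is the
ratio of diffuse to total transmittance, minus the instrument's own
relative scattered transmittance, times 100; band-averaged transmittance
summarises suitability per spectral region (VIS 380-780 nm for the
cameras, 8000-14000 nm for the thermal sensor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TransmittanceSpectrum",
    "haze_index",
    "band_mean_transmittance",
    "VIS_BAND_NM",
    "THERMAL_BAND_NM",
]

VIS_BAND_NM = (380.0, 780.0)
THERMAL_BAND_NM = (8000.0, 14000.0)


@dataclass
class TransmittanceSpectrum:
    """Total and diffuse transmittance (%) over wavelength for one material."""

    wavelength_nm: np.ndarray
    total_pct: np.ndarray
    diffuse_pct: np.ndarray | None = None
    material: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.total_pct = np.asarray(self.total_pct, dtype=float)
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelengths must strictly increase")
        if self.diffuse_pct is not None:
            self.diffuse_pct = np.asarray(self.diffuse_pct, dtype=float)
            if self.diffuse_pct.shape != self.total_pct.shape:
                raise ValueError("diffuse and total must be congruent")

    @property
    def diffuse_exceeds_total(self) -> np.ndarray:
        """Physically impossible samples, flagged rather than silently fixed."""
        if self.diffuse_pct is None:
            return np.zeros_like(self.total_pct, dtype=bool)
        return self.diffuse_pct > self.total_pct

    @classmethod
    def from_csv(cls, path, material: str = "", replicate: int = 0) -> "TransmittanceSpectrum":
        df = pd.read_csv(path)
        return cls(
            df["wavelength_nm"].to_numpy(),
            df["total_pct"].to_numpy(),
            df["diffuse_pct"].to_numpy() if "diffuse_pct" in df else None,
            material=material,
            replicate=replicate,
        )


def haze_index(
    total_pct: float, diffuse_pct: float, system_scatter_fraction: float = 0.0
) -> float:
    """Haze index [%] = ((diffuse/total) - system scatter fraction) * 100.

    The instrument's relative scattered transmittance is an unpublished
    device constant, exposed as a parameter defaulting to 0; results are
    clipped below at 0 since negative haze is unphysical.
    """
    if total_pct <= 0:
        raise ValueError("total transmittance must be positive")
    return max((diffuse_pct / total_pct - system_scatter_fraction) * 100.0, 0.0)


def band_mean_transmittance(
    spec: TransmittanceSpectrum, lo_nm: float, hi_nm: float
) -> float:
    """Arithmetic mean of total transmittance over samples in [lo, hi] nm."""
    sel = (spec.wavelength_nm >= lo_nm) & (spec.wavelength_nm <= hi_nm)
    if not sel.any():
        raise ValueError("band outside the measured wavelength range")
    return float(spec.total_pct[sel].mean())
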
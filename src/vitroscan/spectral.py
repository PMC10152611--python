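"""Chlorophyll-fluorescence spectrum processing.

The micro spectrometer delivers 288 channels over 340-850 nm (about 15 nm
optical resolution, 10-bit counts). Fluorescence is measured at night
under 375 nm UV excitation through a 420 nm long-pass filter; processing
subtracts the mean dark-current spectrum, masks the 400-660 nm band
(residual room light and imperfectly blocked excitation), and summarises
the chlorophyll emission doublet: F690 (mostly photosystem II) and
F730/F740 (PSII and PSI). The F690/F740 ratio serves as a chlorophyll
content estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "FluorescenceResult",
    "map_wavelengths",
    "default_wavelengths",
    "mean_dark",
    "subtract_dark",
    "mask_band",
    "fluorescence_summary",
    "read_spectrum_csv",
    "write_spectrum_csv",
]

N_CHANNELS = 288
#: Synthetic linear wavelength map: 340 nm + 1.7726 nm/channel covers 340-849.
DEFAULT_COEFFICIENTS = (340.0, 1.7726, 0.0, 0.0, 0.0, 0.0)


def map_wavelengths(
    channel_indices, coefficients: Sequence[float] = DEFAULT_COEFFICIENTS
) -> np.ndarray:
    """Convert channel indices to integer wavelengths (nm).

    A 5th-degree polynomial in the channel index (six device-specific
    factory coefficients, lowest order first) evaluated and rounded
    half-up to integer nanometres. Factory coefficients are unpublished;
    the shipped default is a documented linear map over 340-850 nm.
    """
    idx = np.asarray(channel_indices, dtype=float)
    if len(coefficients) != 6:
        raise ValueError("six polynomial coefficients required")
    wl = np.polynomial.polynomial.polyval(idx, np.asarray(coefficients, dtype=float))
    return np.floor(wl + 0.5).astype(int)


def default_wavelengths() -> np.ndarray:
    return map_wavelengths(np.arange(N_CHANNELS))


@dataclass
class Spectrum:
    """A single 288-channel spectrometer readout."""

    counts: np.ndarray
    wavelengths_nm: np.ndarray = field(default_factory=default_wavelengths)
    integration_time_ms: float = 300.0
    kind: str = "fluorescence"  # dark | fluorescence | reflectance
    mask: np.ndarray | None = None  # True where excluded from analysis

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=int)
        if self.counts.shape != self.wavelengths_nm.shape:
            raise ValueError("counts and wavelengths must be congruent")
        if np.any(np.diff(self.wavelengths_nm) < 0):
            raise ValueError("wavelengths must be nondecreasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if not (self.integration_time_ms > 0):
            raise ValueError("integration time must be positive")

    @property
    def is_monotonic(self) -> bool:
        return bool(np.all(np.diff(self.wavelengths_nm) > 0))

    def channel_nearest(self, wavelength_nm: float) -> int:
        return int(np.argmin(np.abs(self.wavelengths_nm - wavelength_nm)))


def mean_dark(darks: Sequence[Spectrum]) -> Spectrum:
    """Channel-wise arithmetic mean of dark-current measurements."""
    if not darks:
        raise ValueError("no dark spectra given")
    counts = np.mean([d.counts for d in darks], axis=0)
    return Spectrum(
        counts,
        darks[0].wavelengths_nm.copy(),
        darks[0].integration_time_ms,
        kind="dark",
    )


def subtract_dark(spec: Spectrum, dark: Spectrum) -> Spectrum:
    """Subtract the mean dark spectrum; negative results clip to 0 counts."""
    if spec.counts.shape != dark.counts.shape:
        raise ValueError("spectra must be congruent")
    counts = np.clip(spec.counts - dark.counts, 0.0, None)
    return Spectrum(
        counts, spec.wavelengths_nm.copy(), spec.integration_time_ms, spec.kind,
        mask=None if spec.mask is None else spec.mask.copy(),
    )


def mask_band(spec: Spectrum, lo_nm: float = 400.0, hi_nm: float = 660.0) -> Spectrum:
    """Flag the [lo, hi] nm band as excluded (residual room/excitation light).

    Masking is idempotent; the masked channels are excluded from peak
    summaries downstream but their counts are preserved.
    """
    if lo_nm > hi_nm:
        raise ValueError("lo_nm must not exceed hi_nm")
    band = (spec.wavelengths_nm >= lo_nm) & (spec.wavelengths_nm <= hi_nm)
    mask = band if spec.mask is None else (spec.mask | band)
    return Spectrum(
        spec.counts.copy(), spec.wavelengths_nm.copy(),
        spec.integration_time_ms, spec.kind, mask=mask,
    )


@dataclass(frozen=True)
class FluorescenceResult:
    """Fluorescence peak summary of a dark-subtracted spectrum."""

    F690: float
    F730: float
    F740: float
    ratio_F690_F740: float | None
    f690_is_local_max: bool
    f730_is_local_max: bool
    f740_is_local_max: bool
    masked_band: tuple[float, float] = (400.0, 660.0)


def _is_local_max(spec: Spectrum, wavelength_nm: float, window_nm: float = 10.0) -> bool:
    # a genuine emission peak near the nominal wavelength puts the window
    # maximum strictly inside the window; a mere shoulder puts it on an edge
    near = np.nonzero(np.abs(spec.wavelengths_nm - wavelength_nm) <= window_nm)[0]
    if near.size < 3:
        return False
    peak = near[np.argmax(spec.counts[near])]
    return bool(near[0] < peak < near[-1])

def fluorescence_summary(spec: Spectrum) -> FluorescenceResult:
    """Summarise the chlorophyll fluorescence emission region (660-780 nm).

    F690/F730/F740 are the counts at the channel nearest each nominal
    wavelength (no interpolation: channel spacing is finer than the 15 nm
    optical resolution). The ratio F690/F740 is None when F740 is zero.
    A local-maximum check within +-10 nm is reported per band as a
    quality flag; with a single red peak the flags reveal which nominal
    band actually carries it.
    """
    f690 = float(spec.counts[spec.channel_nearest(690)])
    f730 = float(spec.counts[spec.channel_nearest(730)])
    f740 = float(spec.counts[spec.channel_nearest(740)])
    ratio = (f690 / f740) if f740 > 0 else None
    return FluorescenceResult(
        F690=f690,
        F730=f730,
        F740=f740,
        ratio_F690_F740=ratio,
        f690_is_local_max=_is_local_max(spec, 690),
        f730_is_local_max=_is_local_max(spec, 730),
        f740_is_local_max=_is_local_max(spec, 740),
    )


# ---------------------------------------------------------------------------
# CSV round trip: "# key=value" metadata header, then wavelength_nm,counts
# ---------------------------------------------------------------------------


def write_spectrum_csv(path: str | Path, spec: Spectrum) -> None:
    lines = [
        f"# integration_time_ms={spec.integration_time_ms}",
        f"# kind={spec.kind}",
        "wavelength_nm,counts",
    ]
    lines += [f"{w},{c:g}" for w, c in zip(spec.wavelengths_nm, spec.counts)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum_csv(path: str | Path) -> Spectrum:
    meta = {"integration_time_ms": 300.0, "kind": "fluorescence"}
    wl, counts = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            continue
        if line.startswith("wavelength"):
            continue
        w, c = line.split(",")
        wl.append(int(w))
        counts.append(float(c))
    return Spectrum(
        np.array(counts),
        np.array(wl),
        float(meta["integration_time_ms"]),
        str(meta["kind"]),
    )
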
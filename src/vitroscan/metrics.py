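"""Validation statistics for the phenotyping pipelines.

Covers the statistics used to characterise the platform: pixel-wise
confusion statistics for segmentation, ordinary-least-squares regression
reports with adjusted R**2 / MAE / RMSE / MRE for cross-pipeline
comparisons, and the repositioning repeatability MAE of the gantry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .calibration import PixelMetric, px_to_mm

__all__ = [
    "ConfusionCounts",
    "RegressionReport",
    "confusion_stats",
    "regression_report",
    "repositioning_mae",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-pair confusion counts; plant pixels are the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def precision(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    def as_dict(self) -> dict:
        return {
            **asdict(self),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
        }


def confusion_stats(pred, truth) -> ConfusionCounts:
    """Pixel-wise confusion counts between a predicted and a truth mask."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if pred.size == 0:
        raise ValueError("empty masks")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(tp, fp, fn, tn)


@dataclass(frozen=True)
class RegressionReport:
    """OLS regression of y on x plus agreement statistics of y vs x.

    adj_r2 is the conventional (Ezekiel) adjustment
    ``1 - (1 - R^2) (n - 1) / (n - p - 1)`` with p = 1 predictor.
    MRE is the signed mean of ``(y - x) / x`` in percent, so positive
    values mean y overestimates x.
    """

    slope: float
    intercept: float
    adj_r2: float
    mae: float
    rmse: float
    mre: float
    n: int
    p_slope: float | None
    p_intercept: float | None

    def as_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2))

    def __str__(self) -> str:  # human-readable one-pager
        return (
            f"n={self.n}  slope={self.slope:.4f}  intercept={self.intercept:.4f}\n"
            f"adj R2={self.adj_r2:.4f}  MAE={self.mae:.4f}  "
            f"RMSE={self.rmse:.4f}  MRE={self.mre:.2f}%"
        )


def regression_report(x, y) -> RegressionReport:
    """Fit y = slope*x + intercept by OLS and report agreement of y with x.

    Requires n >= 3 for coefficient t-tests; with n = 2 the point
    estimates are returned and the p-values are None.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least two observations")

    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0:
        raise ValueError("x is constant; slope undefined")
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = float(ym - slope * xm)

    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    adj_r2 = r2 if n <= 2 else 1.0 - (1.0 - r2) * (n - 1) / (n - 2)

    diff = y - x
    mae = float(np.mean(np.abs(diff)))
    rmse = float(np.sqrt(np.mean(diff**2)))
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(x != 0, diff / x, np.nan)
    mre = float(np.nanmean(rel) * 100.0)

    p_slope = p_intercept = None
    if n >= 3:
        dof = n - 2
        s2 = ss_res / dof
        se_slope = np.sqrt(s2 / sxx)
        se_inter = np.sqrt(s2 * (1.0 / n + xm**2 / sxx))
        if se_slope > 0:
            p_slope = float(2 * stats.t.sf(abs(slope / se_slope), dof))
        else:
            p_slope = 0.0 if slope != 0 else 1.0
        if se_inter > 0:
            p_intercept = float(2 * stats.t.sf(abs(intercept / se_inter), dof))
        else:
            p_intercept = 0.0 if intercept != 0 else 1.0

    return RegressionReport(
        slope=slope,
        intercept=intercept,
        adj_r2=float(adj_r2),
        mae=mae,
        rmse=rmse,
        mre=mre,
        n=n,
        p_slope=p_slope,
        p_intercept=p_intercept,
    )


def repositioning_mae(
    deviations_px: Sequence[float], pm: PixelMetric
) -> tuple[float, float]:
    """Repeatability MAE of gantry repositioning, in px and mm.

    ``deviations_px`` are per-event midpoint deviations from the day-0
    reference position along one axis.
    """
    dev = np.asarray(deviations_px, dtype=float)
    if dev.size == 0:
        raise ValueError("no deviations given")
    mae_px = float(np.mean(np.abs(dev)))
    return mae_px, px_to_mm(pm, mae_px)
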
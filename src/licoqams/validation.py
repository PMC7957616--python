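"""Chromatographic method-validation statistics.

Calibration linearity (ordinary least squares of area on concentration),
ICH-style detection/quantification limits (3.3 and 10 times the baseline
noise over the slope), replicate relative standard deviations, and
standard-addition spike recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "RecoveryResult",
    "fit_calibration",
    "lod_loq",
    "rsd_pct",
    "recovery",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear area-concentration calibration for one analyte.

    slope is in area units per ug/uL (== mg/mL), intercept in area units;
    linear_range, lod and loq are in ug/uL.
    """

    compound: str
    slope: float
    intercept: float
    r_squared: float
    linear_range: tuple[float, float]
    lod: Optional[float] = None
    loq: Optional[float] = None

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")
        lo, hi = self.linear_range
        if not lo < hi:
            raise ValueError("linear_range must satisfy low < high")
        if self.lod is not None and self.loq is not None and not self.lod < self.loq:
            raise ValueError("lod must be smaller than loq")

    def predict_area(self, conc):
        return self.slope * np.asarray(conc) + self.intercept


@dataclass(frozen=True)
class RecoveryResult:
    """Standard-addition recovery for one analyte."""

    compound: str
    recovery_pct: float
    rsd_pct: float

    def __post_init__(self) -> None:
        if self.recovery_pct <= 0:
            raise ValueError("recovery_pct must be > 0")


def fit_calibration(points: Sequence[tuple[float, float]],
                    compound: str = "analyte") -> CalibrationCurve:
    """Least-squares calibration line through (concentration, area) points.

    R^2 is the squared Pearson correlation.  With exactly two distinct
    points the line interpolates and R^2 is 1 by convention.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 (concentration, area) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("all concentrations identical; cannot fit a line")
    res = stats.linregress(x, y)
    r2 = 1.0 if len(x) == 2 else float(res.rvalue) ** 2
    return CalibrationCurve(
        compound=compound,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        linear_range=(float(x.min()), float(x.max())),
    )


def lod_loq(noise_sd: float, slope: float) -> tuple[float, float]:
    """Detection and quantification limits as 3.3*sigma/S and 10*sigma/S."""
    if noise_sd <= 0 or slope <= 0:
        raise ValueError("noise_sd and slope must both be > 0")
    return 3.3 * noise_sd / slope, 10.0 * noise_sd / slope


def rsd_pct(values: Sequence[float]) -> float:
    """Relative standard deviation: 100 x sample SD / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values for an RSD")
    m = v.mean()
    if m == 0:
        raise ValueError("mean is zero; RSD undefined")
    return 100.0 * v.std(ddof=1) / m


def recovery(spiked_measured: float, sample_measured: float,
             spiked_amount: float) -> float:
    """Spike recovery: 100 x (spiked - unspiked measurement) / amount added."""
    if spiked_amount <= 0:
        raise ValueError("spiked_amount must be > 0")
    return 100.0 * (spiked_measured - sample_measured) / spiked_amount
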
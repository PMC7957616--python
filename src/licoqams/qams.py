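"""Single-marker (QAMS) quantification via relative correction factors.

QAMS quantifies several analytes from one internal standard: a relative
correction factor ``f_m/k = (A_k * C_m) / (A_m * C_k)`` links analyte *m*'s
detector response to the internal standard *k*'s, so that one calibrated
marker (here glycyrrhizic acid) prices every co-eluting analyte in the same
chromatogram.  The external-standard method (ESM), one calibration curve per
analyte, serves as the reference the single-marker route is checked against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from statistics import mean, stdev
from typing import Optional, Sequence

__all__ = [
    "PeakRecord",
    "CorrectionFactorSummary",
    "SampleQuantification",
    "rcf_single",
    "rcf_summary",
    "correction_factors_from_records",
    "qams_content",
    "esm_content",
    "relative_error",
]


@dataclass(frozen=True)
class PeakRecord:
    """One chromatographic observation.

    Parameters
    ----------
    compound : str
        Analyte name.
    injection_volume_ul : float
        Injection volume in microlitres; must be positive.
    area : float
        Integrated peak area (detector units); must be non-negative.
    concentration_mg_ml : float, optional
        Known concentration for a standard injection (mg/mL); ``None``
        marks a sample injection.
    """

    compound: str
    injection_volume_ul: float
    area: float
    concentration_mg_ml: Optional[float] = None

    def __post_init__(self) -> None:
        if self.injection_volume_ul <= 0:
            raise ValueError(
                f"injection_volume_ul must be > 0, got {self.injection_volume_ul}")
        if self.area < 0:
            raise ValueError(f"area must be >= 0, got {self.area}")
        if self.concentration_mg_ml is not None and self.concentration_mg_ml <= 0:
            raise ValueError(
                f"concentration_mg_ml must be > 0 when present, "
                f"got {self.concentration_mg_ml}")

    @property
    def is_standard(self) -> bool:
        return self.concentration_mg_ml is not None


@dataclass(frozen=True)
class CorrectionFactorSummary:
    """Per-injection relative correction factors for one analyte with
    their mean and relative standard deviation."""

    compound_m: str
    internal_standard_k: str
    per_injection_f: dict[float, float]  # injection volume (uL) -> f
    mean_f: float
    rsd_pct: float

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.per_injection_f.values()):
            raise ValueError("every per-injection f must be > 0")


@dataclass(frozen=True)
class SampleQuantification:
    """Single-marker and (optionally) external-standard content of one
    analyte in one sample, with their relative error when both exist."""

    compound: str
    qams_content_pct: float
    sample_weight_g: float
    esm_content_pct: Optional[float] = None
    relative_error_pct: Optional[float] = field(default=None)

    def __post_init__(self) -> None:
        if self.qams_content_pct < 0:
            raise ValueError("contents must be >= 0")
        if self.relative_error_pct is not None and self.esm_content_pct is None:
            raise ValueError(
                "relative_error_pct requires both QAMS and ESM contents")


def _require_positive(**fields: float) -> None:
    for name, value in fields.items():
        if not value > 0:
            raise ValueError(f"{name} must be > 0, got {value}")


def rcf_single(area_k: float, conc_k: float, area_m: float, conc_m: float) -> float:
    """Relative correction factor of analyte *m* against internal standard *k*.

    ``f_m/k = (A_k * C_m) / (A_m * C_k)`` from one paired injection of the
    mixed reference solution.  All four inputs must be positive.
    """
    _require_positive(area_k=area_k, conc_k=conc_k, area_m=area_m, conc_m=conc_m)
    return (area_k * conc_m) / (area_m * conc_k)


def rcf_summary(
    series: Sequence[float],
    compound_m: str = "analyte",
    internal_standard_k: str = "internal standard",
    injection_volumes: Optional[Sequence[float]] = None,
) -> CorrectionFactorSummary:
    """Summarize a per-injection f series by its mean and sample-SD RSD.

    The RSD uses the n-1 (sample) standard deviation, the analytical
    convention; at least two values are required for it to be defined.
    """
    series = list(series)
    if len(series) < 2:
        raise ValueError("need at least 2 f values to define an RSD")
    if injection_volumes is None:
        injection_volumes = list(range(1, len(series) + 1))
    if len(injection_volumes) != len(series):
        raise ValueError("injection_volumes length must match series length")
    m = mean(series)
    return CorrectionFactorSummary(
        compound_m=compound_m,
        internal_standard_k=internal_standard_k,
        per_injection_f=dict(zip((float(v) for v in injection_volumes), series)),
        mean_f=m,
        rsd_pct=100.0 * stdev(series) / m,
    )


def correction_factors_from_records(
    records: Sequence[PeakRecord], internal_standard: str
) -> dict[str, CorrectionFactorSummary]:
    """Compute per-analyte correction-factor summaries from standard injections.

    Records are grouped by injection volume; each volume must contain a
    standard injection of the internal standard and of each analyte.
    """
    by_volume: dict[float, dict[str, PeakRecord]] = {}
    for rec in records:
        if not rec.is_standard:
            continue
        by_volume.setdefault(rec.injection_volume_ul, {})[rec.compound] = rec

    series: dict[str, dict[float, float]] = {}
    for volume in sorted(by_volume):
        group = by_volume[volume]
        if internal_standard not in group:
            raise ValueError(
                f"no standard injection of internal standard "
                f"{internal_standard!r} at volume {volume} uL")
        ref = group[internal_standard]
        for name, rec in group.items():
            if name == internal_standard:
                continue
            f = rcf_single(ref.area, ref.concentration_mg_ml,
                           rec.area, rec.concentration_mg_ml)
            series.setdefault(name, {})[volume] = f

    out = {}
    for name, per_vol in series.items():
        volumes = sorted(per_vol)
        out[name] = rcf_summary(
            [per_vol[v] for v in volumes],
            compound_m=name,
            internal_standard_k=internal_standard,
            injection_volumes=volumes,
        )
    return out


def _content_pct(conc_mg_ml: float, weight_g: float, extract_volume_ml: float) -> float:
    # mg analyte in the extract over mg of sample, as a percentage
    return conc_mg_ml * extract_volume_ml * 100.0 / (weight_g * 1000.0)


def qams_content(
    f: float,
    area_m: float,
    area_k: float,
    conc_k: float,
    weight_g: float,
    extract_volume_ml: float,
) -> float:
    """Single-marker content (% w/w) of analyte *m* in a sample.

    The analyte concentration in the extract is priced off the internal
    standard's sample peak: ``C_m = f * A_m * C_k / A_k`` (mg/mL), then
    converted to percent of sample mass through the extract volume:
    ``content% = C_m * V(mL) * 100 / (W(g) * 1000)``.

    Parameters
    ----------
    f : float
        Mean relative correction factor for this analyte (from
        :func:`rcf_summary`).
    area_m, area_k : float
        Sample peak areas of the analyte and the internal standard.
    conc_k : float
        Internal-standard concentration in the extract (mg/mL), typically
        from its own calibration curve.
    weight_g : float
        Sample weight W in grams.
    extract_volume_ml : float
        Extract volume in millilitres.
    """
    _require_positive(f=f, area_m=area_m, area_k=area_k, conc_k=conc_k,
                      weight_g=weight_g, extract_volume_ml=extract_volume_ml)
    conc_m = f * area_m * conc_k / area_k
    return _content_pct(conc_m, weight_g, extract_volume_ml)


def esm_content(curve, area: float, weight_g: float, extract_volume_ml: float) -> float:
    """External-standard content (% w/w) from an analyte's own calibration.

    Inverts ``area = slope * conc + intercept`` and applies the same
    mass-balance convention as :func:`qams_content`.  A warning is issued
    when the back-calculated concentration falls outside the curve's
    validated linearity range.
    """
    if curve.slope == 0:
        raise ValueError("calibration slope must be nonzero")
    _require_positive(weight_g=weight_g, extract_volume_ml=extract_volume_ml)
    conc = (area - curve.intercept) / curve.slope
    lo, hi = curve.linear_range
    if not (lo <= conc <= hi):
        warnings.warn(
            f"{curve.compound}: back-calculated concentration "
            f"{conc:.4g} mg/mL outside linearity range [{lo}, {hi}]",
            stacklevel=2)
    return _content_pct(conc, weight_g, extract_volume_ml)


def relative_error(qams: float, esm: float) -> float:
    """Signed percent difference of QAMS vs ESM: ``100 * (QAMS - ESM) / ESM``."""
    if esm == 0:
        raise ValueError("ESM content must be nonzero for a relative error")
    return 100.0 * (qams - esm) / esm
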
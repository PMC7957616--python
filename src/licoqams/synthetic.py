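"""Synthetic data generation for every stage of the pipeline.

Nothing in this analysis depends on a deposited dataset: standard and sample
chromatograms are simulated from the published linear calibration curves,
extraction-rate tables reproduce the published single-factor blocks exactly,
the 24-system DES screening panel is synthesized with the published ordinal
structure (the choline chloride / 1,3-butanediol systems on top), and
response surfaces are simulated from known quadratic coefficients for
parameter-recovery experiments.

One seeded :class:`numpy.random.Generator` is threaded through all
operations of a :class:`SyntheticGenerator`, so a fixed seed reproduces
every table byte for byte.

Default noise scales are the study's measurement conditions: multiplicative
peak-area noise of 0.5 % RSD (the mid-range of the reported instrument
precision RSDs, 0.33-1.05 %) and response-surface noise
sigma = 0.0164, the replicate (pure-error) scale of the published design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import study_data as sd
from .qams import PeakRecord
from .scoring import ExtractionTable
from .validation import CalibrationCurve

__all__ = ["GeneratorConfig", "SyntheticGenerator"]

#: Replicate-scale response noise (square root of the published pure-error
#: mean square).
DEFAULT_RESPONSE_SIGMA = 0.0164

#: Fractions of the linearity range at the five calibration levels,
#: following the 4/8/10/16/20 uL injection series (endpoints included).
_LEVEL_FRACTIONS = tuple((v - 4.0) / 16.0 for v in sd.INJECTION_VOLUMES_UL)


def default_calibrations() -> dict[str, CalibrationCurve]:
    """The published calibration curves as CalibrationCurve objects."""
    out = {}
    for name, p in sd.CALIBRATION_PARAMS.items():
        out[name] = CalibrationCurve(
            compound=name, slope=p["slope"], intercept=p["intercept"],
            r_squared=p["r_squared"], linear_range=p["range"],
            lod=p["lod"], loq=p["loq"])
    return out


def proportional_calibrations() -> dict[str, CalibrationCurve]:
    """Zero-intercept variants of the published curves.

    With strictly proportional responses the single-marker and
    external-standard routes agree to machine precision; the published
    nonzero intercepts introduce the small method bias that the relative
    error check quantifies.
    """
    out = {}
    for name, p in sd.CALIBRATION_PARAMS.items():
        out[name] = CalibrationCurve(
            compound=name, slope=p["slope"], intercept=0.0,
            r_squared=p["r_squared"], linear_range=p["range"],
            lod=p["lod"], loq=p["loq"])
    return out


@dataclass
class GeneratorConfig:
    """Conditions of the simulated experiments.

    multiplicative_rsd_pct is the peak-area noise (percent of the true
    area); additive_sd is an optional baseline noise in area units;
    design_truth holds the quadratic coefficients the response-surface
    simulator treats as ground truth.
    """

    seed: int = 0
    multiplicative_rsd_pct: float = 0.5
    additive_sd: float = 0.0
    calibrations: dict[str, CalibrationCurve] = field(
        default_factory=default_calibrations)
    design_truth: np.ndarray = field(
        default_factory=lambda: sd.PUBLISHED_QUADRATIC_COEFS.copy())
    response_sigma: float = DEFAULT_RESPONSE_SIGMA

    def __post_init__(self) -> None:
        if self.multiplicative_rsd_pct < 0 or self.additive_sd < 0:
            raise ValueError("noise scales must be >= 0")


class SyntheticGenerator:
    """Seeded generator for all synthetic inputs."""

    def __init__(self, config: Optional[GeneratorConfig] = None):
        self.config = config if config is not None else GeneratorConfig()
        self.rng = np.random.default_rng(self.config.seed)

    # -- noise ---------------------------------------------------------

    def _noisy_area(self, true_area: float, noiseless: bool) -> float:
        if noiseless:
            return true_area
        c = self.config
        area = true_area
        if c.multiplicative_rsd_pct > 0:
            area *= 1.0 + self.rng.normal(0.0, c.multiplicative_rsd_pct / 100.0)
        if c.additive_sd > 0:
            area += self.rng.normal(0.0, c.additive_sd)
        return area

    def _curve(self, compound: str) -> CalibrationCurve:
        try:
            return self.config.calibrations[compound]
        except KeyError:
            raise KeyError(
                f"no calibration parameters for compound {compound!r}") from None

    # -- calibration points -------------------------------------------

    def gen_calibration_points(self, compound: str, n_levels: int = 5,
                               noiseless: bool = False) -> list[tuple[float, float]]:
        """(concentration, area) points across the compound's linearity range.

        The default five levels sit at the fractions of the range implied by
        the 4/8/10/16/20 uL injection series, so both range endpoints are
        always present.
        """
        curve = self._curve(compound)
        lo, hi = curve.linear_range
        if n_levels == 5:
            fracs = np.array(_LEVEL_FRACTIONS)
        else:
            if n_levels < 2:
                raise ValueError("need at least 2 levels")
            fracs = np.linspace(0.0, 1.0, n_levels)
        concs = lo + (hi - lo) * fracs
        return [(float(x), self._noisy_area(float(curve.predict_area(x)), noiseless))
                for x in concs]

    # -- standard injections for correction factors -------------------

    def gen_standard_records(self, noiseless: bool = False) -> list[PeakRecord]:
        """Mixed-reference injections at the five volumes for all compounds.

        Peak area scales with the injected amount; the effective
        concentration at volume v is the mixed-reference concentration
        scaled by v/10 (10 uL being the nominal injection).
        """
        records = []
        for volume in sd.INJECTION_VOLUMES_UL:
            for name in sd.COMPOUNDS:
                curve = self._curve(name)
                conc = sd.MIXED_REFERENCE_MG_ML[name] * volume / 10.0
                area = self._noisy_area(float(curve.predict_area(conc)), noiseless)
                records.append(PeakRecord(
                    compound=name, injection_volume_ul=float(volume),
                    area=max(area, 0.0), concentration_mg_ml=conc))
        return records

    def gen_correction_factor_records(
            self, f_series: Optional[dict[str, Sequence[float]]] = None
    ) -> list[PeakRecord]:
        """Standard injections reconstructed from known per-injection f values.

        The internal standard's areas come from its calibration line; each
        analyte's area is back-solved from ``f = A_k C_m / (A_m C_k)`` so
        that recomputing the correction factors returns ``f_series``
        exactly (defaults to the study's measured series).
        """
        if f_series is None:
            f_series = {c: s for c, s in sd.CORRECTION_FACTOR_SERIES.items()}
        marker = sd.INTERNAL_STANDARD
        curve_k = self._curve(marker)
        records = []
        for i, volume in enumerate(sd.INJECTION_VOLUMES_UL):
            conc_k = sd.MIXED_REFERENCE_MG_ML[marker] * volume / 10.0
            area_k = float(curve_k.predict_area(conc_k))
            records.append(PeakRecord(
                compound=marker, injection_volume_ul=float(volume),
                area=area_k, concentration_mg_ml=conc_k))
            for name, series in f_series.items():
                conc_m = sd.MIXED_REFERENCE_MG_ML[name] * volume / 10.0
                area_m = area_k * conc_m / (series[i] * conc_k)
                records.append(PeakRecord(
                    compound=name, injection_volume_ul=float(volume),
                    area=area_m, concentration_mg_ml=conc_m))
        return records

    # -- sample chromatogram from known contents ----------------------

    def gen_sample_peak_table(self, true_contents: dict[str, float],
                              weight_g: float = 1.0,
                              volume_ml: float = 100.0,
                              noiseless: bool = False,
                              injection_volume_ul: float = 10.0
                              ) -> list[PeakRecord]:
        """Sample peak areas whose noiseless quantification returns
        ``true_contents`` (% w/w) exactly.

        Inverts the content convention (conc = content * 10 * W / V, mg/mL)
        and the calibration line.  Concentrations outside a compound's
        validated range are generated anyway with a warning.
        """
        records = []
        for name, content in true_contents.items():
            if content < 0:
                raise ValueError(f"negative content for {name!r}")
            curve = self._curve(name)
            conc = content * 10.0 * weight_g / volume_ml
            lo, hi = curve.linear_range
            if conc > 0 and not (lo <= conc <= hi):
                warnings.warn(
                    f"{name}: generated concentration {conc:.4g} mg/mL "
                    f"outside linearity range [{lo}, {hi}]", stacklevel=2)
            area = self._noisy_area(float(curve.predict_area(conc)), noiseless)
            records.append(PeakRecord(
                compound=name, injection_volume_ul=injection_volume_ul,
                area=max(area, 0.0), concentration_mg_ml=None))
        return records

    def method_comparison_contents(self, weight_g: float = 1.0,
                                   volume_ml: float = 100.0,
                                   fraction: float = 0.5) -> dict[str, float]:
        """Contents (% w/w) placing every analyte inside its linearity range.

        The QAMS/ESM agreement check is only meaningful where both methods
        are validated, so the comparison sample is generated at the given
        fraction of each compound's linearity range (0.5 = midpoint).
        """
        out = {}
        for name, curve in self.config.calibrations.items():
            lo, hi = curve.linear_range
            conc = lo + (hi - lo) * fraction
            out[name] = conc * volume_ml / (10.0 * weight_g)
        return out

    # -- extraction tables --------------------------------------------

    def gen_extraction_tables(self) -> dict[str, ExtractionTable]:
        """All extraction-rate blocks: the five published single-factor
        sweeps (exact) plus the synthetic 24-system DES screening panel."""
        tables = {}
        for group, rows in sd.SINGLE_FACTOR_RATES.items():
            labels = [r[0] for r in rows]
            rates = pd.DataFrame([r[1] for r in rows], index=labels,
                                 columns=list(sd.COMPOUNDS))
            sds = pd.DataFrame([r[2] for r in rows], index=labels,
                               columns=list(sd.COMPOUNDS))
            tables[group] = ExtractionTable(group_label=group, rates=rates, sds=sds)
        tables["DES screening"] = self.gen_screening_table()
        return tables

    def gen_screening_table(self) -> ExtractionTable:
        """Synthetic 24-system screening panel.

        The published screening figure prints no numbers, so only the
        ordinal structure is reproduced: the choline chloride /
        1,3-butanediol family extracts best, with its 1:5 system
        (DESs-14) on top.  Base rates are the published 30 %-water rates,
        scaled per system and jittered by at most 1 %.
        """
        base = np.array(sd.SINGLE_FACTOR_RATES["water content/%"][2][1])
        family_eff = {"Glycol": 0.80, "Glycerol": 0.76, "1,3-Butanediol": 0.92,
                      "Lactic acid": 0.85, "Urea": 0.65, "Malic acid": 0.72,
                      "Xylitol": 0.74}
        # molar-ratio effect peaks at 1:5 within the polyol families
        ratio_eff = {"1:1": 1.00, "1:2": 0.94, "1:3": 0.97, "1:4": 1.04,
                     "1:5": 1.08, "1:6": 1.01}
        labels, rows = [], []
        for label, hba, hbd, ratio in sd.DES_SYSTEMS:
            labels.append(f"{label} {hba} {hbd} {ratio}")
            scale = family_eff[hbd] * ratio_eff[ratio]
            jitter = 1.0 + self.rng.uniform(-0.01, 0.01, size=6)
            rows.append(np.round(base * scale * jitter, 4))
        rates = pd.DataFrame(rows, index=labels, columns=list(sd.COMPOUNDS))
        return ExtractionTable(group_label="DES screening", rates=rates)

    # -- response-surface simulation ----------------------------------

    def gen_bbd_responses(self, design, truth: Optional[Sequence[float]] = None,
                          sigma: Optional[float] = None) -> np.ndarray:
        """17 responses from a known quadratic truth plus Gaussian noise."""
        from .doe import model_matrix  # local import avoids a cycle
        beta = np.asarray(self.config.design_truth if truth is None else truth,
                          dtype=float)
        s = self.config.response_sigma if sigma is None else float(sigma)
        mean = model_matrix(design.coded_matrix) @ beta
        if s == 0:
            return mean
        return mean + self.rng.normal(0.0, s, size=mean.shape)
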
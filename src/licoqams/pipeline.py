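"""End-to-end analysis: correction factors -> scoring -> RSM -> validation.

`run_full_pipeline` reproduces the whole study from its embedded tables and
the synthetic generator: the single-marker correction factors, the QAMS/ESM
cross-check, screening and single-factor condition ranking, the
Box-Behnken quadratic fit with ANOVA and optimum, verification, and the
method-validation metrics.  All computation happens at full precision;
display rounding is applied only when rendering the report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import study_data as sd
from .doe import FactorDef, anova, bbd_design, fit_quadratic, optimize_in_box
from .qams import (correction_factors_from_records, esm_content, qams_content,
                   relative_error)
from .scoring import rank_conditions
from .synthetic import GeneratorConfig, SyntheticGenerator
from .validation import fit_calibration, lod_loq, recovery, rsd_pct

__all__ = ["PipelineConfig", "run_full_pipeline", "render_report"]


@dataclass
class PipelineConfig:
    internal_standard: str = sd.INTERNAL_STANDARD
    weights: tuple = tuple(1.0 / 6.0 for _ in range(6))
    display_decimals: int = 2
    seed: int = 0
    sample_weight_g: float = 1.0
    extract_volume_ml: float = 100.0
    generator: GeneratorConfig = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.internal_standard not in sd.COMPOUNDS:
            raise ValueError(
                f"internal standard {self.internal_standard!r} is not one of "
                f"the six compounds")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if self.generator is None:
            self.generator = GeneratorConfig(seed=self.seed)


def run_full_pipeline(config: PipelineConfig | None = None) -> dict:
    """Run every stage and return a JSON-serializable report."""
    cfg = config if config is not None else PipelineConfig()
    gen = SyntheticGenerator(cfg.generator)
    report: dict = {"seed": cfg.seed, "internal_standard": cfg.internal_standard}

    # 1. relative correction factors from standard injections
    standards = gen.gen_standard_records(noiseless=False)
    factors = correction_factors_from_records(standards, cfg.internal_standard)
    report["correction_factors"] = {
        name: {"mean_f": s.mean_f, "rsd_pct": s.rsd_pct,
               "per_injection_f": s.per_injection_f}
        for name, s in factors.items()}

    # 2. QAMS vs ESM cross-check on a sample placing every analyte inside
    #    its validated linearity range (method agreement is only defined
    #    where both calibrations hold)
    comparison = gen.method_comparison_contents(
        cfg.sample_weight_g, cfg.extract_volume_ml)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        sample = gen.gen_sample_peak_table(
            comparison, cfg.sample_weight_g, cfg.extract_volume_ml,
            noiseless=False)
        marker_curve = gen.config.calibrations[cfg.internal_standard]
        by_name = {r.compound: r for r in sample}
        marker = by_name[cfg.internal_standard]
        conc_k = (marker.area - marker_curve.intercept) / marker_curve.slope
        quant = {}
        for name in sd.COMPOUNDS:
            esm = esm_content(gen.config.calibrations[name], by_name[name].area,
                              cfg.sample_weight_g, cfg.extract_volume_ml)
            if name == cfg.internal_standard:
                qams = esm
            else:
                qams = qams_content(factors[name].mean_f, by_name[name].area,
                                    marker.area, conc_k, cfg.sample_weight_g,
                                    cfg.extract_volume_ml)
            quant[name] = {"qams_pct": qams, "esm_pct": esm,
                           "relative_error_pct": relative_error(qams, esm)}
    report["quantification"] = quant

    # 3. condition scoring and ranking
    tables = gen.gen_extraction_tables()
    report["rankings"] = {
        label: [(cond, z) for cond, z in rank_conditions(t, cfg.weights)]
        for label, t in tables.items()}

    # 4. response-surface analysis of the published 17-run design
    design = bbd_design([FactorDef(n, c, s) for n, c, s in sd.BBD_FACTORS])
    model = fit_quadratic(design, sd.BBD_RESPONSES)
    av = anova(model)
    opt = optimize_in_box(model)
    report["rsm"] = {
        "coefficients": dict(zip(
            ("Intercept", "A", "B", "C", "AB", "AC", "BC", "A2", "B2", "C2"),
            model.coefficients)),
        "anova": {name: {k: (None if isinstance(v, float) and np.isnan(v) else v)
                         for k, v in row.items()}
                  for name, row in av.table.to_dict("index").items()},
        "r_squared": av.r_squared,
        "adj_r_squared": av.adj_r_squared,
        "optimum": {
            "coded": list(opt.coded_point),
            "natural": dict(zip((f[0] for f in sd.BBD_FACTORS),
                                opt.natural_point)),
            "predicted_z": opt.predicted_response,
            "classification": opt.hessian_definiteness,
            "clipped_to_box": opt.clipped_to_box,
        },
    }

    # 5. verification runs at the adopted optimum (published composite scores)
    ver_z = [z for _, z in sd.VERIFICATION_RUNS]
    report["verification"] = {
        "per_run_z": ver_z,
        "mean_z": float(np.mean(ver_z)),
        "rsd_pct": rsd_pct(ver_z),
    }

    # 6. method validation on synthetic chromatograms
    validation = {}
    for name in sd.COMPOUNDS:
        pts = gen.gen_calibration_points(name)
        curve = fit_calibration(pts, compound=name)
        resid = np.array([a - curve.predict_area(x) for x, a in pts])
        noise_sd = float(resid.std(ddof=2)) if len(pts) > 2 else 0.0
        lod, loq = (lod_loq(noise_sd, curve.slope) if noise_sd > 0
                    else (None, None))
        # six replicate injections at the mixed-reference level
        level = sd.MIXED_REFERENCE_MG_ML[name]
        true_area = gen.config.calibrations[name].predict_area(level)
        reps = [gen._noisy_area(float(true_area), noiseless=False)
                for _ in range(6)]
        # standard-addition spike at 100 % of the native amount; the base
        # level sits low in the range so the doubled level stays inside it
        base = gen.method_comparison_contents(
            cfg.sample_weight_g, cfg.extract_volume_ml, fraction=0.25)[name]
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            unspiked = gen.gen_sample_peak_table(
                {name: base}, cfg.sample_weight_g, cfg.extract_volume_ml)[0]
            spiked = gen.gen_sample_peak_table(
                {name: 2 * base}, cfg.sample_weight_g, cfg.extract_volume_ml)[0]
            cv = gen.config.calibrations[name]
            meas = esm_content(cv, unspiked.area, cfg.sample_weight_g,
                               cfg.extract_volume_ml)
            meas_sp = esm_content(cv, spiked.area, cfg.sample_weight_g,
                                  cfg.extract_volume_ml)
        validation[name] = {
            "slope": curve.slope, "intercept": curve.intercept,
            "r_squared": curve.r_squared,
            "lod": lod, "loq": loq,
            "precision_rsd_pct": rsd_pct(reps),
            "recovery_pct": recovery(meas_sp, meas, base),
        }
    report["validation"] = validation
    return report


def _fmt_p(p: float | None) -> str:
    if p is None:
        return ""
    return "< 0.0001" if p < 1e-4 else f"{p:.4f}"


def render_report(report: dict, decimals: int = 2) -> str:
    """Human-readable report with the display-rounding conventions."""
    d = decimals
    lines = ["Licorice DES extraction analysis", "=" * 34, ""]
    lines.append("Relative correction factors (internal standard: "
                 f"{report['internal_standard']})")
    for name, s in report["correction_factors"].items():
        lines.append(f"  f[{name}] = {s['mean_f']:.{d}f} "
                     f"(RSD {s['rsd_pct']:.2f}%)")
    lines.append("")
    lines.append("QAMS vs external-standard contents (% w/w)")
    for name, q in report["quantification"].items():
        lines.append(f"  {name}: QAMS {q['qams_pct']:.3f}  ESM {q['esm_pct']:.3f}"
                     f"  RE {q['relative_error_pct']:+.2f}%")
    lines.append("")
    lines.append("Best condition per experimental block (composite score Z)")
    for label, ranking in report["rankings"].items():
        cond, z = ranking[0]
        lines.append(f"  {label}: {cond} (Z = {z:.{d}f})")
    lines.append("")
    rsm = report["rsm"]
    lines.append("Second-order model (coded units)")
    coef = rsm["coefficients"]
    lines.append("  Z = " + " ".join(
        f"{v:+.4g}{'' if t == 'Intercept' else t}" for t, v in coef.items()))
    lines.append(f"  R^2 = {rsm['r_squared']:.4f}   "
                 f"Adj R^2 = {rsm['adj_r_squared']:.4f}")
    lines.append("  ANOVA (partial SS):")
    for name, row in rsm["anova"].items():
        F = row["F"]
        lines.append(
            f"    {name:<12} SS={row['sum_sq']:.6g} df={row['df']}"
            + (f" F={F:.2f} p={_fmt_p(row['p'])}" if F is not None else ""))
    opt = rsm["optimum"]
    nat = opt["natural"]
    lines.append("  Optimum ({}):".format(opt["classification"]))
    for fname, value in nat.items():
        lines.append(f"    {fname} = {value:.{d}f}")
    lines.append(f"    predicted Z = {opt['predicted_z']:.{d}f}")
    lines.append("")
    ver = report["verification"]
    lines.append(f"Verification: mean Z = {ver['mean_z']:.{d}f} "
                 f"(RSD {ver['rsd_pct']:.2f}%)")
    lines.append("")
    lines.append("Method validation")
    for name, v in report["validation"].items():
        lod = f"{v['lod']:.5f}" if v["lod"] is not None else "n/a"
        loq = f"{v['loq']:.5f}" if v["loq"] is not None else "n/a"
        lines.append(
            f"  {name}: R^2={v['r_squared']:.4f} LOD={lod} LOQ={loq} "
            f"precision RSD={v['precision_rsd_pct']:.2f}% "
            f"recovery={v['recovery_pct']:.2f}%")
    return "\n".join(lines) + "\n"


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True, default=float)
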
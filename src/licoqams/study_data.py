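"""Published measurement tables from the licorice ultrasonic-DES extraction study.

All downstream analyses run off these printed tables: the per-injection
relative correction factors, the single-factor extraction-rate blocks, the
Box-Behnken design responses, the HPLC calibration curves, the verification
runs and the 24 candidate deep-eutectic-solvent (DES) systems.  Values are
stored exactly as printed (percent extraction rates, detector area units,
mg/mL == ug/uL concentrations); any transcription judgement calls are noted
inline.
"""

from __future__ import annotations

import numpy as np

#: Canonical analyte order used everywhere in this package.
COMPOUNDS = (
    "isoliquiritin apioside",
    "liquiritin",
    "isoliquiritin",
    "liquiritigenin",
    "glycyrrhizic acid",
    "glycyrrhetinic acid",
)

#: The single-marker internal standard.
INTERNAL_STANDARD = "glycyrrhizic acid"

#: Injection volumes (uL) of the mixed reference solution used for the
#: per-volume relative correction factors.
INJECTION_VOLUMES_UL = (4.0, 8.0, 10.0, 16.0, 20.0)

#: Stock standard concentrations (mg/mL) before the 10x dilution to the
#: mixed reference solution.
STOCK_CONCENTRATIONS_MG_ML = {
    "isoliquiritin apioside": 0.43,
    "liquiritin": 0.45,
    "isoliquiritin": 0.26,
    "liquiritigenin": 0.35,
    "glycyrrhizic acid": 0.56,
    "glycyrrhetinic acid": 0.22,
}

#: Mixed reference solution concentrations (mg/mL), a 10x dilution of stock.
MIXED_REFERENCE_MG_ML = {c: v / 10.0 for c, v in STOCK_CONCENTRATIONS_MG_ML.items()}

#: Per-injection relative correction factors f_m/k (glycyrrhizic acid as the
#: internal standard k), one five-value series per analyte m, keyed in
#: INJECTION_VOLUMES_UL order, plus the printed averages.
CORRECTION_FACTOR_SERIES = {
    "isoliquiritin apioside": (1.57, 1.60, 1.59, 1.61, 1.58),
    "liquiritin": (1.34, 1.33, 1.35, 1.34, 1.33),
    "isoliquiritin": (0.88, 0.87, 0.86, 0.87, 0.87),
    "liquiritigenin": (0.73, 0.71, 0.70, 0.71, 0.71),
    "glycyrrhetinic acid": (0.78, 0.80, 0.80, 0.77, 0.79),
}

CORRECTION_FACTOR_PRINTED_MEANS = {
    "isoliquiritin apioside": 1.59,
    "liquiritin": 1.34,
    "isoliquiritin": 0.87,
    "liquiritigenin": 0.71,
    "glycyrrhetinic acid": 0.79,
}

# ---------------------------------------------------------------------------
# Single-factor extraction experiments: per factor level, six extraction
# rates (% w/w of dry sample, in COMPOUNDS order), replicate SDs, and the
# study's printed composite score Z.
# ---------------------------------------------------------------------------

SINGLE_FACTOR_RATES = {
    "water content/%": [
        ("10", (0.59, 0.39, 0.08, 0.05, 1.62, 0.07),
         (0.0047, 0.0037, 0.0041, 0.0045, 0.0033, 0.0045), 0.84),
        ("20", (0.59, 0.41, 0.08, 0.04, 1.70, 0.07),
         (0.0065, 0.0042, 0.0044, 0.0044, 0.0040, 0.0042), 0.83),
        ("30", (0.66, 0.44, 0.10, 0.05, 1.83, 0.07),
         (0.0057, 0.0027, 0.0042, 0.0034, 0.0043, 0.0047), 0.95),
        ("40", (0.61, 0.42, 0.12, 0.03, 1.72, 0.05),
         (0.0036, 0.0045, 0.0045, 0.0027, 0.0034, 0.0040), 0.83),
        ("50", (0.66, 0.43, 0.14, 0.03, 1.73, 0.03),
         (0.0028, 0.0041, 0.0040, 0.0047, 0.0034, 0.0037), 0.82),
    ],
    "liquid to material ratio/mL/g": [
        ("10", (0.59, 0.40, 0.08, 0.03, 1.67, 0.12),
         (0.0032, 0.0033, 0.0034, 0.0044, 0.0050, 0.0033), 0.83),
        ("20", (0.64, 0.44, 0.10, 0.05, 1.83, 0.07),
         (0.0041, 0.0047, 0.0045, 0.0047, 0.0034, 0.0043), 0.91),
        ("30", (0.59, 0.40, 0.11, 0.03, 1.69, 0.07),
         (0.0023, 0.0033, 0.0029, 0.0029, 0.0035, 0.0040), 0.80),
        ("40", (0.62, 0.42, 0.09, 0.05, 1.71, 0.06),
         (0.0034, 0.0025, 0.0050, 0.0047, 0.0029, 0.0035), 0.83),
        ("50", (0.67, 0.44, 0.10, 0.05, 1.80, 0.07),
         (0.0043, 0.0050, 0.0047, 0.0050, 0.0040, 0.0036), 0.90),
    ],
    "extraction time/min": [
        ("20", (0.62, 0.42, 0.09, 0.03, 1.74, 0.06),
         (0.0033, 0.0045, 0.0037, 0.0042, 0.0047, 0.0037), 0.79),
        ("30", (0.62, 0.44, 0.10, 0.05, 1.87, 0.07),
         (0.0042, 0.0034, 0.0050, 0.0043, 0.0045, 0.0043), 0.90),
        ("40", (0.70, 0.47, 0.13, 0.03, 1.89, 0.07),
         (0.0034, 0.0033, 0.0039, 0.0048, 0.0038, 0.0042), 0.93),
        ("50", (0.60, 0.42, 0.11, 0.03, 1.74, 0.06),
         (0.0035, 0.0044, 0.0038, 0.0036, 0.0039, 0.0043), 0.82),
        ("60", (0.62, 0.43, 0.11, 0.03, 1.75, 0.07),
         (0.0045, 0.0023, 0.0037, 0.0039, 0.0034, 0.0040), 0.83),
    ],
    "extraction temperature/C": [
        ("30", (0.63, 0.42, 0.11, 0.03, 1.78, 0.04),
         (0.0044, 0.0045, 0.0045, 0.0036, 0.0039, 0.0045), 0.77),
        ("40", (0.60, 0.41, 0.06, 0.02, 1.72, 0.04),
         (0.0035, 0.0047, 0.0047, 0.0042, 0.0043, 0.0029), 0.64),
        ("50", (0.67, 0.43, 0.13, 0.03, 1.92, 0.12),
         (0.0043, 0.0042, 0.0049, 0.0037, 0.0032, 0.0034), 0.93),
        ("60", (0.67, 0.44, 0.10, 0.05, 1.83, 0.07),
         (0.0032, 0.0033, 0.0038, 0.0043, 0.0037, 0.0050), 0.89),
        ("70", (0.63, 0.44, 0.10, 0.05, 1.83, 0.07),
         (0.0033, 0.0043, 0.0042, 0.0044, 0.0040, 0.0043), 0.88),
        ("80", (0.63, 0.43, 0.13, 0.02, 1.85, 0.08),
         (0.0021, 0.0045, 0.0040, 0.0018, 0.0036, 0.0047), 0.84),
    ],
    "ultrasonic power/W": [
        ("240", (0.63, 0.46, 0.12, 0.02, 1.84, 0.07),
         (0.0023, 0.0044, 0.0039, 0.0022, 0.0045, 0.0040), 0.87),
        ("300", (0.63, 0.44, 0.10, 0.05, 1.83, 0.07),
         (0.0041, 0.0047, 0.0040, 0.0037, 0.0042, 0.0042), 0.94),
        ("360", (0.70, 0.47, 0.08, 0.01, 1.93, 0.06),
         (0.0042, 0.0035, 0.0036, 0.0046, 0.0042, 0.0036), 0.79),
        ("420", (0.59, 0.39, 0.12, 0.02, 1.63, 0.06),
         (0.0022, 0.0039, 0.0034, 0.0047, 0.0034, 0.0047), 0.80),
        ("480", (0.62, 0.38, 0.12, 0.02, 1.63, 0.04),
         (0.0043, 0.0040, 0.0037, 0.0034, 0.0047, 0.0041), 0.76),
    ],
}

# ---------------------------------------------------------------------------
# Box-Behnken factor definitions and the 17-run design/response table.
# ---------------------------------------------------------------------------

#: (name, center, half-range step) so coded -1/0/+1 map to center -/+ step.
BBD_FACTORS = (
    ("liquid to material ratio (mL/g)", 20.0, 10.0),
    ("water content (%)", 30.0, 10.0),
    ("extraction time (min)", 40.0, 10.0),
)

#: Natural-unit settings (A, B, C) of the 17 runs in published run order:
#: the three edge blocks (AB, AC, BC) followed by five center replicates.
BBD_RUNS_NATURAL = (
    (10, 20, 40), (30, 20, 40), (10, 40, 40), (30, 40, 40),
    (10, 30, 30), (30, 30, 30), (10, 30, 50), (30, 30, 50),
    (20, 20, 30), (20, 40, 30), (20, 20, 50), (20, 40, 50),
    (20, 30, 40), (20, 30, 40), (20, 30, 40), (20, 30, 40), (20, 30, 40),
)

#: Measured composite score Z for the 17 runs, same order.
BBD_RESPONSES = np.array([
    0.68, 0.68, 0.69, 0.71,
    0.78, 0.86, 0.80, 0.80,
    0.83, 0.73, 0.82, 0.82,
    0.95, 0.98, 0.94, 0.94, 0.95,
])

#: The study's fitted second-order coefficients in coded units
#: (intercept, A, B, C, AB, AC, BC, A^2, B^2, C^2), as published (rounded).
PUBLISHED_QUADRATIC_COEFS = np.array([
    0.95, 0.013, -0.0075, 0.005, 0.005, -0.020, 0.025, -0.13, -0.14, -0.016,
])

#: Published optimum in natural units and its predicted composite score.
PUBLISHED_OPTIMUM = {"liquid to material ratio (mL/g)": 20.40,
                     "water content (%)": 29.84,
                     "extraction time (min)": 41.19,
                     "predicted_z": 0.95}

# ---------------------------------------------------------------------------
# HPLC calibration curves: slope (area per ug/uL), intercept (area),
# linearity range (ug/uL), printed R^2, LOD, LOQ (ug/uL).
# Slopes with irregular digit grouping in the source table are read by
# magnitude consistency (5.0e6, 8.0e6, 1.0e7): the glycyrrhetinic acid
# slope is taken as 1.0e7, not 1.0e6, because the marker-slope ratio
# 8.0e6 / 1.0e7 = 0.80 matches its measured correction factor (0.79)
# while 1.0e6 would imply f = 8.  The isoliquiritin apioside upper range
# limit is printed as 0.82 but every range in the table is
# stock/10 x (0.4, 2.0); 0.43 mg/mL stock gives 0.086, which is used here.
# ---------------------------------------------------------------------------

CALIBRATION_PARAMS = {
    "isoliquiritin apioside": {
        "slope": 5.0e6, "intercept": -1202.6,
        "range": (0.0172, 0.086), "r_squared": 0.9996,
        "lod": 0.00064, "loq": 0.00194},
    "liquiritin": {
        "slope": 6.0e6, "intercept": -1945.8,
        "range": (0.018, 0.09), "r_squared": 0.9997,
        "lod": 0.00205, "loq": 0.00621},
    "isoliquiritin": {
        "slope": 9.0e6, "intercept": -1581.9,
        "range": (0.0104, 0.052), "r_squared": 1.0,
        "lod": 0.00029, "loq": 0.00088},
    "liquiritigenin": {
        "slope": 1.0e7, "intercept": -5257.6,
        "range": (0.014, 0.07), "r_squared": 1.0,
        "lod": 0.00042, "loq": 0.00128},
    "glycyrrhizic acid": {
        "slope": 8.0e6, "intercept": -2242.8,
        "range": (0.0224, 0.112), "r_squared": 0.9999,
        "lod": 0.00189, "loq": 0.00573},
    "glycyrrhetinic acid": {
        "slope": 1.0e7, "intercept": -3551.6,
        "range": (0.0088, 0.044), "r_squared": 0.9996,
        "lod": 0.00225, "loq": 0.00683},
}

# ---------------------------------------------------------------------------
# Method-validation replicate RSDs (%) and spike recoveries (%), in
# COMPOUNDS order.  These summarize unpublished raw replicates and serve as
# noise-scale targets for the synthetic generator, not as recomputable data.
# ---------------------------------------------------------------------------

PRECISION_RSD_PCT = (0.60, 0.33, 1.05, 0.45, 0.98, 1.02)
REPEATABILITY_RSD_PCT = (1.24, 1.43, 2.01, 1.77, 0.48, 1.49)
STABILITY_RSD_PCT = (2.02, 1.93, 1.77, 1.32, 1.03, 2.39)
RECOVERY_PCT = (102.12, 104.22, 101.38, 103.41, 103.36, 100.97)
RECOVERY_RSD_PCT = (1.43, 0.03, 0.58, 0.57, 0.41, 0.51)

#: Verification runs at the adopted optimum (20 mL/g, 30 % water, 41 min):
#: six extraction rates plus the study's printed composite score per run.
#: The normalization group behind those scores is unpublished, so the
#: printed Z is carried as data rather than recomputed.
VERIFICATION_RUNS = [
    ((0.66, 0.46, 0.12, 0.11, 1.84, 0.021), 0.92),
    ((0.65, 0.46, 0.12, 0.11, 1.81, 0.021), 0.92),
    ((0.66, 0.45, 0.12, 0.11, 1.87, 0.021), 0.93),
]

#: The 24 candidate DES systems screened: (label, hydrogen-bond acceptor,
#: hydrogen-bond donor, molar ratio).
DES_SYSTEMS = [
    ("DESs-1", "ChCl", "Glycol", "1:2"),
    ("DESs-2", "ChCl", "Glycol", "1:3"),
    ("DESs-3", "ChCl", "Glycol", "1:4"),
    ("DESs-4", "ChCl", "Glycol", "1:5"),
    ("DESs-5", "ChCl", "Glycol", "1:6"),
    ("DESs-6", "ChCl", "Glycerol", "1:2"),
    ("DESs-7", "ChCl", "Glycerol", "1:3"),
    ("DESs-8", "ChCl", "Glycerol", "1:4"),
    ("DESs-9", "ChCl", "Glycerol", "1:5"),
    ("DESs-10", "ChCl", "Glycerol", "1:6"),
    ("DESs-11", "ChCl", "1,3-Butanediol", "1:2"),
    ("DESs-12", "ChCl", "1,3-Butanediol", "1:3"),
    ("DESs-13", "ChCl", "1,3-Butanediol", "1:4"),
    ("DESs-14", "ChCl", "1,3-Butanediol", "1:5"),
    ("DESs-15", "ChCl", "1,3-Butanediol", "1:6"),
    ("DESs-16", "ChCl", "Lactic acid", "1:2"),
    ("DESs-17", "ChCl", "Lactic acid", "1:3"),
    ("DESs-18", "ChCl", "Lactic acid", "1:4"),
    ("DESs-19", "ChCl", "Lactic acid", "1:5"),
    ("DESs-20", "ChCl", "Lactic acid", "1:6"),
    ("DESs-21", "ChCl", "Urea", "1:2"),
    ("DESs-22", "ChCl", "Urea", "1:3"),
    ("DESs-23", "ChCl", "Malic acid", "1:1"),
    ("DESs-24", "ChCl", "Xylitol", "1:1"),
]
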
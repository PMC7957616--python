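"""CSV interchange: peak tables, extraction tables, design/response files.

All files are UTF-8 CSV with a header row and "." decimal separator.
Schemas:

* peak table        — compound,injection_volume_ul,concentration_mg_ml,area
                      (empty concentration marks a sample injection)
* extraction table  — condition,<six compound rate columns>[,<sd columns>]
* design/response   — run,A,B,C,response with A,B,C in natural units
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd

from . import study_data as sd
from .doe import BBDesign, FactorDef
from .qams import PeakRecord
from .scoring import ExtractionTable

__all__ = [
    "read_peak_table", "write_peak_table",
    "read_extraction_table", "write_extraction_table",
    "read_design", "write_design",
]

PEAK_COLUMNS = ["compound", "injection_volume_ul", "concentration_mg_ml", "area"]
DESIGN_COLUMNS = ["run", "A", "B", "C", "response"]


class ParseError(ValueError):
    """A structural problem in an input file, with file/line context."""


def _read_csv(path: str, required: Sequence[str]) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, comment="#", dtype={"compound": str,
                                                   "condition": str})
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: file is empty") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}; "
                         f"found {list(df.columns)}")
    return df


def _numeric(df: pd.DataFrame, path: str, columns: Sequence[str],
             allow_nan: Sequence[str] = ()) -> pd.DataFrame:
    for col in columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ParseError(
                f"{path}:{line}: non-numeric value {df.loc[bad.idxmax(), col]!r} "
                f"in column {col!r}")
        if converted.isna().any() and col not in allow_nan:
            line = int(converted.isna().idxmax()) + 2
            raise ParseError(f"{path}:{line}: missing value in column {col!r}")
        df[col] = converted
    return df


# -- peak tables -------------------------------------------------------

def read_peak_table(path: str) -> list[PeakRecord]:
    df = _read_csv(path, PEAK_COLUMNS)
    df = _numeric(df, path, PEAK_COLUMNS[1:], allow_nan=["concentration_mg_ml"])
    records = []
    for i, row in df.iterrows():
        conc = row["concentration_mg_ml"]
        try:
            records.append(PeakRecord(
                compound=str(row["compound"]),
                injection_volume_ul=float(row["injection_volume_ul"]),
                area=float(row["area"]),
                concentration_mg_ml=None if pd.isna(conc) else float(conc)))
        except ValueError as exc:
            raise ParseError(f"{path}:{int(i) + 2}: {exc}") from None
    return records


def write_peak_table(path: str, records: Sequence[PeakRecord]) -> None:
    df = pd.DataFrame(
        [(r.compound, r.injection_volume_ul, r.concentration_mg_ml, r.area)
         for r in records], columns=PEAK_COLUMNS)
    df.to_csv(path, index=False)


# -- extraction tables -------------------------------------------------

def _slug(compound: str) -> str:
    return compound.replace(" ", "_").replace(",", "").replace("-", "_")


def read_extraction_table(path: str, group_label: str | None = None) -> ExtractionTable:
    rate_cols = [_slug(c) for c in sd.COMPOUNDS]
    sd_cols = [c + "_sd" for c in rate_cols]
    df = _read_csv(path, ["condition"] + rate_cols)
    df = _numeric(df, path, rate_cols + [c for c in sd_cols if c in df.columns])
    if df["condition"].duplicated().any():
        dup = df["condition"][df["condition"].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate condition label {dup!r}")
    rates = df.set_index("condition")[rate_cols]
    rates.columns = list(sd.COMPOUNDS)
    sds = None
    if all(c in df.columns for c in sd_cols):
        sds = df.set_index("condition")[sd_cols]
        sds.columns = list(sd.COMPOUNDS)
    label = group_label if group_label is not None else os.path.basename(path)
    return ExtractionTable(group_label=label, rates=rates, sds=sds)


def write_extraction_table(path: str, table: ExtractionTable) -> None:
    out = table.rates.copy()
    out.columns = [_slug(c) for c in sd.COMPOUNDS]
    if table.sds is not None:
        for c in sd.COMPOUNDS:
            out[_slug(c) + "_sd"] = table.sds[c]
    out.index.name = "condition"
    out.to_csv(path)


# -- BBD design / response files --------------------------------------

def read_design(path: str,
                factors: Sequence[FactorDef] | None = None
                ) -> tuple[BBDesign, np.ndarray]:
    """Read a natural-unit design/response CSV as a coded design.

    Factor definitions default to the study's levels; natural settings are
    encoded with each factor's center and step.
    """
    if factors is None:
        factors = [FactorDef(name, center, step)
                   for name, center, step in sd.BBD_FACTORS]
    df = _read_csv(path, DESIGN_COLUMNS)
    df = _numeric(df, path, DESIGN_COLUMNS[1:])
    natural = df[["A", "B", "C"]].to_numpy(float)
    coded = np.array([[f.encode(x) for f, x in zip(factors, row)]
                      for row in natural])
    off_grid = ~np.isin(np.round(coded, 9), (-1.0, 0.0, 1.0))
    if off_grid.any():
        i, j = np.argwhere(off_grid)[0]
        raise ParseError(
            f"{path}:{int(i) + 2}: setting {natural[i, j]} is not a "
            f"-1/0/+1 level of factor {factors[j].name!r}")
    center_count = int((np.abs(coded).sum(axis=1) == 0).sum())
    design = BBDesign(factors=tuple(factors), coded_matrix=coded,
                      center_count=center_count)
    return design, df["response"].to_numpy(float)


def write_design(path: str, design: BBDesign, response: Sequence[float]) -> None:
    natural = design.natural_matrix()
    df = pd.DataFrame({
        "run": np.arange(1, design.n_runs + 1),
        "A": natural[:, 0], "B": natural[:, 1], "C": natural[:, 2],
        "response": np.asarray(response, float),
    })
    df.to_csv(path, index=False)
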
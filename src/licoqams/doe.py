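"""Box-Behnken design, second-order response-surface fit, ANOVA, optimization.

The three-factor Box-Behnken design (BBD) places 12 runs at the midpoints of
the edges of the coded cube (each pair of factors at +/-1 with the third at
0) plus replicated center runs, here five, for 17 runs total.  A full
second-order model

    z = b0 + bA*A + bB*B + bC*C + bAB*AB + bAC*AC + bBC*BC
        + bAA*A^2 + bBB*B^2 + bCC*C^2

is fitted by ordinary least squares in coded units.  The ANOVA reports
partial (drop-one-term) sums of squares, and splits the residual into pure
error (from the center replicates) and lack of fit, whose F ratio against
the pure-error mean square tests model adequacy.  The stationary point of
the fitted quadratic, decoded to natural units, is the candidate optimum; a
box-constrained maximizer guards against stationary points outside the
design region.

Design properties used throughout: the linear columns are mutually
orthogonal with sum of squares 8; the pairwise-product columns are
orthogonal to everything else with sum of squares 4.  Linear and
interaction coefficients therefore equal simple contrasts of the run
responses, which the tests exploit as closed-form oracles.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FactorDef", "BBDesign", "QuadraticModel", "AnovaTable", "OptimumResult",
    "bbd_design", "fit_quadratic", "anova", "fit_stats",
    "stationary_point", "optimize_in_box", "quadratic_response",
]

TERM_NAMES = ("Intercept", "A", "B", "C", "AB", "AC", "BC", "A2", "B2", "C2")

#: Canonical run order: AB-edge block, AC-edge block, BC-edge block, centers.
_EDGE_ROWS = (
    (-1, -1, 0), (1, -1, 0), (-1, 1, 0), (1, 1, 0),
    (-1, 0, -1), (1, 0, -1), (-1, 0, 1), (1, 0, 1),
    (0, -1, -1), (0, 1, -1), (0, -1, 1), (0, 1, 1),
)


@dataclass(frozen=True)
class FactorDef:
    """One experimental factor: coded levels -1/0/+1 map to
    center - step / center / center + step in natural units."""

    name: str
    center: float
    step: float

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"step must be > 0 for factor {self.name!r}")

    def encode(self, natural: float) -> float:
        return (natural - self.center) / self.step

    def decode(self, coded: float) -> float:
        return self.center + self.step * coded


@dataclass(frozen=True)
class BBDesign:
    """Three-factor Box-Behnken design in coded units."""

    factors: tuple[FactorDef, FactorDef, FactorDef]
    coded_matrix: np.ndarray  # (12 + center_count) x 3 with entries in {-1,0,1}
    center_count: int = 5

    @property
    def n_runs(self) -> int:
        return self.coded_matrix.shape[0]

    def encode(self, natural_point: Sequence[float]) -> np.ndarray:
        p = np.asarray(natural_point, dtype=float)
        coded = np.array([f.encode(x) for f, x in zip(self.factors, p)])
        if (np.abs(coded) > 1 + 1e-9).any():
            warnings.warn("point lies outside the coded design cube "
                          "(extrapolation)", stacklevel=2)
        return coded

    def decode(self, coded_point: Sequence[float]) -> np.ndarray:
        p = np.asarray(coded_point, dtype=float)
        return np.array([f.decode(x) for f, x in zip(self.factors, p)])

    def natural_matrix(self) -> np.ndarray:
        return np.array([self.decode(row) for row in self.coded_matrix])


def bbd_design(factors: Sequence[FactorDef], center_runs: int = 5) -> BBDesign:
    """Construct the canonical 3-factor Box-Behnken design.

    Run order is the fixed edge-block order (AB, AC, BC pairs) followed by
    ``center_runs`` all-zero rows; model fitting is invariant to it.
    """
    factors = tuple(factors)
    if len(factors) != 3:
        raise ValueError(
            f"only the 3-factor Box-Behnken design is supported, "
            f"got {len(factors)} factors")
    if center_runs < 1:
        raise ValueError("need at least one center run")
    coded = np.array(list(_EDGE_ROWS) + [(0, 0, 0)] * center_runs, dtype=float)
    return BBDesign(factors=factors, coded_matrix=coded, center_count=center_runs)


def model_matrix(coded: np.ndarray) -> np.ndarray:
    """10-column second-order model matrix for coded design rows."""
    A, B, C = np.asarray(coded, dtype=float).T
    return np.column_stack(
        [np.ones_like(A), A, B, C, A * B, A * C, B * C, A * A, B * B, C * C])


def quadratic_response(coefs: Sequence[float], coded_point: Sequence[float]) -> float:
    """Evaluate the second-order polynomial at one coded point."""
    pt = np.atleast_2d(np.asarray(coded_point, dtype=float))
    return float((model_matrix(pt) @ np.asarray(coefs, dtype=float))[0])


@dataclass(frozen=True)
class QuadraticModel:
    """Fitted full second-order model in coded units."""

    design: BBDesign
    coefficients: np.ndarray  # TERM_NAMES order
    response: np.ndarray
    fitted_values: np.ndarray
    residuals: np.ndarray

    def coef(self, term: str) -> float:
        return float(self.coefficients[TERM_NAMES.index(term)])

    @property
    def sse(self) -> float:
        return float(self.residuals @ self.residuals)

    def predict(self, coded_point: Sequence[float]) -> float:
        return quadratic_response(self.coefficients, coded_point)

    def gradient_hessian(self) -> tuple[np.ndarray, np.ndarray]:
        """Gradient at the origin and (constant) Hessian of the quadratic."""
        b = self.coefficients
        g = b[1:4].copy()
        H = np.array([
            [2 * b[7], b[4], b[5]],
            [b[4], 2 * b[8], b[6]],
            [b[5], b[6], 2 * b[9]],
        ])
        return g, H


def fit_quadratic(design: BBDesign, response: Sequence[float]) -> QuadraticModel:
    """Ordinary least squares of the response on the 10-term model matrix."""
    y = np.asarray(response, dtype=float)
    if y.shape != (design.n_runs,):
        raise ValueError(
            f"response length {y.size} does not match the {design.n_runs}-run design")
    X = model_matrix(design.coded_matrix)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            "rank-deficient model matrix; design does not support a full "
            "second-order model")
    fitted = X @ beta
    return QuadraticModel(design=design, coefficients=beta, response=y,
                          fitted_values=fitted, residuals=y - fitted)


@dataclass(frozen=True)
class AnovaTable:
    """Design-of-experiments ANOVA with lack-of-fit decomposition."""

    table: pd.DataFrame  # index: Model, terms, Residual, Lack of Fit, Pure Error, Cor Total
    r_squared: float
    adj_r_squared: float

    def row(self, name: str) -> pd.Series:
        return self.table.loc[name]


def _pure_error(design: BBDesign, y: np.ndarray) -> tuple[float, int]:
    """Within-replicate-group sum of squares and df over identical design rows."""
    groups: dict[tuple, list[float]] = {}
    for row, yi in zip(design.coded_matrix, y):
        groups.setdefault(tuple(row), []).append(float(yi))
    ss = 0.0
    df = 0
    for vals in groups.values():
        if len(vals) > 1:
            v = np.asarray(vals)
            ss += float(((v - v.mean()) ** 2).sum())
            df += len(vals) - 1
    return ss, df


def anova(model: QuadraticModel,
          design: Optional[BBDesign] = None,
          response: Optional[Sequence[float]] = None) -> AnovaTable:
    """Partial-SS ANOVA of a fitted second-order model.

    Each term's sum of squares is the increase in residual SS when that
    single term is dropped from the full model (partial / Type III SS; for
    this design's orthogonal linear and interaction columns it reduces to
    beta^2 * sum(x^2)).  Term and model F ratios use the residual mean
    square; the lack-of-fit F uses the pure-error mean square from the
    replicated center runs.
    """
    design = design if design is not None else model.design
    y = np.asarray(response, dtype=float) if response is not None else model.response

    X = model_matrix(design.coded_matrix)
    sse = model.sse
    ss_total = float(((y - y.mean()) ** 2).sum())
    ss_model = ss_total - sse
    df_model, df_resid = 9, design.n_runs - 10

    rows: list[tuple[str, float, int]] = [("Model", ss_model, df_model)]
    for j, term in enumerate(TERM_NAMES[1:], start=1):
        Xr = np.delete(X, j, axis=1)
        br, *_ = np.linalg.lstsq(Xr, y, rcond=None)
        er = y - Xr @ br
        rows.append((term, float(er @ er) - sse, 1))
    rows.append(("Residual", sse, df_resid))

    ss_pe, df_pe = _pure_error(design, y)
    have_reps = df_pe > 0
    if have_reps:
        rows.append(("Lack of Fit", sse - ss_pe, df_resid - df_pe))
        rows.append(("Pure Error", ss_pe, df_pe))
    else:
        warnings.warn("no replicate runs: lack-of-fit rows omitted", stacklevel=2)
    rows.append(("Cor Total", ss_total, design.n_runs - 1))

    ms_resid = sse / df_resid
    records = []
    for name, ss, df in rows:
        ms = ss / df if df > 0 else np.nan
        if name in ("Residual", "Cor Total", "Pure Error"):
            F = p = np.nan
        elif name == "Lack of Fit":
            ms_pe = ss_pe / df_pe
            F = ms / ms_pe if ms_pe > 0 else np.nan
            p = stats.f.sf(F, df, df_pe) if np.isfinite(F) else np.nan
        else:
            F = ms / ms_resid if ms_resid > 0 else np.nan
            p = stats.f.sf(F, df, df_resid) if np.isfinite(F) else np.nan
        records.append((name, ss, df, ms, F, p))

    table = pd.DataFrame(
        records, columns=["source", "sum_sq", "df", "mean_sq", "F", "p"]
    ).set_index("source")
    r2, adj = fit_stats_from_ss(ss_model, ss_total, design.n_runs, df_model)
    return AnovaTable(table=table, r_squared=r2, adj_r_squared=adj)


def fit_stats_from_ss(ss_model: float, ss_total: float,
                      n: int, p_terms: int) -> tuple[float, float]:
    if n <= p_terms + 1:
        raise ValueError("adjusted R^2 undefined: n must exceed p_terms + 1")
    r2 = ss_model / ss_total
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 1 - p_terms)
    return float(r2), float(adj)


def fit_stats(anova_table: AnovaTable, n: int, p_terms: int) -> tuple[float, float]:
    """R^2 = SS_model / SS_total and its df-adjusted version."""
    t = anova_table.table
    return fit_stats_from_ss(t.loc["Model", "sum_sq"],
                             t.loc["Cor Total", "sum_sq"], n, p_terms)


@dataclass(frozen=True)
class OptimumResult:
    """A candidate optimum of the fitted surface."""

    coded_point: np.ndarray
    natural_point: np.ndarray
    predicted_response: float
    hessian_definiteness: str  # "max" | "min" | "saddle"
    clipped_to_box: bool = False


def _classify(H: np.ndarray) -> str:
    eig = np.linalg.eigvalsh(H)
    if (eig < 0).all():
        return "max"
    if (eig > 0).all():
        return "min"
    return "saddle"


def stationary_point(model: QuadraticModel) -> OptimumResult:
    """Solve grad z = 0 for the fitted quadratic and classify the point.

    The Hessian is constant (H_ii = 2*b_ii, H_ij = b_ij); the stationary
    point solves H x = -g with g the linear-coefficient vector.  It is a
    maximum / minimum / saddle according to the Hessian's eigenvalue signs.
    """
    g, H = model.gradient_hessian()
    sv = np.linalg.svd(H, compute_uv=False)
    scale = max(sv[0], float(np.abs(model.coefficients).max()), 1e-12)
    if sv[-1] <= 1e-8 * scale:
        raise np.linalg.LinAlgError(
            "singular Hessian: no unique stationary point; use "
            "optimize_in_box instead")
    x = np.linalg.solve(H, -g)
    return OptimumResult(
        coded_point=x,
        natural_point=model.design.decode(x),
        predicted_response=model.predict(x),
        hessian_definiteness=_classify(H),
        clipped_to_box=False,
    )


def optimize_in_box(model: QuadraticModel, bound: float = 1.0) -> OptimumResult:
    """Global maximum of the fitted quadratic over the coded cube [-b, b]^3.

    For a quadratic the maximum lies at a stationary point of the objective
    restricted to some face of the cube, so all 27 face-interior candidates
    (each coordinate free or fixed at +/-b) are enumerated exactly and the
    best feasible one returned.  Coincides with :func:`stationary_point`
    when that point is an interior maximum.
    """
    g, H = model.gradient_hessian()
    best_x, best_val = None, -np.inf
    for fixed in itertools.product((None, -bound, bound), repeat=3):
        free = [i for i, v in enumerate(fixed) if v is None]
        x = np.array([0.0 if v is None else v for v in fixed])
        if free:
            # stationary point of the restriction: solve reduced system
            Hff = H[np.ix_(free, free)]
            rhs = -(g[free] + H[np.ix_(free, [i for i in range(3) if i not in free])]
                    @ x[[i for i in range(3) if i not in free]])
            try:
                xf = np.linalg.solve(Hff, rhs)
            except np.linalg.LinAlgError:
                continue
            if (np.abs(xf) > bound + 1e-12).any():
                continue
            x[free] = xf
        val = model.predict(x)
        if val > best_val:
            best_val, best_x = val, x
    interior = bool((np.abs(best_x) < bound - 1e-9).all())
    return OptimumResult(
        coded_point=best_x,
        natural_point=model.design.decode(best_x),
        predicted_response=best_val,
        hessian_definiteness=_classify(H),
        clipped_to_box=not interior,
    )
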
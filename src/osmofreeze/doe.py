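"""Three-factor Box–Behnken design and second-order response-surface fitting.

The design places runs at the midpoints of the edges of the factor cube
(all permutations of (±1, ±1, 0)) plus replicated centre points, and the
response is modelled by the full ten-term quadratic

    y = a0 + Σ ai·xi + Σ aii·xi² + Σ aij·xi·xj

in coded units xi ∈ [−1, +1].  Coded and uncoded (actual-unit) coefficient
vectors are kept in the fixed term order

    (1, x1, x2, x3, x1², x2², x3², x1·x2, x1·x3, x2·x3).

Coding is the affine map xi = (Xi − centre) / half-range, with the larger
actual level always mapping to +1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "Factor",
    "FactorSpace",
    "DesignRun",
    "QuadraticModel",
    "TERM_NAMES",
    "generate_bbd",
    "fit_quadratic",
    "predict",
    "anova_table",
]

TERM_NAMES = ("a0", "a1", "a2", "a3", "a11", "a22", "a33", "a12", "a13", "a23")


class SingularDesignError(np.linalg.LinAlgError):
    """The design matrix does not identify all ten quadratic terms."""


class UnsupportedDesignError(ValueError):
    """Raised for factor counts other than three."""


@dataclass(frozen=True)
class Factor:
    """One continuous design factor with its three symmetric levels."""

    name: str
    low: float
    center: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not self.low < self.center < self.high:
            raise ValueError(f"factor {self.name}: need low < center < high")

    @property
    def half_range(self) -> float:
        return (self.high - self.low) / 2.0

    def code(self, value: float) -> float:
        """Map an actual value to coded units; centre → 0, high → +1."""
        coded = (np.asarray(value, dtype=float) - self.center) / self.half_range
        if np.any(np.abs(coded) > 1.0 + 1e-12):
            logger.info(
                "factor %s: value %s codes outside [-1, +1] (extrapolation)",
                self.name, value,
            )
        return coded if np.ndim(value) else float(coded)

    def decode(self, coded: float) -> float:
        """Exact inverse of :meth:`code`."""
        actual = np.asarray(coded, dtype=float) * self.half_range + self.center
        return actual if np.ndim(coded) else float(actual)


@dataclass(frozen=True)
class FactorSpace:
    """Ordered triple of design factors (temperature, time, concentration)."""

    factors: tuple[Factor, Factor, Factor]

    def __post_init__(self) -> None:
        if len(self.factors) != 3:
            raise UnsupportedDesignError("exactly three factors are supported")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    def code(self, actual: Sequence[float]) -> tuple[float, ...]:
        return tuple(f.code(v) for f, v in zip(self.factors, actual))

    def decode(self, coded: Sequence[float]) -> tuple[float, ...]:
        return tuple(f.decode(v) for f, v in zip(self.factors, coded))


@dataclass(frozen=True)
class DesignRun:
    """One experimental run: coded levels, actual levels, ordinal run id."""

    run_id: int
    coded: tuple[float, float, float]
    actual: tuple[float, float, float]


def generate_bbd(factor_space: FactorSpace, n_center: int = 3) -> list[DesignRun]:
    """Generate the three-factor Box–Behnken design.

    Twelve edge-midpoint runs — for each factor pair, the four (±1, ±1)
    combinations with the third factor at 0 — followed by ``n_center``
    replicated centre runs.  With the default three centre points the design
    has 15 runs; every coded column sums to zero with sum of squares 8.
    """
    if n_center < 1:
        raise ValueError("need at least one center run")
    rows: list[tuple[float, float, float]] = []
    for i, j in combinations(range(3), 2):
        for si in (-1.0, 1.0):
            for sj in (-1.0, 1.0):
                row = [0.0, 0.0, 0.0]
                row[i], row[j] = si, sj
                rows.append(tuple(row))
    rows.extend([(0.0, 0.0, 0.0)] * n_center)
    return [
        DesignRun(run_id=k + 1, coded=r, actual=factor_space.decode(r))
        for k, r in enumerate(rows)
    ]


def _basis(x1, x2, x3) -> np.ndarray:
    """Ten-column quadratic basis in the fixed term order, vectorised."""
    x1, x2, x3 = np.broadcast_arrays(
        np.asarray(x1, float), np.asarray(x2, float), np.asarray(x3, float)
    )
    one = np.ones_like(x1)
    return np.stack(
        [one, x1, x2, x3, x1 * x1, x2 * x2, x3 * x3, x1 * x2, x1 * x3, x2 * x3],
        axis=-1,
    )


def _eval_quad(coeffs: np.ndarray, x1, x2, x3):
    # elementwise accumulation (not a matmul) so equal inputs give
    # bitwise-equal outputs regardless of their position in an array
    a = np.asarray(coeffs, float)
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    x3 = np.asarray(x3, float)
    out = (
        a[0]
        + a[1] * x1 + a[2] * x2 + a[3] * x3
        + a[4] * x1 * x1 + a[5] * x2 * x2 + a[6] * x3 * x3
        + a[7] * x1 * x2 + a[8] * x1 * x3 + a[9] * x2 * x3
    )
    return float(out) if out.ndim == 0 else out


def _coded_to_uncoded(coded: np.ndarray, space: FactorSpace) -> np.ndarray:
    """Exact algebraic expansion of the coding map xi = (Xi − ci)/hi."""
    a = np.asarray(coded, float)
    c = np.array([f.center for f in space.factors])
    h = np.array([f.half_range for f in space.factors])
    lin, quad = a[1:4], a[4:7]
    inter = {(0, 1): a[7], (0, 2): a[8], (1, 2): a[9]}
    b = np.zeros(10)
    b[0] = (
        a[0]
        - np.sum(lin * c / h)
        + np.sum(quad * c**2 / h**2)
        + sum(v * c[i] * c[j] / (h[i] * h[j]) for (i, j), v in inter.items())
    )
    for i in range(3):
        b[1 + i] = lin[i] / h[i] - 2 * quad[i] * c[i] / h[i] ** 2
        for (p, q), v in inter.items():
            if p == i:
                b[1 + i] -= v * c[q] / (h[p] * h[q])
            elif q == i:
                b[1 + i] -= v * c[p] / (h[p] * h[q])
        b[4 + i] = quad[i] / h[i] ** 2
    for k, (i, j) in enumerate(((0, 1), (0, 2), (1, 2))):
        b[7 + k] = inter[(i, j)] / (h[i] * h[j])
    return b


def _uncoded_to_coded(uncoded: np.ndarray, space: FactorSpace) -> np.ndarray:
    """Inverse expansion: substitute Xi = ci + hi·xi into the actual-unit form."""
    b = np.asarray(uncoded, float)
    c = np.array([f.center for f in space.factors])
    h = np.array([f.half_range for f in space.factors])
    lin, quad = b[1:4], b[4:7]
    inter = {(0, 1): b[7], (0, 2): b[8], (1, 2): b[9]}
    a = np.zeros(10)
    a[0] = (
        b[0]
        + np.sum(lin * c)
        + np.sum(quad * c**2)
        + sum(v * c[i] * c[j] for (i, j), v in inter.items())
    )
    for i in range(3):
        a[1 + i] = lin[i] * h[i] + 2 * quad[i] * c[i] * h[i]
        for (p, q), v in inter.items():
            if p == i:
                a[1 + i] += v * c[q] * h[i]
            elif q == i:
                a[1 + i] += v * c[p] * h[i]
        a[4 + i] = quad[i] * h[i] ** 2
    for k, (i, j) in enumerate(((0, 1), (0, 2), (1, 2))):
        a[7 + k] = inter[(i, j)] * h[i] * h[j]
    return a


@dataclass(frozen=True)
class QuadraticModel:
    """A fitted (or constructed) ten-term quadratic for one response.

    Holds both coefficient parameterisations: ``coded_coeffs`` in the
    dimensionless ±1 units and ``uncoded_coeffs`` in actual factor units,
    related by exact algebraic expansion of the coding map, so predictions
    from either form agree to numerical precision.  Fit diagnostics are
    ``None`` when the model was constructed from published coefficients
    rather than fitted to data.
    """

    response_name: str
    coded_coeffs: np.ndarray
    uncoded_coeffs: np.ndarray
    factor_space: FactorSpace
    r2: Optional[float] = None
    r2_adj: Optional[float] = None
    p_model: Optional[float] = None
    p_lack_of_fit: Optional[float] = None
    residual_df: Optional[int] = None
    coef_pvalues: Optional[np.ndarray] = field(default=None, repr=False)
    coef_stderr: Optional[np.ndarray] = field(default=None, repr=False)

    @classmethod
    def from_uncoded(
        cls, response_name: str, coeffs: Sequence[float], space: FactorSpace
    ) -> "QuadraticModel":
        """Build a model from actual-unit coefficients (e.g. published equations)."""
        b = np.asarray(coeffs, float)
        if b.shape != (10,):
            raise ValueError("expected 10 coefficients")
        return cls(response_name, _uncoded_to_coded(b, space), b.copy(), space)

    @classmethod
    def from_coded(
        cls, response_name: str, coeffs: Sequence[float], space: FactorSpace
    ) -> "QuadraticModel":
        a = np.asarray(coeffs, float)
        if a.shape != (10,):
            raise ValueError("expected 10 coefficients")
        return cls(response_name, a.copy(), _coded_to_uncoded(a, space), space)

    def predict(self, T, t, C):
        """Evaluate the surface at actual factor values (scalars or arrays)."""
        return _eval_quad(self.uncoded_coeffs, T, t, C)

    def predict_coded(self, x1, x2, x3):
        """Evaluate the surface at coded factor values."""
        return _eval_quad(self.coded_coeffs, x1, x2, x3)


def fit_quadratic(
    runs: Sequence[DesignRun], y: Sequence[float], response_name: str = "y"
) -> QuadraticModel:
    """Ordinary least squares of the ten-term quadratic in coded units.

    Lack-of-fit is tested against pure error from replicated design points
    (the centre replicates, in a standard Box–Behnken design); with fewer
    than two replicates the lack-of-fit p-value is reported as ``None``,
    never as zero.
    """
    y = np.asarray(y, float)
    if len(runs) != len(y):
        raise ValueError("runs and y must have equal length")
    if len(runs) < 11:
        raise ValueError("need at least 11 runs for 10 terms + 1 residual df")
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")

    coded = np.array([r.coded for r in runs], float)
    X = _basis(coded[:, 0], coded[:, 1], coded[:, 2])
    if np.linalg.matrix_rank(X) < 10:
        raise SingularDesignError("design does not identify all quadratic terms")

    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    df_res = n - p
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / df_res if ss_tot > 0 else 1.0

    mse = ss_res / df_res
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(mse * np.diag(XtX_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_res)

    # Overall model F-test against the intercept-only model.
    ss_reg = ss_tot - ss_res
    if ss_tot > 0 and mse > 0:
        f_model = (ss_reg / (p - 1)) / mse
        p_model = float(stats.f.sf(f_model, p - 1, df_res))
    else:
        p_model = 0.0 if ss_tot > 0 else 1.0

    p_lof = _lack_of_fit_pvalue(coded, y, ss_res, df_res)

    space = _infer_space(runs)
    return QuadraticModel(
        response_name=response_name,
        coded_coeffs=beta,
        uncoded_coeffs=_coded_to_uncoded(beta, space),
        factor_space=space,
        r2=r2,
        r2_adj=r2_adj,
        p_model=p_model,
        p_lack_of_fit=p_lof,
        residual_df=df_res,
        coef_pvalues=pvals,
        coef_stderr=se,
    )


def _lack_of_fit_pvalue(coded, y, ss_res, df_res):
    groups: dict[tuple, list[float]] = {}
    for row, yi in zip(coded, y):
        groups.setdefault(tuple(np.round(row, 10)), []).append(yi)
    ss_pe, df_pe = 0.0, 0
    for vals in groups.values():
        if len(vals) > 1:
            v = np.asarray(vals)
            ss_pe += float(np.sum((v - v.mean()) ** 2))
            df_pe += len(vals) - 1
    if df_pe < 1:
        warnings.warn(
            "fewer than 2 replicated runs: lack-of-fit test unavailable",
            stacklevel=3,
        )
        return None
    df_lof = df_res - df_pe
    if df_lof < 1:
        return None
    ss_lof = max(ss_res - ss_pe, 0.0)
    scale = float(np.sum(y**2)) + 1.0
    if ss_pe <= 1e-14 * scale:
        # Zero pure error: any lack-of-fit is infinitely significant,
        # unless the residuals vanish too (perfect fit up to round-off).
        return 1.0 if ss_lof <= 1e-14 * scale else 0.0
    f = (ss_lof / df_lof) / (ss_pe / df_pe)
    return float(stats.f.sf(f, df_lof, df_pe))


def _infer_space(runs: Sequence[DesignRun]) -> FactorSpace:
    """Recover the factor space from a design's coded/actual value pairs."""
    coded = np.array([r.coded for r in runs], float)
    actual = np.array([r.actual for r in runs], float)
    factors = []
    for i in range(3):
        x, X = coded[:, i], actual[:, i]
        # affine fit: X = center + half_range * x (exact for a valid design)
        A = np.stack([np.ones_like(x), x], axis=1)
        (center, half), *_ = np.linalg.lstsq(A, X, rcond=None)
        factors.append(
            Factor(name=f"x{i + 1}", low=center - half, center=center, high=center + half)
        )
    return FactorSpace(tuple(factors))


def predict(model: QuadraticModel, T: float, t: float, C: float) -> float:
    """Evaluate a quadratic model at actual units (module-level convenience)."""
    return model.predict(T, t, C)


def anova_table(
    model: QuadraticModel, runs: Sequence[DesignRun], y: Sequence[float]
) -> pd.DataFrame:
    """Per-term coefficient table with t-tests starred at 95% confidence.

    Returns a DataFrame with one row per quadratic term (coded coefficient,
    standard error, p-value, star) plus summary rows for R², adjusted R²,
    the overall model F-test and the lack-of-fit test.
    """
    if model.coef_pvalues is None:
        model = fit_quadratic(runs, y, model.response_name)
    rows = [
        {
            "term": name,
            "coef_coded": model.coded_coeffs[i],
            "coef_uncoded": model.uncoded_coeffs[i],
            "stderr": model.coef_stderr[i],
            "p_value": model.coef_pvalues[i],
            "starred": bool(model.coef_pvalues[i] < 0.05),
        }
        for i, name in enumerate(TERM_NAMES)
    ]
    table = pd.DataFrame(rows)
    table.attrs.update(
        r2=model.r2,
        r2_adj=model.r2_adj,
        p_model=model.p_model,
        p_lack_of_fit=model.p_lack_of_fit,
        residual_df=model.residual_df,
    )
    return table
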
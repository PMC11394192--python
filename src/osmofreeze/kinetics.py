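"""Degradation kinetics and shelf life of frozen produce under Arrhenius scaling.

Concentration-type quality indices (vitamin C, lycopene) decay by apparent
first-order kinetics, C(t) = C0·exp(−k t); sensory scores decay by apparent
zero-order kinetics, S(t) = S0 − k t.  The temperature dependence of the rate
constant follows the reference-temperature Arrhenius form

    k(T) = k_ref · exp[ −(E_a/R) (1/T − 1/T_ref) ]        (T in kelvin)

so that k(T_ref) = k_ref exactly and k increases with temperature for
E_a > 0.  Shelf life is the time for the index to reach its acceptance limit
(50% retention for concentrations; a fixed score for sensory quality).

Fluctuating (piecewise-constant) storage is summarised by the *effective
temperature*: the constant temperature that produces the same quality loss
over the same total time, obtained by time-averaging the rate constant and
inverting the Arrhenius relation in closed form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize as sp_optimize
from scipy import stats

__all__ = [
    "R_GAS",
    "KELVIN",
    "T_REF_C_DEFAULT",
    "IsothermalSeries",
    "RateEstimate",
    "ArrheniusModel",
    "TemperatureProfile",
    "fit_rate",
    "fit_arrhenius",
    "rate_at",
    "shelf_life",
    "effective_temperature",
    "predict_nonisothermal",
    "relative_error",
]

R_GAS = 8.314  # J mol^-1 K^-1
KELVIN = 273.15
#: Default reference temperature for frozen storage (°C).
T_REF_C_DEFAULT = -18.0

Order = Literal["zero", "first"]


def _to_kelvin(t_c: float) -> float:
    return t_c + KELVIN


@dataclass(frozen=True)
class IsothermalSeries:
    """Time course of one quality index at one constant storage temperature.

    ``times`` (days) must be sorted non-decreasing with the first time ≥ 0;
    repeated times represent replicate measurements.  Fitting requires at
    least three distinct sampling times.
    """

    quality_name: str
    temperature_c: float
    times: tuple[float, ...]
    values: tuple[float, ...]
    unit: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        if len(t) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(t) and (t[0] < 0 or np.any(np.diff(t) < 0)):
            raise ValueError("times must be sorted non-decreasing, starting >= 0")

    @property
    def n_distinct_times(self) -> int:
        return len(set(self.times))


@dataclass(frozen=True)
class RateEstimate:
    """Fitted degradation rate at one temperature."""

    k: float  # per day; positive when degradation is detected
    order: Order
    temperature_c: float
    intercept: float  # C0 (value units) for first order, S0 for zero order
    r2: float
    stderr_k: float
    degradation_detected: bool = True


@dataclass(frozen=True)
class ArrheniusModel:
    """Reference-temperature Arrhenius model for one quality index.

    Parameters
    ----------
    k_ref : float
        Rate constant (per day) at the reference temperature.
    E_a : float
        Activation energy in J/mol (note: presets quote kJ/mol in comments).
    T_ref : float
        Reference temperature in kelvin (default 255.15 K = −18 °C).
    order : {"zero", "first"}
        Kinetic order of the quality index.
    initial_value, limit_value : float, optional
        Initial level and acceptance limit, in the index's own units; both
        are required for shelf-life computations.
    """

    k_ref: float
    E_a: float
    T_ref: float = T_REF_C_DEFAULT + KELVIN
    order: Order = "first"
    initial_value: Optional[float] = None
    limit_value: Optional[float] = None
    quality: str = ""

    def __post_init__(self) -> None:
        if self.k_ref <= 0:
            raise ValueError("k_ref must be positive")
        if self.order not in ("zero", "first"):
            raise ValueError("order must be 'zero' or 'first'")


@dataclass(frozen=True)
class TemperatureProfile:
    """Ordered piecewise-constant storage profile: (duration hours, °C) segments."""

    segments: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("profile needs at least one segment")
        if any(d <= 0 for d, _ in self.segments):
            raise ValueError("segment durations must be positive")

    @property
    def total_hours(self) -> float:
        return sum(d for d, _ in self.segments)

    @property
    def total_days(self) -> float:
        return self.total_hours / 24.0

    @property
    def temperatures_c(self) -> tuple[float, ...]:
        return tuple(t for _, t in self.segments)

    def time_weighted_mean_c(self) -> float:
        """Arithmetic time-weighted mean temperature (°C) — not the effective one."""
        return sum(d * t for d, t in self.segments) / self.total_hours


def fit_rate(
    series: IsothermalSeries,
    order: Order,
    method: Literal["loglinear", "nls"] = "loglinear",
) -> RateEstimate:
    """Fit the degradation rate at one temperature.

    First order fits ln(value) against time by least squares (the reference
    behaviour, assuming homoscedastic multiplicative error); ``method="nls"``
    instead fits C0·exp(−k t) by nonlinear least squares.  Zero order fits
    value against time directly.  A non-negative fitted slope triggers a
    "no degradation detected" warning; the (possibly ≤ 0) estimate is still
    returned, flagged via ``degradation_detected=False``.
    """
    if series.n_distinct_times < 3:
        raise ValueError("need at least 3 distinct sampling times")
    t = np.asarray(series.times, float)
    v = np.asarray(series.values, float)
    if order == "first":
        if np.any(v <= 0):
            raise ValueError("first-order fitting requires strictly positive values")
        res = stats.linregress(t, np.log(v))
        k, c0 = -res.slope, math.exp(res.intercept)
        if method == "nls":
            (c0, k), _ = sp_optimize.curve_fit(
                lambda tt, c, kk: c * np.exp(-kk * tt), t, v, p0=(c0, max(k, 1e-12))
            )
            r2 = 1.0 - np.sum((v - c0 * np.exp(-k * t)) ** 2) / np.sum((v - v.mean()) ** 2)
            stderr = float("nan")
        else:
            r2, stderr = res.rvalue**2, res.stderr
    elif order == "zero":
        res = stats.linregress(t, v)
        k, c0 = -res.slope, res.intercept
        r2, stderr = res.rvalue**2, res.stderr
    else:
        raise ValueError("order must be 'zero' or 'first'")
    detected = k > 0
    if not detected:
        warnings.warn(
            f"no degradation detected at {series.temperature_c} °C "
            f"(fitted k = {k:.3g}/d)",
            stacklevel=2,
        )
    return RateEstimate(
        k=float(k),
        order=order,
        temperature_c=series.temperature_c,
        intercept=float(c0),
        r2=float(r2),
        stderr_k=float(stderr),
        degradation_detected=detected,
    )


def fit_arrhenius(
    rates: Mapping[float, RateEstimate] | Sequence[RateEstimate],
    T_ref: float = T_REF_C_DEFAULT + KELVIN,
    initial_value: Optional[float] = None,
    limit_value: Optional[float] = None,
) -> ArrheniusModel:
    """Fit the Arrhenius line ln k vs (1/T − 1/T_ref) across temperatures.

    The slope is −E_a/R and the intercept ln k_ref; with exactly two
    temperatures the fit is exact.  All rate estimates must share the same
    kinetic order and have positive k.
    """
    ests = list(rates.values()) if isinstance(rates, Mapping) else list(rates)
    if len({e.temperature_c for e in ests}) < 2:
        raise ValueError("need rates at >= 2 distinct temperatures")
    orders = {e.order for e in ests}
    if len(orders) != 1:
        raise ValueError(f"mixed kinetic orders: {sorted(orders)}")
    if any(e.k <= 0 for e in ests):
        raise ValueError("all rate constants must be positive for Arrhenius fitting")
    x = np.array([1.0 / _to_kelvin(e.temperature_c) - 1.0 / T_ref for e in ests])
    y = np.log([e.k for e in ests])
    if len(ests) == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
    else:
        res = stats.linregress(x, y)
        slope, intercept = res.slope, res.intercept
    interc = np.mean([e.intercept for e in ests])
    return ArrheniusModel(
        k_ref=float(math.exp(intercept)),
        E_a=float(-slope * R_GAS),
        T_ref=T_ref,
        order=orders.pop(),
        initial_value=initial_value if initial_value is not None else float(interc),
        limit_value=limit_value,
    )


def rate_at(model: ArrheniusModel, T_c: float) -> float:
    """Rate constant (per day) at storage temperature ``T_c`` in °C."""
    T = np.asarray(T_c, float) + KELVIN
    k = model.k_ref * np.exp(-(model.E_a / R_GAS) * (1.0 / T - 1.0 / model.T_ref))
    return float(k) if np.ndim(T_c) == 0 else k


def shelf_life(
    model: ArrheniusModel,
    T_c: float,
    initial: Optional[float] = None,
    limit: Optional[float] = None,
) -> float:
    """Days until the quality index reaches its acceptance limit at ``T_c`` °C.

    First order: ln(initial/limit) / k(T); zero order: (initial − limit) / k(T).
    ``initial`` and ``limit`` default to the model's stored values (for
    concentrations the conventional limit is 50% of the initial level).
    """
    initial = model.initial_value if initial is None else initial
    limit = model.limit_value if limit is None else limit
    if initial is None or limit is None:
        raise ValueError("shelf life needs both initial and limit values")
    if limit >= initial:
        raise ValueError("acceptance limit must lie below the initial value")
    k = rate_at(model, T_c)
    if model.order == "first":
        if limit <= 0 or initial <= 0:
            raise ValueError("first-order shelf life needs positive initial and limit")
        return math.log(initial / limit) / k
    return (initial - limit) / k


def effective_temperature(
    profile: TemperatureProfile, model: ArrheniusModel
) -> float:
    """Effective constant temperature (°C) equivalent to a fluctuating profile.

    The time-weighted mean rate k_eff = Σ k(T_i)·t_i / t_tot is mapped back
    through the Arrhenius relation: 1/T_eff = 1/T_ref − (R/E_a)·ln(k_eff/k_ref).
    The result always lies within [min T_i, max T_i] and, by Jensen's
    inequality, at or above the arithmetic time-weighted mean temperature.

    With E_a = 0 the rate carries no temperature information; the harmonic
    time-weighted mean (the E_a → 0 limit) is returned with a warning.
    """
    durs = np.array([d for d, _ in profile.segments], float)
    temps_k = np.array([t for _, t in profile.segments], float) + KELVIN
    if model.E_a == 0:
        warnings.warn(
            "E_a = 0: effective temperature degenerates to the harmonic "
            "time-weighted mean",
            stacklevel=2,
        )
        inv = np.sum(durs / temps_k) / durs.sum()
        return float(1.0 / inv - KELVIN)
    k_seg = model.k_ref * np.exp(
        -(model.E_a / R_GAS) * (1.0 / temps_k - 1.0 / model.T_ref)
    )
    k_eff = float(np.sum(k_seg * durs) / durs.sum())
    inv_teff = 1.0 / model.T_ref - (R_GAS / model.E_a) * math.log(k_eff / model.k_ref)
    return float(1.0 / inv_teff - KELVIN)


def predict_nonisothermal(
    model: ArrheniusModel,
    profile: TemperatureProfile,
    initial: Optional[float] = None,
) -> pd.DataFrame:
    """Quality trajectory under a piecewise-constant temperature profile.

    Each segment is integrated in closed form (first order multiplies by
    exp(−k·Δt); zero order subtracts k·Δt), sampling the value at every
    segment boundary.  Durations are stored in hours and converted to days.
    Zero-order values are *not* floored: a prediction crossing below the
    acceptance limit is reported as-is and flagged in the ``below_limit``
    column.
    """
    value = model.initial_value if initial is None else initial
    if value is None:
        raise ValueError("need an initial value")
    times = [0.0]
    values = [float(value)]
    temps: list[float] = [profile.segments[0][1]]
    t = 0.0
    for dur_h, temp_c in profile.segments:
        dt_days = dur_h / 24.0
        k = rate_at(model, temp_c)
        if model.order == "first":
            value *= math.exp(-k * dt_days)
        else:
            value -= k * dt_days
        t += dt_days
        times.append(t)
        values.append(float(value))
        temps.append(temp_c)
    out = pd.DataFrame({"time_d": times, "value": values, "T_C": temps})
    if model.limit_value is not None:
        out["below_limit"] = out["value"] < model.limit_value
    return out


def relative_error(k_exp: float, k_fit: float) -> float:
    """Percent relative error 100·(k_exp − k_fit)/k_exp; |RE| ≤ 20% is accepted."""
    if k_exp == 0:
        raise ValueError("experimental rate must be nonzero")
    return 100.0 * (k_exp - k_fit) / k_exp
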
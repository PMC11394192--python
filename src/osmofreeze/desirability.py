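"""Multi-response optimisation of fitted surfaces via composite desirability.

Each response prediction y is mapped to an individual desirability d ∈ [0, 1]
by a Derringer–Suich linear ramp, and candidate settings are ranked by the
weighted geometric mean D of the individual desirabilities.  The optimiser is
fully deterministic: a coarse grid search over the closed factor cube picks
the best cell (ties broken toward the cheapest process: lowest temperature,
then shortest time, then lowest concentration), and a Nelder–Mead simplex
refines from there with evaluations clamped to the cube, so the search never
extrapolates outside the experimental region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import minimize as _nm_minimize

from .doe import FactorSpace, QuadraticModel

__all__ = [
    "Criterion",
    "DesirabilityResult",
    "InfeasibleCriteriaError",
    "individual_desirability",
    "composite_desirability",
    "optimize",
    "validation_error",
]

Goal = Literal["minimize", "maximize", "upper_bound", "target"]


class InfeasibleCriteriaError(ValueError):
    """Composite desirability is zero everywhere in the factor cube."""


@dataclass(frozen=True)
class Criterion:
    """Optimisation goal for one response.

    Ramp shapes (all linear, raised to ``weight``, clamped to [0, 1]):

    - ``minimize``:    d = 1 at ``bound_low``, 0 at ``bound_high``.
    - ``maximize``:    d = 0 at ``bound_low``, 1 at ``bound_high``.
    - ``upper_bound``: d = 1 for y ≤ ``bound_low`` (the stated cap) falling
      to 0 at ``bound_high`` — i.e. anything at or under the cap is fully
      acceptable, the standard "smaller-is-better with a target at the cap"
      constraint form.
    - ``target``:      d = 1 at ``target``, 0 at either bound (triangular).

    Bounds left as ``None`` are resolved by :func:`optimize` from the range
    of the fitted surface over the factor cube.
    """

    response_name: str
    goal: Goal
    bound_low: Optional[float] = None
    bound_high: Optional[float] = None
    target: Optional[float] = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if (
            self.bound_low is not None
            and self.bound_high is not None
            and not self.bound_low < self.bound_high
        ):
            raise ValueError("bound_low must be below bound_high")
        if self.goal == "upper_bound" and self.bound_low is None:
            raise ValueError("upper_bound criterion needs its cap in bound_low")
        if self.goal == "target" and self.target is None:
            raise ValueError("target criterion needs a target value")


@dataclass(frozen=True)
class DesirabilityResult:
    """Optimal setting plus its individual and composite desirabilities."""

    optimum_actual: tuple[float, float, float]
    optimum_coded: tuple[float, float, float]
    d_individual: dict[str, float]
    D_composite: float
    predictions: dict[str, float]


def individual_desirability(y, c: Criterion):
    """Desirability of response value(s) ``y`` under criterion ``c``."""
    y = np.asarray(y, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response values must be finite")
    lo, hi = c.bound_low, c.bound_high
    if c.goal in ("minimize", "upper_bound"):
        if lo is None or hi is None:
            raise ValueError("criterion bounds unresolved")
        d = (hi - y) / (hi - lo)
    elif c.goal == "maximize":
        if lo is None or hi is None:
            raise ValueError("criterion bounds unresolved")
        d = (y - lo) / (hi - lo)
    elif c.goal == "target":
        if lo is None or hi is None:
            raise ValueError("criterion bounds unresolved")
        d = np.where(
            y <= c.target,
            (y - lo) / (c.target - lo),
            (hi - y) / (hi - c.target),
        )
    else:  # pragma: no cover - guarded by the Literal type
        raise ValueError(f"unknown goal {c.goal!r}")
    d = np.clip(d, 0.0, 1.0) ** c.weight
    return float(d) if d.ndim == 0 else d


def composite_desirability(
    d: Mapping[str, float], weights: Optional[Mapping[str, float]] = None
) -> float:
    """Weighted geometric mean of individual desirabilities; 0 if any d is 0."""
    if not d:
        raise ValueError("need at least one desirability value")
    total, wsum = 0.0, 0.0
    for name, di in d.items():
        if not 0.0 <= di <= 1.0:
            raise ValueError(f"desirability for {name!r} outside [0, 1]")
        w = 1.0 if weights is None else weights[name]
        if di == 0.0:
            return 0.0
        total += w * math.log(di)
        wsum += w
    return math.exp(total / wsum)


def _surface_extremum(
    model: QuadraticModel, space: FactorSpace, grid_best: np.ndarray, sign: float
) -> float:
    """Refine a grid extremum of one surface by clamped Nelder–Mead."""
    lows = np.array([f.low for f in space.factors])
    highs = np.array([f.high for f in space.factors])

    def obj(x):
        return sign * model.predict(*np.clip(x, lows, highs))

    res = _nm_minimize(obj, grid_best, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-12})
    return float(sign * min(res.fun, obj(grid_best)))


def _resolve_bounds(
    criteria: Sequence[Criterion],
    surfaces: Mapping[str, np.ndarray],
    model_map: Mapping[str, QuadraticModel],
    space: FactorSpace,
    grids: tuple[np.ndarray, np.ndarray, np.ndarray],
) -> list[Criterion]:
    """Fill missing criterion bounds from each surface's range over the cube.

    Grid extrema are refined by a local search so the resolved ramp reaches
    d = 1 (or 0) only at the surface's true extremum, not at the nearest
    grid point — otherwise the desirability would plateau around it.
    """
    Tg, tg, Cg = grids
    resolved = []
    for c in criteria:
        surf = surfaces[c.response_name]
        model = model_map[c.response_name]
        needs_min = (c.goal != "upper_bound" and c.bound_low is None)
        needs_max = c.bound_high is None
        ymin = ymax = None
        if needs_min:
            i = np.unravel_index(np.argmin(surf), surf.shape)
            ymin = _surface_extremum(
                model, space, np.array([Tg[i], tg[i], Cg[i]]), 1.0
            )
        if needs_max:
            i = np.unravel_index(np.argmax(surf), surf.shape)
            ymax = _surface_extremum(
                model, space, np.array([Tg[i], tg[i], Cg[i]]), -1.0
            )
        lo, hi = c.bound_low, c.bound_high
        if c.goal == "upper_bound":
            hi = ymax if hi is None else hi
            if hi <= c.bound_low:  # cap above the whole surface: always desirable
                hi = c.bound_low + 1.0
        else:
            lo = ymin if lo is None else lo
            hi = ymax if hi is None else hi
            if hi <= lo:  # flat surface: degenerate ramp
                hi = lo + 1.0
        resolved.append(replace(c, bound_low=lo, bound_high=hi))
    return resolved


def optimize(
    models: Sequence[QuadraticModel] | Mapping[str, QuadraticModel],
    criteria: Sequence[Criterion],
    space: FactorSpace,
    grid_n: int = 51,
    refine: bool = True,
) -> DesirabilityResult:
    """Maximise composite desirability over the closed factor cube.

    Deterministic and idempotent: an exhaustive ``grid_n``³ grid search
    (first-occurrence argmax implements the cheapest-process tie-break)
    seeds a Nelder–Mead refinement whose evaluations are clamped to the
    cube.  Raises :class:`InfeasibleCriteriaError`, naming the most binding
    criterion, if D is zero everywhere on the grid.
    """
    if grid_n < 11:
        raise ValueError("grid_n must be at least 11")
    model_map = (
        dict(models) if isinstance(models, Mapping)
        else {m.response_name: m for m in models}
    )
    for c in criteria:
        if c.response_name not in model_map:
            raise KeyError(f"criterion references unknown response {c.response_name!r}")
    if not criteria:
        raise ValueError("need at least one criterion")

    axes = [np.linspace(f.low, f.high, grid_n) for f in space.factors]
    Tg, tg, Cg = np.meshgrid(*axes, indexing="ij")
    surfaces = {
        name: model_map[name].predict(Tg, tg, Cg)
        for name in {c.response_name for c in criteria}
    }
    crits = _resolve_bounds(criteria, surfaces, model_map, space, (Tg, tg, Cg))

    logD = np.zeros_like(Tg)
    wsum = sum(c.weight for c in crits)
    zero_frac = {}
    with np.errstate(divide="ignore"):
        for c in crits:
            d = individual_desirability(surfaces[c.response_name], c)
            zero_frac[c.response_name] = float(np.mean(d == 0.0))
            logD = logD + c.weight * np.log(d)
    D = np.exp(logD / wsum)

    if not np.any(D > 0):
        worst = max(zero_frac, key=zero_frac.get)
        raise InfeasibleCriteriaError(
            f"composite desirability is zero everywhere; "
            f"binding criterion: {worst!r}"
        )

    # np.argmax returns the first maximum in C order, i.e. lowest
    # temperature, then shortest time, then lowest concentration.
    idx = np.unravel_index(np.argmax(D), D.shape)
    best = np.array([Tg[idx], tg[idx], Cg[idx]])

    lows = np.array([f.low for f in space.factors])
    highs = np.array([f.high for f in space.factors])

    def neg_D(x: np.ndarray) -> float:
        xc = np.clip(x, lows, highs)
        dmap = {
            c.response_name: individual_desirability(
                model_map[c.response_name].predict(*xc), c
            )
            for c in crits
        }
        return -composite_desirability(
            dmap, {c.response_name: c.weight for c in crits}
        )

    if refine:
        res = _nm_minimize(
            neg_D,
            best,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000},
        )
        cand = np.clip(res.x, lows, highs)
        if -neg_D(cand) >= D[idx]:
            best = cand

    preds = {name: float(m.predict(*best)) for name, m in model_map.items()}
    d_ind = {
        c.response_name: individual_desirability(preds[c.response_name], c)
        for c in crits
    }
    return DesirabilityResult(
        optimum_actual=tuple(float(v) for v in best),
        optimum_coded=space.code(best),
        d_individual=d_ind,
        D_composite=composite_desirability(
            d_ind, {c.response_name: c.weight for c in crits}
        ),
        predictions=preds,
    )


def validation_error(experimental: float, predicted: float) -> float:
    """Signed percent error 100·(experimental − predicted)/experimental.

    The absolute value is conventionally compared against a 20% acceptance
    limit when validating surface predictions against an independent
    experiment.
    """
    if experimental == 0:
        raise ValueError("experimental value must be nonzero")
    return 100.0 * (experimental - predicted) / experimental
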
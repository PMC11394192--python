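"""Delimited-table reading with schema validation, and the end-to-end driver.

All user-facing files are comma-separated, dot-decimal, UTF-8, with a header
row; temperatures in user files are always °C (kelvin appears only inside the
kinetics module).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import presets
from .desirability import Criterion, optimize, validation_error
from .doe import FactorSpace
from .kinetics import ArrheniusModel, T_REF_C_DEFAULT, effective_temperature, shelf_life

__all__ = [
    "SCHEMAS",
    "SchemaError",
    "RowError",
    "RunConfig",
    "read_table",
    "reproduce_study",
    "write_report",
]


class SchemaError(ValueError):
    """The file's header does not match the requested schema."""


class RowError(ValueError):
    """One or more rows failed numeric validation; carries line numbers."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("; ".join(problems))


#: Schema name -> (required numeric columns, optional string columns).
SCHEMAS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "od_raw": (
        ("run_id", "T_C", "t_min", "C_glyc_pct", "M0_g", "m0_g", "M_g", "m_g",
         "aw", "L", "a", "b", "Fmax_N"),
        (),
    ),
    "design": (("run_id", "T_C", "t_min", "C_glyc_pct", "x1", "x2", "x3"), ()),
    "storage_series": (("T_C", "time_d", "value"), ("quality", "treatment", "unit")),
    "profile": (("segment", "duration_h", "T_C"), ()),
}


def read_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read and validate a CSV against one of the package schemas.

    Missing required columns raise :class:`SchemaError` naming the columns;
    unparseable numeric cells are collected across the file and raised as a
    single :class:`RowError` with 1-based data line numbers.
    """
    if schema_name not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_name!r}")
    numeric_cols, _ = SCHEMAS[schema_name]
    raw = pd.read_csv(
        path, dtype=str, skipinitialspace=True, encoding="utf-8",
        keep_default_na=False,
    )
    raw = raw.replace("", None)
    missing = [c for c in numeric_cols if c not in raw.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    problems: list[str] = []
    out = raw.copy()
    for col in numeric_cols:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        for i in raw.index[bad]:
            problems.append(
                f"{path}: line {i + 2}: column {col!r}: "
                f"cannot parse {raw.loc[i, col]!r} as a number"
            )
        out[col] = converted
    if problems:
        raise RowError(problems)
    return out


@dataclass(frozen=True)
class RunConfig:
    """Configuration bundle for the end-to-end driver.

    Defaults reproduce the published study: its factor space, its three
    optimisation criteria, its kinetic parameter presets, the −18 °C
    reference temperature, and the parameter-table sensory rejection score.
    """

    factor_space: FactorSpace = presets.FACTOR_SPACE
    criteria: tuple[Criterion, ...] = (
        Criterion("water_activity", "minimize"),
        Criterion("water_loss", "upper_bound", bound_low=5.0),
        Criterion("delta_e", "upper_bound", bound_low=8.0),
    )
    kinetic_presets: Optional[dict[tuple[str, str], ArrheniusModel]] = None
    T_ref_c: float = T_REF_C_DEFAULT
    sensory_limit_preset: str = "table"
    seed: int = 0
    out_dir: Optional[Path] = None

    def __post_init__(self) -> None:
        if self.sensory_limit_preset not in presets.SENSORY_LIMIT_PRESETS:
            raise ValueError(
                f"unknown sensory limit preset {self.sensory_limit_preset!r}"
            )
        if not -40.0 <= self.T_ref_c <= 0.0:
            raise ValueError("reference temperature must lie in [-40, 0] °C")

    @property
    def models(self) -> dict[tuple[str, str], ArrheniusModel]:
        return dict(
            presets.KINETIC_PRESETS if self.kinetic_presets is None
            else self.kinetic_presets
        )


def reproduce_study(
    sensory_limit_preset: str = "table",
    grid_n: int = 51,
    ea_grid_kj: Sequence[float] = (40.0, 60.0, 80.0, 88.8, 100.0, 120.0),
    config: Optional[RunConfig] = None,
) -> dict:
    """Recompute the study's headline results from the published constants.

    Deterministic end-to-end driver returning a JSON-serialisable report:
    surface predictions at the reported optimum and at the design centre,
    validation percent errors, the desirability optimum, closed-form shelf
    lives from the kinetic presets, the published sensory shelf-life ratios,
    and the effective temperature of the temperature-abuse cycle over a grid
    of activation energies.
    """
    if config is None:
        config = RunConfig(sensory_limit_preset=sensory_limit_preset)
    models = presets.surface_models()
    T_opt, t_opt, C_opt = presets.OPTIMUM

    predictions_at_optimum = {
        name: float(m.predict(T_opt, t_opt, C_opt)) for name, m in models.items()
    }
    center = tuple(f.center for f in presets.FACTOR_SPACE.factors)
    predictions_at_center = {
        name: float(m.predict(*center)) for name, m in models.items()
    }

    validation = {
        name: {
            "experimental": exp,
            "predicted": pred,
            "pct_error": validation_error(exp, pred),
            "accepted": abs(validation_error(exp, pred)) <= 20.0,
        }
        for name, (exp, pred) in presets.VALIDATION_PAIRS.items()
    }

    opt = optimize(models, list(config.criteria), config.factor_space, grid_n=grid_n)

    sensory_limit = presets.SENSORY_LIMIT_PRESETS[config.sensory_limit_preset]
    temps = list(presets.STORAGE_TEMPERATURES_C) + [config.T_ref_c]
    shelf_lives = {}
    for (quality, treatment), model in config.models.items():
        limit = sensory_limit if quality == "sensory" else model.limit_value
        shelf_lives[f"{quality}:{treatment}"] = {
            str(T): shelf_life(model, T, limit=limit) for T in temps
        }

    printed = presets.PRINTED_SHELF_LIVES_D
    sensory_ratios = {
        str(T): printed[("sensory", "od")][T] / printed[("sensory", "untreated")][T]
        for T in presets.STORAGE_TEMPERATURES_C
    }

    profile = presets.reference_profile()
    teff_by_ea = {}
    for ea in ea_grid_kj:
        probe = config.models[("vitamin_c", "untreated")]
        probe = type(probe)(
            k_ref=probe.k_ref, E_a=ea * 1000.0, T_ref=probe.T_ref,
            order=probe.order, initial_value=probe.initial_value,
            limit_value=probe.limit_value,
        )
        teff_by_ea[str(ea)] = effective_temperature(profile, probe)

    return {
        "optimum_conditions": {"T_C": T_opt, "t_min": t_opt, "C_glyc_pct": C_opt},
        "predictions_at_optimum": predictions_at_optimum,
        "predictions_at_center": predictions_at_center,
        "validation": validation,
        "desirability_optimum": {
            "actual": list(opt.optimum_actual),
            "coded": list(opt.optimum_coded),
            "d_individual": opt.d_individual,
            "D_composite": opt.D_composite,
        },
        "shelf_life_days": shelf_lives,
        "printed_sensory_shelf_life_ratio_od_over_untreated": sensory_ratios,
        "max_printed_sensory_shelf_life_ratio": max(sensory_ratios.values()),
        "cycle_profile": {
            "segments_h_C": [list(s) for s in profile.segments],
            "total_hours": profile.total_hours,
            "time_weighted_mean_C": profile.time_weighted_mean_c(),
        },
        "effective_temperature_C_by_Ea_kJ": teff_by_ea,
    }


def write_report(report: dict, out_dir: str | Path) -> Path:
    """Write the report as JSON (plus flat CSV tables) under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True))
    pd.DataFrame(
        [
            {"response": k, **v}
            for k, v in report["validation"].items()
        ]
    ).to_csv(out / "validation.csv", index=False)
    rows = []
    for key, by_T in report["shelf_life_days"].items():
        quality, treatment = key.split(":")
        for T, sl in by_T.items():
            rows.append(
                {"quality": quality, "treatment": treatment, "T_C": float(T),
                 "shelf_life_d": sl}
            )
    pd.DataFrame(rows).to_csv(out / "shelf_life.csv", index=False)
    return path
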
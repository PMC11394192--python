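"""Synthetic experiment generators for the OD design and frozen-storage study.

These emulate the two data-producing stages of an osmodehydrofreezing study:

* a Box–Behnken OD experiment, sampling each response from its published
  second-order surface plus additive Gaussian measurement noise; and
* an isothermal frozen-storage (ASLT) study, simulating first-order decay of
  vitamin C and lycopene with multiplicative lognormal noise and zero-order
  sensory-score decay with additive Gaussian noise, with rates set by the
  published Arrhenius parameters.

All generators are bit-reproducible given a seed.  They emulate measurement
noise only — not sample-to-sample biological variability, batch effects, or
deviations from the assumed kinetic forms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .doe import DesignRun
from .kinetics import ArrheniusModel, IsothermalSeries, TemperatureProfile, rate_at

__all__ = [
    "DEFAULT_OD_NOISE_SD",
    "ODSurfaceSpec",
    "StorageStudySpec",
    "simulate_od_experiment",
    "simulate_degradation",
    "make_cycle_profile",
]

#: Default measurement-noise standard deviations per OD response (response
#: units), on the scale of the replicate scatter typical of such assays.
DEFAULT_OD_NOISE_SD: dict[str, float] = {
    "water_activity": 0.005,
    "water_loss": 0.2,
    "solid_gain": 0.02,
    "delta_e": 0.4,
    "firmness": 0.15,
}

#: Sensory scores live on a 1–9 scale; simulated values are truncated at 1.
SENSORY_SCALE_MIN = 1.0


@dataclass(frozen=True)
class ODSurfaceSpec:
    """Generating surfaces and noise levels for a synthetic OD experiment.

    ``coefficients`` maps response name to its 10-term uncoded coefficient
    vector (defaults to the published regression equations).
    """

    coefficients: Mapping[str, np.ndarray] = None  # type: ignore[assignment]
    noise_sd: Mapping[str, float] = None  # type: ignore[assignment]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coefficients is None:
            from .presets import UNCODED_SURFACES

            object.__setattr__(self, "coefficients", dict(UNCODED_SURFACES))
        if self.noise_sd is None:
            object.__setattr__(
                self,
                "noise_sd",
                {k: DEFAULT_OD_NOISE_SD.get(k, 0.0) for k in self.coefficients},
            )
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise_sd must be non-negative")


def simulate_od_experiment(
    spec: ODSurfaceSpec, design: Sequence[DesignRun]
) -> pd.DataFrame:
    """Simulate one OD experiment over a design.

    Returns a tidy table with the factor settings and one column per
    response: surface value plus N(0, noise_sd²).  Centre replicates differ
    only by noise.  Deterministic given ``spec.seed``.
    """
    from .doe import _eval_quad

    rng = np.random.default_rng(spec.seed)
    T = np.array([r.actual[0] for r in design])
    t = np.array([r.actual[1] for r in design])
    C = np.array([r.actual[2] for r in design])
    out = pd.DataFrame(
        {
            "run_id": [r.run_id for r in design],
            "T_C": T,
            "t_min": t,
            "C_glyc_pct": C,
        }
    )
    for name, coeffs in spec.coefficients.items():
        clean = _eval_quad(np.asarray(coeffs, float), T, t, C)
        sd = float(spec.noise_sd.get(name, 0.0))
        out[name] = clean + (rng.normal(0.0, sd, size=len(design)) if sd > 0 else 0.0)
    return out


@dataclass(frozen=True)
class StorageStudySpec:
    """Design of a synthetic isothermal frozen-storage (ASLT) study.

    ``models`` maps (quality, treatment) to the generating Arrhenius model
    (defaults to the published kinetic parameters).  ``sampling_times``
    maps storage temperature (°C) to sampling days; the defaults span
    roughly one sensory shelf life at each temperature, denser at the warm
    (fast-degrading) conditions.
    """

    models: Mapping[tuple[str, str], ArrheniusModel] = None  # type: ignore[assignment]
    temperatures_c: tuple[float, ...] = (-5.0, -8.0, -14.0, -23.0)
    sampling_times: Mapping[float, tuple[float, ...]] = None  # type: ignore[assignment]
    sigma: float = 0.05  # multiplicative lognormal sd for concentrations
    sensory_sigma: float = 0.3  # additive sd, score units
    replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.models is None:
            from .presets import KINETIC_PRESETS

            object.__setattr__(self, "models", dict(KINETIC_PRESETS))
        if self.sampling_times is None:
            horizons = {-5.0: 30.0, -8.0: 45.0, -14.0: 90.0, -23.0: 180.0}
            times = {
                T: tuple(np.linspace(0.0, horizons.get(T, 120.0), 8))
                for T in self.temperatures_c
            }
            object.__setattr__(self, "sampling_times", times)
        if self.sigma < 0 or self.sensory_sigma < 0:
            raise ValueError("noise levels must be non-negative")
        if any(not -40.0 <= T <= 0.0 for T in self.temperatures_c):
            raise ValueError("storage temperatures must lie in [-40, 0] °C")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def simulate_degradation(spec: StorageStudySpec) -> list[IsothermalSeries]:
    """Simulate the full storage study: one series per quality/treatment/temperature.

    First-order qualities decay as C0·exp(−k(T)·t) with multiplicative
    lognormal noise (so simulated values stay strictly positive); the
    zero-order sensory score decays as S0 − k(T)·t with additive Gaussian
    noise, truncated at the scale floor of 1 (truncation triggers a
    warning).  Replicates appear as repeated sampling times within a series.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[IsothermalSeries] = []
    truncated = 0
    for (quality, treatment), model in spec.models.items():
        c0 = model.initial_value
        if c0 is None:
            raise ValueError(f"model for {(quality, treatment)} lacks initial_value")
        for T in spec.temperatures_c:
            k = rate_at(model, T)
            times = np.repeat(np.asarray(spec.sampling_times[T], float), spec.replicates)
            if model.order == "first":
                clean = c0 * np.exp(-k * times)
                noise = rng.lognormal(0.0, spec.sigma, size=times.size) if spec.sigma > 0 else 1.0
                values = clean * noise
            else:
                clean = c0 - k * times
                noise = (
                    rng.normal(0.0, spec.sensory_sigma, size=times.size)
                    if spec.sensory_sigma > 0
                    else 0.0
                )
                values = clean + noise
                n_below = int(np.sum(values < SENSORY_SCALE_MIN))
                if n_below:
                    truncated += n_below
                    values = np.maximum(values, SENSORY_SCALE_MIN)
            out.append(
                IsothermalSeries(
                    quality_name=f"{quality}:{treatment}",
                    temperature_c=T,
                    times=tuple(times),
                    values=tuple(float(v) for v in values),
                )
            )
    if truncated:
        warnings.warn(
            f"{truncated} simulated sensory value(s) truncated at the scale "
            f"floor {SENSORY_SCALE_MIN}; fitting windows should end earlier",
            stacklevel=2,
        )
    return out


def make_cycle_profile(
    cycle: Sequence[tuple[float, float]], repeats: int = 1
) -> TemperatureProfile:
    """Build a piecewise-constant profile by repeating a (°C, hours) cycle."""
    if repeats < 1:
        raise ValueError("repeats must be at least 1")
    if any(hours <= 0 for _, hours in cycle):
        raise ValueError("segment durations must be positive")
    segments = tuple((float(hours), float(t_c)) for t_c, hours in cycle) * repeats
    return TemperatureProfile(segments=segments)
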
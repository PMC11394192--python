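"""Published study constants: factor space, regression surfaces, kinetic parameters.

These are the fitted results reported for the cherry-tomato osmodehydrofreezing
study this package reproduces: the Box–Behnken factor ranges, the uncoded
second-order regression equations for the five OD responses, the validation
pairs at the optimum, and the Arrhenius kinetic parameters for vitamin C,
lycopene and sensory quality of untreated and OD-pretreated frozen tomatoes.

Coefficient vectors follow the package-wide term order
(1, T, t, C, T², t², C², T·t, T·C, t·C) with T in °C, t in min, C in % w/w.
"""

from __future__ import annotations

import numpy as np

from .doe import Factor, FactorSpace, QuadraticModel
from .kinetics import ArrheniusModel, TemperatureProfile

__all__ = [
    "FACTOR_SPACE",
    "UNCODED_SURFACES",
    "surface_models",
    "OPTIMUM",
    "VALIDATION_PAIRS",
    "KINETIC_PRESETS",
    "PRINTED_SHELF_LIVES_D",
    "SENSORY_LIMIT_PRESETS",
    "STORAGE_TEMPERATURES_C",
    "REFERENCE_CYCLE",
    "REFERENCE_CYCLE_REPEATS",
    "REFERENCE_CYCLE_TEFF_C",
]

#: OD design factors: temperature (°C), immersion time (min), glycerol (% w/w).
FACTOR_SPACE = FactorSpace(
    (
        Factor("temperature", 25.0, 35.0, 45.0, "°C"),
        Factor("time", 30.0, 60.0, 90.0, "min"),
        Factor("glycerol", 50.0, 60.0, 70.0, "% w/w"),
    )
)

#: Uncoded (actual-unit) coefficients of the published regression equations.
#: In the firmness/colour equations the factor units are as in FACTOR_SPACE.
#: The solid-gain equation's final interaction is read as t·C (the published
#: form repeats T·C, an apparent typographical slip — t·C is the only
#: interaction otherwise missing from the ten-term basis).
UNCODED_SURFACES: dict[str, np.ndarray] = {
    "water_activity": np.array(
        [1.871, -0.014408, -0.001750, -0.02115,
         0.000232, 0.000017, 0.000185,
         -0.000007, -0.000032, -0.000003]
    ),
    "water_loss": np.array(
        [-95.8, 0.643, 0.044, 2.887,
         -0.00325, -0.000560, -0.02251,
         0.00133, -0.00602, -0.00022]
    ),
    "solid_gain": np.array(
        [6.40, -0.262, 0.0183, -0.085,
         0.00394, -0.000061, 0.00086,
         0.000146, -0.00008, -0.000255]
    ),
    "delta_e": np.array(
        [-15.5, -0.278, -0.5008, 1.386,
         -0.00941, 0.003228, -0.01624,
         0.00109, 0.01511, 0.00110]
    ),
    "firmness": np.array(
        [12.90, -0.210, -0.3016, 0.016,
         0.00374, 0.001656, -0.00055,
         0.000572, -0.00076, 0.001300]
    ),
}


def surface_models() -> dict[str, QuadraticModel]:
    """The five published response surfaces as :class:`QuadraticModel` objects."""
    return {
        name: QuadraticModel.from_uncoded(name, coeffs, FACTOR_SPACE)
        for name, coeffs in UNCODED_SURFACES.items()
    }


#: Reported optimal OD conditions (T °C, t min, glycerol % w/w).
OPTIMUM = (36.0, 72.0, 61.5)

#: Validation at the optimum: response -> (experimental, predicted) as published.
VALIDATION_PAIRS: dict[str, tuple[float, float]] = {
    "water_loss": (4.881, 4.890),
    "solid_gain": (0.130, 0.152),
    "water_activity": (0.9105, 0.9117),
    "delta_e": (6.24, 7.49),
    "firmness": (2.08, 1.26),
}

#: Isothermal frozen-storage temperatures of the ASLT study (°C).
STORAGE_TEMPERATURES_C = (-5.0, -8.0, -14.0, -23.0)

#: Published Arrhenius kinetic parameters, keyed (quality, treatment).
#: Vitamin C and lycopene degrade first-order (initial contents in mg/100 g,
#: acceptance limit 50% retention); sensory score degrades zero-order on the
#: 9-point hedonic scale with rejection at score 4.
KINETIC_PRESETS: dict[tuple[str, str], ArrheniusModel] = {
    ("vitamin_c", "untreated"): ArrheniusModel(
        k_ref=0.0033, E_a=88.8e3, order="first",
        initial_value=38.79, limit_value=38.79 / 2, quality="vitamin_c",
    ),
    ("vitamin_c", "od"): ArrheniusModel(
        k_ref=0.0025, E_a=115.6e3, order="first",
        initial_value=39.15, limit_value=39.15 / 2, quality="vitamin_c",
    ),
    ("lycopene", "untreated"): ArrheniusModel(
        k_ref=0.0025, E_a=88.5e3, order="first",
        initial_value=10.35, limit_value=10.35 / 2, quality="lycopene",
    ),
    ("lycopene", "od"): ArrheniusModel(
        k_ref=0.0020, E_a=86.1e3, order="first",
        initial_value=11.35, limit_value=11.35 / 2, quality="lycopene",
    ),
    ("sensory", "untreated"): ArrheniusModel(
        k_ref=0.017, E_a=56.58e3, order="zero",
        initial_value=7.1, limit_value=4.0, quality="sensory",
    ),
    ("sensory", "od"): ArrheniusModel(
        k_ref=0.009, E_a=57.10e3, order="zero",
        initial_value=9.0, limit_value=4.0, quality="sensory",
    ),
}

#: Shelf lives (days) as published per storage temperature.  These derive
#: from per-temperature fitted rates on unpublished raw data and are not
#: consistent with the closed-form shelf life computed from (k_ref, E_a)
#: above; they are retained for ratio-level comparisons (e.g. the up-to-3.5×
#: sensory shelf-life extension by OD pretreatment).
PRINTED_SHELF_LIVES_D: dict[tuple[str, str], dict[float, float]] = {
    ("vitamin_c", "untreated"): {-5.0: 20, -8.0: 37, -14.0: 87, -23.0: 402},
    ("vitamin_c", "od"): {-5.0: 15, -8.0: 33, -14.0: 102, -23.0: 737},
    ("lycopene", "untreated"): {-5.0: 44, -8.0: 68, -14.0: 130, -23.0: 415},
    ("lycopene", "od"): {-5.0: 46, -8.0: 70, -14.0: 131, -23.0: 395},
    ("sensory", "untreated"): {-5.0: 14, -8.0: 19, -14.0: 30, -23.0: 67},
    ("sensory", "od"): {-5.0: 50, -8.0: 66, -14.0: 100, -23.0: 207},
}

#: Sensory rejection score presets.  The kinetic parameter table uses 4
#: ("table"); the accompanying text states 5 ("text").  The limit is always
#: an explicit input to shelf-life computations, never a hidden default.
SENSORY_LIMIT_PRESETS = {"table": 4.0, "text": 5.0}

#: Fluctuating-storage validation scenario: one cycle of the temperature
#: abuse programme (°C, hours), applied REFERENCE_CYCLE_REPEATS times.
REFERENCE_CYCLE: list[tuple[float, float]] = [(-12.0, 24.0), (-5.0, 24.0), (-8.0, 24.0)]
REFERENCE_CYCLE_REPEATS = 3
#: Effective temperature reported for that scenario (°C); the activation
#: energy behind it is not published, so it is a qualitative anchor only.
REFERENCE_CYCLE_TEFF_C = -7.3


def reference_profile() -> TemperatureProfile:
    """The three-times-repeated temperature-abuse cycle as a profile object."""
    from .simulate import make_cycle_profile

    return make_cycle_profile(REFERENCE_CYCLE, REFERENCE_CYCLE_REPEATS)
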
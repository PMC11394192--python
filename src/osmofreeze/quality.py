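"""Scalar process and quality indices for osmotic dehydration and freeze–thaw.

Mass-transfer indices (water loss, solid gain) are expressed per gram of the
sample's *initial dry mass* — note that a sizeable fraction of the literature
normalises by initial *total* mass instead, which yields values roughly an
order of magnitude smaller.  Colour change is the Euclidean distance in CIELab
space; drip loss is the percent weight lost as exudate on thawing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ODMassRecord",
    "ColorReading",
    "ThawWeights",
    "DELTA_E_VISIBLE",
    "water_loss",
    "solid_gain",
    "delta_e",
    "is_visible_difference",
    "drip_loss",
]

#: CIELab distance above which a colour difference is conventionally
#: perceptible to the eye.  Stored as a named constant; :func:`delta_e`
#: itself always returns the raw numeric distance.
DELTA_E_VISIBLE = 2.0


@dataclass(frozen=True)
class ODMassRecord:
    """Total/dry mass of one sample at the start and after ``t`` minutes of OD.

    Attributes
    ----------
    M0, m0 : float
        Total and dry mass (g) at OD time zero.
    M, m : float
        Total and dry mass (g) at OD time ``t``.
    t : float
        Osmotic-dehydration time in minutes.
    """

    M0: float
    m0: float
    M: float
    m: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.M0 <= 0:
            raise ValueError("initial total mass M0 must be positive")
        if self.m0 <= 0:
            raise ValueError("zero initial dry mass")
        if self.m0 > self.M0:
            raise ValueError("dry mass m0 cannot exceed total mass M0")
        if self.M < 0 or self.m < 0:
            raise ValueError("masses must be non-negative")
        if self.m > self.M:
            raise ValueError("dry mass m cannot exceed total mass M")


@dataclass(frozen=True)
class ColorReading:
    """One CIELab colour measurement (L lightness, a red–green, b yellow–blue)."""

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.L <= 100.0:
            raise ValueError("CIELab lightness L must lie in [0, 100]")


@dataclass(frozen=True)
class ThawWeights:
    """Sample weight (g) before and after thawing."""

    w_before: float
    w_after: float

    def __post_init__(self) -> None:
        if self.w_before <= 0:
            raise ValueError("weight before thawing must be positive")
        if self.w_after < 0:
            raise ValueError("weight after thawing cannot be negative")


def water_loss(rec: ODMassRecord) -> float:
    """Water loss WL = ((M0 − m0) − (M − m)) / m0, in g water / g initial dry mass.

    Negative values (net water uptake) are physically meaningful and are
    returned as-is, never clipped: the response-surface optimiser needs the
    raw surface.
    """
    return ((rec.M0 - rec.m0) - (rec.M - rec.m)) / rec.m0


def solid_gain(rec: ODMassRecord) -> float:
    """Solid gain SG = (m − m0) / m0, in g solids / g initial dry mass.

    Bounded below by −1 (total loss of solids); negative values indicate
    leaching and are returned as-is.
    """
    return (rec.m - rec.m0) / rec.m0


def delta_e(c: ColorReading, c0: ColorReading) -> float:
    """Total colour change ΔE: Euclidean CIELab distance between two readings.

    Symmetric in its arguments and non-negative.  Compare against
    :data:`DELTA_E_VISIBLE` (or use :func:`is_visible_difference`) to judge
    whether the change is perceptible.
    """
    return math.sqrt((c.L - c0.L) ** 2 + (c.a - c0.a) ** 2 + (c.b - c0.b) ** 2)


def is_visible_difference(de: float) -> bool:
    """Whether a ΔE value exceeds the conventional visibility threshold (2)."""
    return de > DELTA_E_VISIBLE


def drip_loss(w: ThawWeights) -> float:
    """Drip loss in percent: 100 · (w_before − w_after) / w_before.

    Equals 100 only when the sample loses all its weight; may be negative if
    the sample gains weight (condensation), which is reported as-is.
    """
    # computed as 100·(1 − after/before) so the w_after = 0 bound is exact
    return 100.0 * (1.0 - w.w_after / w.w_before)
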
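"""Hyaluronan solution rheology and interstitial-fluid viscosity.

Free hyaluronan (HA) dominates the viscosity of interstitial fluid (IF).
For HA in the Newtonian regime the specific viscosity follows a virial-type
expansion in the coil-overlap parameter C[η]

    η_sp = C[η] + 0.42 (C[η])² + 7.77e-3 (C[η])^4.18,      0.1 ≤ C[η] ≤ 46

with the intrinsic viscosity linear in molecular weight,
[η] = 1.56e-3·MW + 125 (mL/g, MW in g/mol). IF shear rates during injection
stay below the ~3 s⁻¹ rheo-thinning onset, so a Newtonian treatment is used.

Type-2 diabetes raises tissue HA concentration 1.5-fold, which is the
mechanism by which disease raises injection backpressure downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from pydantic import BaseModel, Field

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "HAState",
    "IFViscosity",
    "DEFAULT_WATER_VISCOSITY",
    "DEFAULT_HA_MW",
    "HA_CONCENTRATIONS",
    "intrinsic_viscosity",
    "specific_viscosity",
    "relative_viscosity",
    "if_viscosity",
    "if_viscosity_for_state",
]

#: Water viscosity at ~35 °C tissue temperature, mPa·s. Configurable: the
#: relative-viscosity model is referenced "to water" without a fixed
#: temperature.
DEFAULT_WATER_VISCOSITY = 0.719

#: Upper human HA molecular weight (g/mol); used for all tissue IF lookups.
DEFAULT_HA_MW = 3.30e6

#: Validity range of the specific-viscosity fit in C[η].
_CETA_VALID = (0.1, 46.0)


class HAState(BaseModel):
    """Hyaluronan solution state. concentration g/mL, molecular_weight g/mol."""

    model_config = {"extra": "forbid"}

    concentration: float = Field(ge=0)
    molecular_weight: float = Field(DEFAULT_HA_MW, gt=0)
    water_viscosity: float = Field(DEFAULT_WATER_VISCOSITY, gt=0)

    @classmethod
    def from_ug_per_ml(cls, c_ug_ml: float, **kw) -> "HAState":
        return cls(concentration=c_ug_ml * 1e-6, **kw)


@dataclass(frozen=True)
class IFViscosity:
    relative: float  # η/η_water, dimensionless, >= 1
    absolute: float  # mPa·s

    def __post_init__(self):
        if self.relative < 1.0:
            raise InvalidInputError("relative viscosity must be >= 1")


def intrinsic_viscosity(mw: float) -> float:
    """Intrinsic viscosity [η] of HA in mL/g from molecular weight (g/mol)."""
    if mw <= 0:
        raise InvalidInputError("molecular weight must be positive")
    return 1.56e-3 * mw + 125.0


def specific_viscosity(c: float, intrinsic: float) -> float:
    """Specific viscosity η_sp = η/η0 − 1 of an HA solution.

    ``c`` in g/mL, ``intrinsic`` in mL/g. Warns outside the fitted
    C[η] ∈ [0.1, 46] range (except at C=0, which trivially gives 0).
    """
    if c < 0:
        raise InvalidInputError("concentration must be >= 0")
    x = c * intrinsic
    if c > 0 and not _CETA_VALID[0] <= x <= _CETA_VALID[1]:
        warnings.warn(
            f"C[eta]={x:.3g} outside fitted range {_CETA_VALID}", stacklevel=2
        )
    return x + 0.42 * x**2 + 7.77e-3 * x**4.18


def relative_viscosity(c: float, mw: float = DEFAULT_HA_MW) -> float:
    """Relative-to-water viscosity of an HA solution (c in g/mL)."""
    return 1.0 + specific_viscosity(c, intrinsic_viscosity(mw))


def if_viscosity(state: HAState) -> IFViscosity:
    rel = relative_viscosity(state.concentration, state.molecular_weight)
    return IFViscosity(relative=rel, absolute=rel * state.water_viscosity)


#: HA concentrations (μg/mL) by (disease, tissue, level). The diabetic adipose
#: values are the healthy ones ×1.5; diabetic lymph spans ×1 (low) to ×1.5
#: (high) of healthy lymph. Healthy adipose "mid" is the 100 μg/mL average.
HA_CONCENTRATIONS: dict[tuple[str, str], dict[str, float]] = {
    ("healthy", "lymph"): {"low": 0.2, "mid": 8.9, "high": 18.0},
    ("healthy", "adipose_if"): {"low": 70.0, "mid": 100.0, "high": 130.0},
    ("T2D", "lymph"): {"low": 0.2, "mid": 8.9 * 1.25, "high": 18.0 * 1.5},
    ("T2D", "adipose_if"): {"low": 105.0, "mid": 150.0, "high": 195.0},
}


def if_viscosity_for_state(
    disease: str,
    tissue: str,
    level: str,
    *,
    mw: float = DEFAULT_HA_MW,
    water_viscosity: float = DEFAULT_WATER_VISCOSITY,
) -> IFViscosity:
    """Look up the IF viscosity for a (disease, tissue, level) shorthand.

    ``disease`` in {healthy, T2D}, ``tissue`` in {lymph, adipose_if},
    ``level`` in {low, mid, high}.
    """
    try:
        c_ug_ml = HA_CONCENTRATIONS[(disease, tissue)][level]
    except KeyError as exc:
        raise ConfigurationError(
            f"unknown IF-viscosity category ({disease!r}, {tissue!r}, {level!r})"
        ) from exc
    state = HAState.from_ug_per_ml(
        c_ug_ml, molecular_weight=mw, water_viscosity=water_viscosity
    )
    return if_viscosity(state)
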
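"""Hyaluronidase (rHuPH20) degradation of hyaluronan.

Co-formulated recombinant human hyaluronidase PH20 cleaves tissue
hyaluronan (HA) into ~20 kDa fragments, collapsing the HA molecular weight
and with it the tissue's resistance to injected fluid. Degradation follows
Michaelis-Menten kinetics,

    v(t) = V_max · [HA](t) / ([HA](t) + K_m)        (nM/s)

with the substrate/K_m ratio formed on mass concentrations (mg/mL) as
reported — any mass↔molar conversion factor cancels inside the ratio. The
rate v depletes the molar pool of intact chains and produces an equal molar
pool of fragments, so the apparent molecular weight

    MW(t) = ([HA](t)·MW_0 + [P](t)·MW_f) / [HA]_0       (molar pools)

falls from MW_0 to MW_f at completion. The backpressure proportionality
factor scales linearly with MW(t) down to a floor at MW_end = 1e6 g/mol,
below which further degradation no longer reduces the pressure.

Defaults: V_max = 1.7 nM/s (×2 for rHuPH20-containing formulations at the
25,000 U/mL anchor), K_m = 0.9 mg/mL, k_cat = 41 s⁻¹, MW_0 = 3.3e6 g/mol,
[HA]_0 = 100 μg/mL (healthy human IF average).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .errors import InvalidInputError

__all__ = [
    "EnzymeKinetics",
    "DegradationSeries",
    "degradation_rate",
    "integrate_degradation",
    "time_dependent_pressure_factor",
]


class EnzymeKinetics(BaseModel):
    """Kinetic constants of rHuPH20 action on tissue HA."""

    model_config = {"extra": "forbid"}

    v_max: float = Field(1.7, ge=0)  # nM/s, measured
    vmax_multiplier: float = Field(2.0, gt=0)  # sensitivity factor (×1..×10)
    k_m: float = Field(0.9, gt=0)  # mg/mL
    k_cat: float = Field(41.0, gt=0)  # s⁻¹
    mw_0: float = Field(3.3e6, gt=0)  # g/mol, intact tissue HA
    mw_f: float = Field(2.0e4, gt=0)  # g/mol, cleavage fragment
    mw_end: float = Field(1.0e6, gt=0)  # g/mol, pressure-effect floor
    ha_0: float = Field(0.1, gt=0)  # mg/mL initial HA concentration

    @model_validator(mode="after")
    def _check(self):
        if self.mw_f >= self.mw_0:
            raise InvalidInputError("fragment MW must be below intact MW")
        return self

    @property
    def v_max_effective(self) -> float:
        return self.v_max * self.vmax_multiplier

    @property
    def ha_0_nM(self) -> float:
        """Initial molar chain concentration, nM ([mg/mL]=[g/L] over MW_0)."""
        return self.ha_0 / self.mw_0 * 1e9


@dataclass(frozen=True)
class DegradationSeries:
    """Euler-integrated degradation time course."""

    t: np.ndarray  # s
    ha_mg_ml: np.ndarray  # intact HA mass concentration
    ha_nM: np.ndarray  # intact chains, molar
    p_nM: np.ndarray  # fragments, molar
    mw: np.ndarray  # apparent molecular weight, g/mol

    def mw_at(self, t) -> np.ndarray:
        return np.interp(t, self.t, self.mw)


def degradation_rate(ha_mg_ml: float, kin: EnzymeKinetics) -> float:
    """Michaelis-Menten degradation rate in nM/s at HA concentration mg/mL."""
    if ha_mg_ml < 0:
        raise InvalidInputError("HA concentration must be >= 0")
    return kin.v_max_effective * ha_mg_ml / (ha_mg_ml + kin.k_m)


def integrate_degradation(
    kin: EnzymeKinetics, horizon: float, dt: float
) -> DegradationSeries:
    """Explicit-Euler time course of ([HA], [P], MW_apparent) over ``horizon`` s.

    Molar chain bookkeeping: each catalytic event converts one intact chain
    into (counted as) one fragment, so consumed HA equals produced fragments
    in molar-equivalents at every step. [HA] is floored at zero.
    """
    if dt <= 0:
        raise InvalidInputError("dt must be > 0")
    n = int(np.ceil(horizon / dt)) + 1
    t = np.arange(n) * dt
    ha = np.empty(n)
    ha[0] = kin.ha_0_nM
    clamped = False
    for i in range(1, n):
        ha_mass = ha[i - 1] * 1e-9 * kin.mw_0  # back to mg/mL
        v = kin.v_max_effective * ha_mass / (ha_mass + kin.k_m)
        nxt = ha[i - 1] - v * dt
        if nxt < 0.0:
            nxt, clamped = 0.0, True
        ha[i] = nxt
    if clamped:
        warnings.warn("HA pool exhausted before horizon; clamped at zero")
    p = kin.ha_0_nM - ha  # exact molar conservation
    mw = (ha * kin.mw_0 + p * kin.mw_f) / kin.ha_0_nM
    return DegradationSeries(t=t, ha_mg_ml=ha * 1e-9 * kin.mw_0, ha_nM=ha, p_nM=p, mw=mw)


def time_dependent_pressure_factor(
    f_base: float, mw_t: float, kin: EnzymeKinetics
) -> float:
    """Pressure factor under enzyme action: F·MW(t)/MW_0, frozen once the
    apparent MW reaches MW_end (the linear scaling is only valid above it)."""
    mw_eff = max(mw_t, kin.mw_end)
    return f_base * mw_eff / kin.mw_0
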
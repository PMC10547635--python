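"""Scenario configuration: schema, YAML/JSON I/O and shipped fixtures.

A scenario bundles everything one simulated injection needs: the subject,
the tissue state (average RCS ε, hydraulic conductivity k, interstitial
fluid viscosity, skin model), the injection protocol, optional enzyme
kinetics, a life-event timeline and the numerical settings. Units are fixed
per key (documented on the models: volumes μL, rates μL/min, lengths mm,
viscosities mPa·s, conductivity m², times s).

Config files are YAML (plain JSON is valid YAML and loads unchanged).
Unknown keys are rejected, so typos surface as schema errors.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Callable, Literal, Optional

import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from .depot import DEFAULT_EPSILON, RCSProfileParams
from .conductivity import DEFAULT_TISSUE_K
from .enzyme import EnzymeKinetics
from .errors import ConfigurationError
from .physiology import LifeEventTimeline, SubjectCovariates
from .pressure import InjectionProtocol, Numerics, SkinModel
from .rheology import (
    DEFAULT_HA_MW,
    DEFAULT_WATER_VISCOSITY,
    if_viscosity_for_state,
    relative_viscosity,
)

__all__ = [
    "TissueConfig",
    "DepotConfig",
    "Scenario",
    "load_scenario",
    "dump_scenario",
    "fixture",
    "fixture_names",
    "leakage_fixture_grid",
]


class TissueConfig(BaseModel):
    """Tissue-side parameters of a scenario.

    The IF viscosity can be given three ways, in order of precedence:
    an absolute value (``if_viscosity_mpas``), an HA state
    (``ha_concentration_ug_ml`` + ``ha_mw`` + ``water_viscosity``), or the
    (disease, tissue, level) shorthand resolved through the rheology table.
    """

    model_config = {"extra": "forbid"}

    epsilon: float = Field(DEFAULT_EPSILON, gt=0, le=1)
    k: float = Field(DEFAULT_TISSUE_K, gt=0)  # m²
    if_viscosity_mpas: Optional[float] = Field(None, gt=0)
    ha_concentration_ug_ml: Optional[float] = Field(None, ge=0)
    ha_mw: float = Field(DEFAULT_HA_MW, gt=0)
    water_viscosity: float = Field(DEFAULT_WATER_VISCOSITY, gt=0)
    if_disease: Literal["healthy", "T2D"] = "healthy"
    if_tissue: Literal["lymph", "adipose_if"] = "adipose_if"
    if_level: Literal["low", "mid", "high"] = "mid"
    skin: SkinModel = Field(default_factory=SkinModel)

    def resolve_if_viscosity(self) -> float:
        """Absolute IF viscosity in mPa·s after applying the precedence."""
        if self.if_viscosity_mpas is not None:
            return self.if_viscosity_mpas
        if self.ha_concentration_ug_ml is not None:
            rel = relative_viscosity(self.ha_concentration_ug_ml * 1e-6, self.ha_mw)
            return rel * self.water_viscosity
        return if_viscosity_for_state(
            self.if_disease,
            self.if_tissue,
            self.if_level,
            mw=self.ha_mw,
            water_viscosity=self.water_viscosity,
        ).absolute


class DepotConfig(BaseModel):
    """Voxel-field settings; ``grid_n = 0`` skips field construction."""

    model_config = {"extra": "forbid"}

    grid_n: int = Field(0, ge=0)
    rcs_max: float = Field(0.2, gt=0, le=1)
    alpha: float = 2.0
    beta: float = 2.2
    dose: float = Field(1.0, gt=0)

    def profile_params(self) -> RCSProfileParams:
        return RCSProfileParams(rcs_max=self.rcs_max, alpha=self.alpha, beta=self.beta)


class Scenario(BaseModel):
    model_config = {"extra": "forbid"}

    name: str = "scenario"
    subject: SubjectCovariates = Field(default_factory=SubjectCovariates)
    tissue: TissueConfig = Field(default_factory=TissueConfig)
    protocol: InjectionProtocol
    enzyme: Optional[EnzymeKinetics] = None
    timeline: LifeEventTimeline = Field(default_factory=LifeEventTimeline)
    numerics: Numerics = Field(default_factory=Numerics)
    depot: DepotConfig = Field(default_factory=DepotConfig)
    f_calibration: float = Field(1.0, gt=0)
    observed_leakage_ul: Optional[float] = Field(None, ge=0)

    @model_validator(mode="after")
    def _cross_checks(self):
        if self.protocol.t_removal is not None and self.numerics.horizon is not None:
            if self.numerics.horizon < self.protocol.t_removal + self.protocol.leak_window:
                raise ConfigurationError(
                    "horizon ends before the needle-removal leak window"
                )
        return self


def load_scenario(path: str | Path) -> Scenario:
    """Load and validate a scenario config (YAML or JSON)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a mapping, got {type(data).__name__}")
    try:
        return Scenario(**data)
    except ValidationError as exc:
        raise ConfigurationError(f"{path}: invalid scenario:\n{exc}") from exc


def dump_scenario(scenario: Scenario, path: str | Path) -> None:
    """Write a scenario back to YAML (load→dump→load is idempotent)."""
    data = scenario.model_dump(exclude_none=True)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# Shipped fixtures: in-paper scenarios
# ---------------------------------------------------------------------------

_TABLE3_PROTOCOL = dict(
    v_inj=500.0,
    q_inj=6000.0,
    needle_length=6.0,
    needle_ext_radius=0.311,
    needle_int_diameter=0.318,
    injection_angle=90.0,
    syringe_diameter=12.07,
    formulation_viscosity=1.0,
    formulation_density=1000.0,
)

#: Pig / healthy-human-average IF viscosity used in the validation studies.
PIG_IF_VISCOSITY = 1.66
#: T2D IF viscosity used in the human leakage validation.
T2D_IF_VISCOSITY = 2.08


def _table3(name: str, disease: str, level: str) -> Scenario:
    proto = dict(_TABLE3_PROTOCOL)
    proto["t_removal"] = 15.0  # 5 s injection + 10 s hold
    return Scenario(
        name=name,
        subject=SubjectCovariates(disease="T2D" if disease == "T2D" else "healthy"),
        tissue=TissueConfig(if_disease=disease, if_tissue="adipose_if", if_level=level),
        protocol=InjectionProtocol(**proto),
    )


def _doughty(name: str, rate_ml_h: float) -> Scenario:
    q = rate_ml_h * 1000.0 / 60.0  # μL/min
    t_end = 2000.0 / (q / 60.0)
    return Scenario(
        name=name,
        tissue=TissueConfig(if_viscosity_mpas=PIG_IF_VISCOSITY),
        protocol=InjectionProtocol(
            **dict(_TABLE3_PROTOCOL, v_inj=2000.0, q_inj=q, t_removal=t_end + 10.0)
        ),
        numerics=Numerics(dt_injection=0.01 if t_end > 60 else 0.001),
    )


def _kang(name: str, with_enzyme: bool) -> Scenario:
    q = 2000.0  # μL/min (120 mL/h)
    t_end = 10000.0 / (q / 60.0)  # 300 s
    return Scenario(
        name=name,
        tissue=TissueConfig(if_viscosity_mpas=PIG_IF_VISCOSITY),
        protocol=InjectionProtocol(
            **dict(
                _TABLE3_PROTOCOL,
                v_inj=10000.0,
                q_inj=q,
                formulation_viscosity=7.2,
                t_removal=t_end + 10.0,
            )
        ),
        enzyme=EnzymeKinetics(vmax_multiplier=2.0) if with_enzyme else None,
        numerics=Numerics(dt_injection=0.01, horizon=t_end + 30.0),
    )


_FIXTURES: dict[str, Callable[[], Scenario]] = {
    "table3_healthy": lambda: _table3("table3_healthy", "healthy", "low"),
    "table3_t2d": lambda: _table3("table3_t2d", "T2D", "high"),
    "doughty_2mL_20mLh": lambda: _doughty("doughty_2mL_20mLh", 20.0),
    "doughty_2mL_120mLh": lambda: _doughty("doughty_2mL_120mLh", 120.0),
    "doughty_2mL_360mLh": lambda: _doughty("doughty_2mL_360mLh", 360.0),
    "kang_10mL_plain": lambda: _kang("kang_10mL_plain", False),
    "kang_10mL_ph20": lambda: _kang("kang_10mL_ph20", True),
}


def fixture(name: str) -> Scenario:
    """Return a fresh copy of a named in-built scenario."""
    try:
        return copy.deepcopy(_FIXTURES[name]())
    except KeyError as exc:
        raise ConfigurationError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(_FIXTURES))}"
        ) from exc


def fixture_names() -> list[str]:
    return sorted(_FIXTURES)


#: (gauge label, external radius mm, length mm) of common pen needles.
_PEN_NEEDLES = [
    ("32G_4mm", 0.1175, 4.0),
    ("31G_6mm", 0.1275, 6.0),
    ("29G_8mm", 0.1675, 8.0),
]


def leakage_fixture_grid(
    volumes_ul: tuple[float, ...] = (100.0, 300.0, 800.0),
    rates_ul_min: tuple[float, ...] = (600.0, 1800.0),
    hold_s: float = 5.0,
) -> list[Scenario]:
    """Synthetic grid of human-pen injection scenarios for the leakage
    harness (needle gauges/lengths × volumes × rates). Observed leakages are
    placeholders (None): attach measurements before computing an AFE."""
    out = []
    for label, r_ext, length in _PEN_NEEDLES:
        for v in volumes_ul:
            for q in rates_ul_min:
                t_end = v / (q / 60.0)
                out.append(
                    Scenario(
                        name=f"leak_{label}_{v:.0f}uL_{q:.0f}uLmin",
                        subject=SubjectCovariates(disease="T2D"),
                        tissue=TissueConfig(if_viscosity_mpas=T2D_IF_VISCOSITY),
                        protocol=InjectionProtocol(
                            v_inj=v,
                            q_inj=q,
                            needle_length=length,
                            needle_ext_radius=r_ext,
                            needle_int_diameter=max(2 * r_ext - 0.1, 0.1),
                            syringe_diameter=9.7,
                            t_removal=t_end + hold_s,
                        ),
                    )
                )
    return out
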
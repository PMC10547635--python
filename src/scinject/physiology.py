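"""Adipose-tissue physiology: blood and interstitial-fluid flows.

The subcutaneous depot sits in adipose tissue whose capillary bed receives a
partial cardiac output ``PCO`` (percent of CO). Plasma is ultrafiltrated
across the capillary walls into the interstitium; on average about 20 L of
interstitial fluid (IF) are produced per 8400 L of blood pumped per day, so
the IF-to-blood filtration ratio ``R_IF/B`` is ~0.0024. Of the IF produced,
15% drains to lymph and 85% is reabsorbed by the venous capillaries.

Public functions accept and return the conventional units of the physiology
literature (mL/min, μL/h/g); conversions are handled internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "SubjectCovariates",
    "AdiposeFlows",
    "LifeEvent",
    "LifeEventTimeline",
    "EventParameters",
    "fractional_blood_volume",
    "perfusion_rate",
    "if_flow",
    "partition_if_flow",
    "adipose_flows",
    "age_blood_flow_factor",
    "blood_flow_multiplier",
    "flows_table",
]

#: IF produced (L/day) over blood pumped (L/day) in a resting healthy adult.
DEFAULT_IF_TO_BLOOD_RATIO = 20.0 / 8400.0

#: Fraction of adipose blood flow remaining in T2D relative to healthy (35 °C).
T2D_BASELINE_FLOW_FACTOR = 0.624


class SubjectCovariates(BaseModel):
    """Per-subject physiological constants.

    Units: masses kg, cardiac_output mL/min, blood_volume L,
    adipose_density g/mL, percentages in [0, 100], fractions in [0, 1].
    """

    model_config = {"extra": "forbid"}

    sex: Literal["male", "female"] = "male"
    body_mass: float = Field(73.0, gt=0)
    age: float = Field(35.0, ge=0)
    disease: Literal["healthy", "T2D", "obese"] = "healthy"
    cardiac_output: float = Field(6700.0, gt=0)
    blood_volume: float = Field(5.21, gt=0)
    hematocrit: float = Field(0.47, ge=0, le=1)
    adipose_mass: float = Field(12.5, gt=0)
    adipose_density: float = Field(0.92, gt=0)
    pco_adipose: float = Field(5.0, ge=0, le=100)
    pblood_cap: float = Field(6.0, ge=0, le=100)
    if_to_blood_ratio: float = Field(DEFAULT_IF_TO_BLOOD_RATIO, ge=0)
    lymph_fraction_of_if: float = Field(0.15, ge=0, le=1)

    @classmethod
    def default_male(cls, **overrides) -> "SubjectCovariates":
        return cls(**overrides)

    @classmethod
    def default_female(cls, **overrides) -> "SubjectCovariates":
        base = dict(
            sex="female",
            body_mass=60.0,
            cardiac_output=5800.0,
            blood_volume=4.29,
            hematocrit=0.42,
            adipose_mass=17.5,
            pco_adipose=8.5,
        )
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class AdiposeFlows:
    """Resting adipose flow summary for one subject."""

    theta_blood: float  # fractional capillary blood volume, dimensionless
    perfusion_total: float  # mL/min
    perfusion_per_100g: float  # mL/min/100 g tissue
    qif: float  # μL/h/g tissue
    q_lymph: float  # μL/h/g tissue
    qif_venous: float  # μL/h/g tissue


def fractional_blood_volume(cov: SubjectCovariates) -> float:
    """Fraction of adipose tissue volume occupied by capillary blood.

    θ_blood = (V_blood · D_adipose / M_adipose) · (Pblood_cap/100) · (PCO/100),
    with V_blood in mL and M_adipose in g so the first factor is the
    blood-to-tissue volume ratio. Typical adult male defaults give ~0.00115.
    """
    if cov.adipose_mass <= 0:
        raise InvalidInputError("adipose_mass must be positive")
    v_blood_ml = cov.blood_volume * 1000.0
    m_adipose_g = cov.adipose_mass * 1000.0
    return (
        v_blood_ml
        * cov.adipose_density
        / m_adipose_g
        * (cov.pblood_cap / 100.0)
        * (cov.pco_adipose / 100.0)
    )


def perfusion_rate(cov: SubjectCovariates) -> tuple[float, float]:
    """Adipose blood perfusion: (total mL/min, per-100 g mL/min/100 g)."""
    total = cov.cardiac_output * cov.pco_adipose / 100.0
    per_100g = total / (cov.adipose_mass * 10.0)  # kg -> hundreds of grams
    return total, per_100g


def if_flow(cov: SubjectCovariates) -> float:
    """Interstitial-fluid production rate in μL/h/g of adipose tissue.

    QIF = R_IF/B × PR_adipose / M_adipose. With PR in mL/min and M in kg,
    the quotient is μL/min/g; the factor 60 converts to μL/h/g.
    """
    total, _ = perfusion_rate(cov)
    return cov.if_to_blood_ratio * total / cov.adipose_mass * 60.0


def partition_if_flow(qif: float, lymph_fraction: float) -> tuple[float, float]:
    """Split IF production into (lymph, venous-return) flows, sum-conserving."""
    if not 0.0 <= lymph_fraction <= 1.0:
        raise InvalidInputError("lymph_fraction must be in [0, 1]")
    q_venous = qif - lymph_fraction * qif
    q_lymph = qif - q_venous  # re-derive so the pair sums to qif exactly
    return q_lymph, q_venous


def adipose_flows(cov: SubjectCovariates) -> AdiposeFlows:
    total, per100 = perfusion_rate(cov)
    qif = if_flow(cov)
    q_lymph, q_ven = partition_if_flow(qif, cov.lymph_fraction_of_if)
    return AdiposeFlows(
        theta_blood=fractional_blood_volume(cov),
        perfusion_total=total,
        perfusion_per_100g=per100,
        qif=qif,
        q_lymph=q_lymph,
        qif_venous=q_ven,
    )


def age_blood_flow_factor(age: float) -> float:
    """Limb blood-flow reduction with age: −26% from 28 to 63 y, linear,
    clamped outside that range."""
    frac = min(max((age - 28.0) / (63.0 - 28.0), 0.0), 1.0)
    return 1.0 - 0.26 * frac


# ---------------------------------------------------------------------------
# Life events: time-dependent blood-flow multipliers
# ---------------------------------------------------------------------------

EVENT_KINDS = (
    "exercise",
    "posture",
    "sleep",
    "stress",
    "meal",
    "temperature",
    "glp1",
    "needle_insertion",
)


class LifeEvent(BaseModel):
    """One external factor active on [start, end) minutes.

    ``magnitude`` is kind-specific: exercise intensity in [0, 1] (fraction of
    50% maximal capacity), temperature excess in °C; ignored for the other
    kinds (their factors are fixed or configured in :class:`EventParameters`).
    """

    model_config = {"extra": "forbid"}

    kind: str
    start: float = Field(ge=0)
    end: float
    magnitude: float = 1.0

    @model_validator(mode="after")
    def _check(self):
        if self.kind not in EVENT_KINDS:
            raise ConfigurationError(f"unknown life-event kind {self.kind!r}")
        if not self.start < self.end:
            raise ConfigurationError("event start must precede end")
        return self


class LifeEventTimeline(BaseModel):
    model_config = {"extra": "forbid"}

    events: list[LifeEvent] = Field(default_factory=list)


class EventParameters(BaseModel):
    """Tunable per-kind multipliers (defaults from resting-human literature)."""

    model_config = {"extra": "forbid"}

    exercise_max_healthy: float = 3.5  # peak fold-increase, healthy (range 3-4)
    exercise_max_t2d: float = 1.2
    posture_factor: float = 1.2  # standing/sitting vs supine
    stress_factor_thigh: float = 1.89
    stress_factor_abdomen: float = 1.63
    meal_peak: float = 2.0  # doubles abdominal flow, decays over meal window
    sleep_factor: float = Field(1.8, ge=1.0)  # reported range 1.8-3.0
    temperature_slope: float = 0.0  # per °C above reference; off by default
    glp1_factor: float = 1.76
    needle_peak: float = 7.0  # local flow at insertion
    needle_half_life_min: float = 23.0


def _event_factor(
    ev: LifeEvent, t: float, disease: str, site: str, params: EventParameters
) -> float:
    k = ev.kind
    if k == "exercise":
        peak = (
            params.exercise_max_t2d if disease == "T2D" else params.exercise_max_healthy
        )
        intensity = min(max(ev.magnitude, 0.0), 1.0)
        return 1.0 + intensity * (peak - 1.0)
    if k == "posture":
        return params.posture_factor
    if k == "sleep":
        return params.sleep_factor
    if k == "stress":
        return params.stress_factor_thigh if site == "thigh" else params.stress_factor_abdomen
    if k == "meal":
        if disease == "obese":
            return 1.0  # postprandial response suppressed in obesity
        frac = (t - ev.start) / (ev.end - ev.start)
        return params.meal_peak - (params.meal_peak - 1.0) * frac
    if k == "temperature":
        return max(1.0 + params.temperature_slope * ev.magnitude, 0.0)
    if k == "glp1":
        return params.glp1_factor
    if k == "needle_insertion":
        # transient local hyperaemia; decays exponentially from insertion
        decay = 0.5 ** ((t - ev.start) / params.needle_half_life_min)
        return 1.0 + (params.needle_peak - 1.0) * decay
    raise ConfigurationError(f"unknown life-event kind {k!r}")


def blood_flow_multiplier(
    timeline: Optional[LifeEventTimeline],
    disease: str = "healthy",
    t: float = 0.0,
    *,
    site: str = "abdomen",
    params: Optional[EventParameters] = None,
    channel: Literal["total", "systemic", "local"] = "total",
) -> float:
    """Product of active blood-flow multipliers at time ``t`` (minutes).

    Simultaneous events compose multiplicatively. The needle-insertion
    hyperaemia is a *local* (injection-site) effect and is kept on its own
    channel; ``channel="systemic"`` excludes it, ``channel="local"`` returns
    it alone, and the default ``"total"`` is the product of both. A T2D
    baseline scaling of 0.624 applies to the systemic channel.
    """
    if t < 0:
        raise InvalidInputError("t must be >= 0")
    params = params or EventParameters()
    systemic = T2D_BASELINE_FLOW_FACTOR if disease == "T2D" else 1.0
    local = 1.0
    events: Sequence[LifeEvent] = timeline.events if timeline is not None else ()
    for ev in events:
        if ev.kind == "needle_insertion":
            if t >= ev.start:
                local *= _event_factor(ev, t, disease, site, params)
        elif ev.start <= t < ev.end:
            systemic *= _event_factor(ev, t, disease, site, params)
    if channel == "systemic":
        return systemic
    if channel == "local":
        return local
    return systemic * local


def flows_table(cov: SubjectCovariates) -> pd.DataFrame:
    """Tabular export of the resting flows: columns (parameter, value, units)."""
    f = adipose_flows(cov)
    rows = [
        ("theta_blood", f.theta_blood, ""),
        ("perfusion_total", f.perfusion_total, "mL/min"),
        ("perfusion_per_100g", f.perfusion_per_100g, "mL/min/100 g"),
        ("qif", f.qif, "uL/h/g"),
        ("q_lymph", f.q_lymph, "uL/h/g"),
        ("qif_venous", f.qif_venous, "uL/h/g"),
    ]
    return pd.DataFrame(rows, columns=["parameter", "value", "units"])
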
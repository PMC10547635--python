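"""Five-phase tissue backpressure, needle-removal backflow, residual pressure.

The backpressure recorded during and after a subcutaneous injection is
modelled in five phases:

1. spherical depot growth — Darcy-type resistance builds with the depot,
2. horizontal elongation — vertical growth halts and the pressure plateaus,
3. post-injection relaxation with the needle in place — the stressed fluid
   at the depot edge (2.5% of the injected volume) drains into the tissue
   and the pressure decays,
4. premature needle removal — the puncture hole leaks formulation for a
   25 ms window (Hagen-Poiseuille through the needle track),
5. residual bleb pressure — skin deformation times skin stiffness, slowly
   decaying as the depot keeps draining.

The phase-1/2 pressure is a modified Darcy law

    P(t) = F · Q_inj · η_app · 4π WFV(t)² / k

where k is the tissue hydraulic conductivity, η_app = 0.1 η_form + 0.9 η_IF
is the effective viscosity at the depot edge, and F is an empirical
proportionality factor F = 2 ln(Q_inj[μL/min]/V_inj[mL]²) + 5 evaluated in
those mixed units exactly as fitted (a configurable calibration constant,
default 1, carries the implicit m⁻³ scaling). Validity: low-viscosity
formulations up to ~12 mL/min; above ~2 mL/min for η > 10 mPa·s the model
is known to overpredict and a warning is emitted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .conductivity import DEFAULT_TISSUE_K
from .depot import DEFAULT_EPSILON, elongation, waterfronts
from .enzyme import EnzymeKinetics, integrate_degradation, time_dependent_pressure_factor
from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "InjectionProtocol",
    "SkinModel",
    "Numerics",
    "BackflowResult",
    "PressureTrace",
    "gliding_force",
    "pressure_factor",
    "apparent_viscosity",
    "phase12_pressure",
    "stressed_volume",
    "relaxation_flow",
    "phase3_pressure",
    "residual_pressure",
    "dead_volume",
    "simulate_pressure",
    "needle_removal",
]

#: Fraction of the depot volume under stress at its edge.
STRESS_FRACTION = 0.025

#: Exponent of the Thomsen-style ellipsoid surface-area approximation.
_SURF_P = 1.6


class InjectionProtocol(BaseModel):
    """Device, formulation and timing parameters of one injection.

    Units: volumes μL, rates μL/min, lengths mm, viscosity mPa·s, density
    kg/m³, times s. ``t_removal`` is measured from the start of injection;
    ``None`` leaves the needle in place for the whole simulation. The
    injection angle is retained for provenance but does not enter the
    backflow model (the needle punctures to its full length regardless).
    """

    model_config = {"extra": "forbid"}

    v_inj: float = Field(gt=0)
    q_inj: float = Field(gt=0)
    needle_length: float = Field(6.0, gt=0)
    needle_ext_radius: float = Field(0.311, gt=0)
    needle_int_diameter: float = Field(0.318, gt=0)
    injection_angle: float = Field(90.0, gt=0, le=90)
    syringe_diameter: float = Field(12.07, gt=0)
    formulation_viscosity: float = Field(1.0, gt=0)
    formulation_density: float = Field(1000.0, gt=0)
    t_removal: Optional[float] = Field(None, ge=0)
    leak_window: float = Field(0.025, gt=0)
    v_device_residual: float = Field(0.0, ge=0)

    @property
    def t_end(self) -> float:
        """End of injection in seconds."""
        return self.v_inj / (self.q_inj / 60.0)


class SkinModel(BaseModel):
    """Skin bleb: spherical cap of the depot volume under a circular patch.

    The cap height h under a patch of radius a solves
    V = π h (3a² + h²) / 6; the deformation angle is δ = atan(h/a) and the
    bleb pressure is δ·St_skin. The default stiffness is calibrated so a
    2 mL abdominal bleb exerts ≈3 kPa.
    """

    model_config = {"extra": "forbid"}

    stiffness: float = Field(19.2, ge=0)  # kPa/rad
    patch_radius: float = Field(20.0, gt=0)  # mm

    def deformation(self, bleb_volume_ul: float, footprint_radius_mm: float = 0.0) -> float:
        """Skin deformation angle δ (rad) for a bleb of given volume (μL).

        The cap base is the wider of the configured patch and the depot's
        horizontal waterfront footprint (skin is raised over at least the
        depot's extent, which keeps large-volume blebs shallow).
        """
        if bleb_volume_ul <= 0:
            return 0.0
        a = max(self.patch_radius, footprint_radius_mm)
        q = 6.0 * bleb_volume_ul / math.pi  # volume in mm³ == μL
        disc = math.sqrt(q * q / 4.0 + a**6)  # (p/3)³ with p = 3a²
        h = np.cbrt(q / 2.0 + disc) + np.cbrt(q / 2.0 - disc)
        return math.atan(h / a)

    def pressure(self, bleb_volume_ul: float, footprint_radius_mm: float = 0.0) -> float:
        """Bleb pressure in kPa."""
        return self.deformation(bleb_volume_ul, footprint_radius_mm) * self.stiffness


class Numerics(BaseModel):
    """Time stepping: explicit Euler on piecewise-uniform grids (s)."""

    model_config = {"extra": "forbid"}

    dt_injection: float = Field(1e-3, gt=0)
    dt_post: float = Field(1e-2, gt=0)
    dt_leak: float = Field(1e-4, gt=0)
    horizon: Optional[float] = Field(None, gt=0)


@dataclass(frozen=True)
class BackflowResult:
    v_dead: float  # μL, needle-track volume expelled on hole collapse
    v_loss: float  # μL, total loss through the puncture hole (≥ v_dead)
    percent_dose_loss: float  # % of intended dose, device residual included


@dataclass
class PressureTrace:
    """Backpressure time series with volume bookkeeping (arrays aligned on t)."""

    t: np.ndarray  # s
    p_tissue: np.ndarray  # kPa
    p_bleb: np.ndarray  # kPa
    p_total: np.ndarray  # kPa
    phase: np.ndarray  # int 1..5
    v_out: np.ndarray  # μL, cumulative relaxation outflow into tissue
    v_leak: np.ndarray  # μL, cumulative puncture-hole leak
    v_delivered: np.ndarray  # μL
    backflow: Optional[BackflowResult] = None

    @property
    def peak_pressure(self) -> float:
        return float(self.p_total.max())

    @property
    def v_in_tissue(self) -> np.ndarray:
        return self.v_delivered - self.v_out - self.v_leak

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "p_tissue_kPa": self.p_tissue,
                "p_bleb_kPa": self.p_bleb,
                "p_total_kPa": self.p_total,
                "phase": self.phase,
                "v_out_uL": self.v_out,
                "v_loss_uL": self.v_leak,
            }
        )


def gliding_force(protocol: InjectionProtocol) -> float:
    """Plunger gliding force F = 32 η L Q D_S² / d⁴ in newtons."""
    if protocol.needle_int_diameter <= 0:
        raise InvalidInputError("needle internal diameter must be > 0")
    eta = protocol.formulation_viscosity * 1e-3  # Pa·s
    length = protocol.needle_length * 1e-3  # m
    q = protocol.q_inj * 1e-9 / 60.0  # m³/s
    d_s = protocol.syringe_diameter * 1e-3
    d = protocol.needle_int_diameter * 1e-3
    return 32.0 * eta * length * q * d_s**2 / d**4


def pressure_factor(q_inj: float, v_inj_ml: float) -> float:
    """Empirical Darcy proportionality factor F = 2 ln(Q/V²) + 5, floored at 0.

    Evaluated in the fitted units: ``q_inj`` μL/min, ``v_inj_ml`` mL.
    """
    if q_inj <= 0 or v_inj_ml <= 0:
        raise InvalidInputError("q_inj and v_inj must be > 0")
    return max(2.0 * math.log(q_inj / v_inj_ml**2) + 5.0, 0.0)


def apparent_viscosity(eta_form: float, eta_if: float) -> float:
    """Effective viscosity at the depot edge: fixed 10:90 formulation:IF blend
    (the RCS at the resisting 'onion ring' is ~0.1). mPa·s in, mPa·s out."""
    if eta_form <= 0 or eta_if <= 0:
        raise InvalidInputError("viscosities must be > 0")
    return 0.1 * eta_form + 0.9 * eta_if


def _p12_pa(f: float, q_si: float, eta_app_pas: float, wfv_m: float, k: float) -> float:
    return f * q_si * eta_app_pas * 4.0 * math.pi * wfv_m**2 / k


def phase12_pressure(
    t: float,
    protocol: InjectionProtocol,
    eta_if: float,
    epsilon: float = DEFAULT_EPSILON,
    k: float = DEFAULT_TISSUE_K,
    f: Optional[float] = None,
    f_calibration: float = 1.0,
) -> float:
    """Tissue component of the backpressure during injection, kPa (bleb
    pressure not included). Plateaus as vertical depot growth halts."""
    if k <= 0:
        raise InvalidInputError("tissue conductivity must be > 0")
    if not 0.0 <= t <= protocol.t_end:
        raise InvalidInputError("t outside the injection window")
    v_ml = protocol.q_inj / 60.0 * t / 1000.0
    wfv_mm, _ = waterfronts(v_ml, epsilon, elongation(v_ml, protocol.q_inj))
    if f is None:
        f = pressure_factor(protocol.q_inj, protocol.v_inj / 1000.0)
    eta_app = apparent_viscosity(protocol.formulation_viscosity, eta_if) * 1e-3
    q_si = protocol.q_inj * 1e-9 / 60.0
    return _p12_pa(f * f_calibration, q_si, eta_app, wfv_mm * 1e-3, k) / 1000.0


def stressed_volume(v_injected_ul: float) -> float:
    """Stressed fluid volume at the depot edge, μL: 2.5% of the depot's total
    (apparent) volume times ε — algebraically 2.5% of the injected volume."""
    if v_injected_ul < 0:
        raise InvalidInputError("injected volume must be >= 0")
    return STRESS_FRACTION * v_injected_ul


def _ellipsoid_area_term(wfh_m: float, wfv_m: float) -> float:
    """((WFH^p + 2(WFH·WFV)^{p/2})/3)^{1/p} with p = 3.2 — the Thomsen-style
    mean that reduces to R² for a sphere."""
    return (
        (wfh_m**(2 * _SURF_P) + 2.0 * (wfh_m * wfv_m) ** _SURF_P) / 3.0
    ) ** (1.0 / _SURF_P)


def relaxation_flow(
    p_drive_kpa: float,
    wfv_mm: float,
    wfh_mm: float,
    eta_app: float,
    f: float,
    k: float = DEFAULT_TISSUE_K,
) -> float:
    """Fluid outflow from the depot surface into intact tissue, μL/s.

    Q = k (P_tissue + P_bleb) / (F η_app 4π A_eff) where A_eff is the
    ellipsoid surface term; active from injection start for as long as
    pressure is exerted. ``eta_app`` in mPa·s, waterfronts in mm.
    """
    if wfv_mm <= 0 or wfh_mm <= 0:
        return 0.0
    area = _ellipsoid_area_term(wfh_mm * 1e-3, wfv_mm * 1e-3)
    q_si = k * (p_drive_kpa * 1000.0) / (f * eta_app * 1e-3 * 4.0 * math.pi * area)
    return q_si * 1e9  # m³/s -> μL/s


def phase3_pressure(
    p12_end_kpa: float, drained_ul: float, v_stress_ul: float, p_bleb_kpa: float
) -> float:
    """Post-injection pressure: the end-of-injection tissue component scaled
    by the undrained fraction of the stressed volume, floored at the bleb
    pressure once the stressed volume has fully drained."""
    if v_stress_ul <= 0:
        return p_bleb_kpa
    frac = max(1.0 - drained_ul / v_stress_ul, 0.0)
    return p12_end_kpa * frac + p_bleb_kpa


def residual_pressure(bleb_volume_ul: float, skin: SkinModel) -> float:
    """Phase-5 residual pressure (kPa) of the collapsed-hole bleb."""
    return skin.pressure(bleb_volume_ul)


def dead_volume(protocol: InjectionProtocol) -> float:
    """Needle-track dead volume π L_N R_ext², μL."""
    return math.pi * protocol.needle_length * protocol.needle_ext_radius**2


def _segments(protocol: InjectionProtocol, num: Numerics):
    """Piecewise-uniform integration grid with phase-boundary alignment."""
    t_end = protocol.t_end
    t_rem = protocol.t_removal
    if t_rem is not None and t_rem < 0:
        raise InvalidInputError("t_removal must be >= 0")
    horizon = num.horizon
    if horizon is None:
        tail = (t_rem + protocol.leak_window) if t_rem is not None else t_end
        horizon = tail + 30.0
    bounds = [0.0]
    dts = []
    t_inj_stop = t_end if t_rem is None else min(t_end, t_rem)
    if t_inj_stop > 0:
        bounds.append(t_inj_stop)
        dts.append(num.dt_injection)
    if t_rem is not None:
        if num.dt_leak > protocol.leak_window:
            raise ConfigurationError("dt_leak exceeds the leak window")
        if t_rem > t_inj_stop:
            bounds.append(t_rem)
            dts.append(num.dt_post)
        bounds.append(t_rem + protocol.leak_window)
        dts.append(num.dt_leak)
    if horizon > bounds[-1]:
        bounds.append(horizon)
        dts.append(num.dt_post)
    ts = [np.array([0.0])]
    for lo, hi, dt in zip(bounds[:-1], bounds[1:], dts):
        n = max(int(math.ceil((hi - lo) / dt)), 1)
        ts.append(np.linspace(lo, hi, n + 1)[1:])
    return np.concatenate(ts)


def simulate_pressure(
    protocol: InjectionProtocol,
    eta_if: float,
    *,
    epsilon: float = DEFAULT_EPSILON,
    k: float = DEFAULT_TISSUE_K,
    skin: Optional[SkinModel] = None,
    enzyme: Optional[EnzymeKinetics] = None,
    f_calibration: float = 1.0,
    numerics: Optional[Numerics] = None,
) -> PressureTrace:
    """Integrate the full five-phase backpressure profile.

    ``eta_if`` is the absolute interstitial-fluid viscosity in mPa·s.
    Explicit Euler on piecewise-uniform grids; deterministic. Returns a
    :class:`PressureTrace` with a :class:`BackflowResult` attached when the
    protocol includes needle removal.
    """
    if k <= 0:
        raise InvalidInputError("tissue conductivity must be > 0")
    skin = skin if skin is not None else SkinModel()
    num = numerics if numerics is not None else Numerics()
    if protocol.formulation_viscosity > 10.0 and protocol.q_inj > 2000.0:
        warnings.warn(
            "viscous formulation above 2 mL/min: backpressure is likely "
            "overpredicted in this regime"
        )

    t_grid = _segments(protocol, num)
    n = t_grid.size
    t_end = protocol.t_end
    t_rem = protocol.t_removal
    t_inj_stop = t_end if t_rem is None else min(t_end, t_rem)
    leak_end = (t_rem + protocol.leak_window) if t_rem is not None else math.inf

    eta_app = apparent_viscosity(protocol.formulation_viscosity, eta_if)
    f_base = pressure_factor(protocol.q_inj, protocol.v_inj / 1000.0) * f_calibration
    q_ul_s = protocol.q_inj / 60.0
    q_si = protocol.q_inj * 1e-9 / 60.0

    if enzyme is not None:
        degr = integrate_degradation(enzyme, float(t_grid[-1]), min(num.dt_post, 0.1))
        mw_grid = degr.mw_at(t_grid)
        f_of = lambda i: time_dependent_pressure_factor(f_base, float(mw_grid[i]), enzyme)
    else:
        f_of = lambda i: f_base

    p_tissue = np.zeros(n)
    p_bleb = np.zeros(n)
    phase = np.zeros(n, dtype=int)
    v_out = np.zeros(n)
    v_leak = np.zeros(n)
    v_del = np.zeros(n)

    leak_coef = (  # μL/s per kPa: π R_ext⁴ / (8 η_form L_N) in SI, rescaled
        math.pi
        * (protocol.needle_ext_radius * 1e-3) ** 4
        / (8.0 * protocol.formulation_viscosity * 1e-3 * protocol.needle_length * 1e-3)
        * 1e9
        * 1e3
    )

    drained = 0.0  # μL drained from the stressed volume since injection stop
    p_ref = 0.0  # tissue pressure when injection stopped
    v_stress_ref = stressed_volume(protocol.v_inj)
    wfv = wfh = 0.0
    cur_out = cur_leak = cur_del = 0.0
    dissipated = 0.0  # μL of bleb fluid lost to tissue after hole collapse

    for i, t in enumerate(t_grid):
        injecting = t <= t_inj_stop and t < t_end
        if t <= t_inj_stop:
            cur_del = q_ul_s * t
            v_ml = cur_del / 1000.0
            e_expr = elongation(v_ml, protocol.q_inj)
            wfv, wfh = waterfronts(v_ml, epsilon, e_expr)
            pt = _p12_pa(f_of(i), q_si, eta_app * 1e-3, wfv * 1e-3, k) / 1000.0
            if t == t_inj_stop:
                p_ref = pt
                v_stress_ref = stressed_volume(cur_del)
            ph = 1 if (v_ml == 0.0 or 0.574 * (v_ml * protocol.q_inj ** (1 / 3)) ** 0.4828 < 1.0) else 2
        else:
            pt = phase3_pressure(p_ref, drained, v_stress_ref, 0.0)
            if t < (t_rem if t_rem is not None else math.inf):
                ph = 3
            elif t < leak_end:
                ph = 4
            else:
                ph = 5
        if t_rem is not None and t_inj_stop == t_rem and t >= t_rem and t < leak_end:
            ph = 4  # removal during injection goes straight to the leak phase

        # Bleb fluid = everything delivered minus puncture-hole losses: the
        # relaxation outflow stays in the tissue around the depot and keeps
        # raising the skin until the hole has collapsed, after which the
        # continuing outflow dissipates the bleb.
        bleb_vol = cur_del - cur_leak - dissipated
        pb = skin.pressure(bleb_vol, wfh)
        p_tissue[i], p_bleb[i], phase[i] = pt, pb, ph
        v_out[i], v_leak[i], v_del[i] = cur_out, cur_leak, cur_del

        if i + 1 < n:
            dt = t_grid[i + 1] - t
            q_out = relaxation_flow(pt + pb, wfv, wfh, eta_app, f_of(i), k)
            q_lk = leak_coef * (pt + pb) if (t_rem is not None and t_rem <= t < leak_end) else 0.0
            cur_out += q_out * dt
            cur_leak += q_lk * dt
            if t >= t_inj_stop:
                drained += (q_out + q_lk) * dt
            if t >= leak_end:
                dissipated += q_out * dt

    trace = PressureTrace(
        t=t_grid,
        p_tissue=p_tissue,
        p_bleb=p_bleb,
        p_total=p_tissue + p_bleb,
        phase=phase,
        v_out=v_out,
        v_leak=v_leak,
        v_delivered=v_del,
    )
    if t_rem is not None:
        v_dead = dead_volume(protocol)
        total_leak = float(v_leak[-1]) + v_dead
        undelivered = max(protocol.v_inj - q_ul_s * t_inj_stop, 0.0)
        if t_rem < t_end:
            undelivered += protocol.v_device_residual
        else:
            undelivered = 0.0
        pct = min((undelivered + total_leak) / protocol.v_inj * 100.0, 100.0)
        trace.backflow = BackflowResult(
            v_dead=v_dead, v_loss=total_leak, percent_dose_loss=pct
        )
    return trace


def needle_removal(
    t_rem: float,
    protocol: InjectionProtocol,
    eta_if: float,
    **kwargs,
) -> tuple[BackflowResult, PressureTrace]:
    """Simulate with the needle removed at ``t_rem`` s and return the
    backflow summary together with the full pressure trace."""
    proto = protocol.model_copy(update={"t_removal": t_rem})
    trace = simulate_pressure(proto, eta_if, **kwargs)
    assert trace.backflow is not None
    return trace.backflow, trace
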
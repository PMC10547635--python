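"""Depot geometry and initial drug / interstitial-protein fields.

The injected formulation forms an ellipsoidal depot centred at the needle
tip: one vertical semi-axis WFV (along the needle) and two equal horizontal
semi-axes WFH ("waterfronts"). Subcutaneous tissue resists vertical
displacement more than horizontal, so above a volume-rate threshold the
depot elongates horizontally with elongation E = WFH/WFV following the
empirical law

    E(t) = 0.574 · (V_inj(t)[mL] · Q_inj[μL/min]^{1/3})^{0.4828},  clamped ≥ 1.

The depot occupies an apparent volume V_app = V_inj/ε where ε is the average
relative content of solution (RCS, default 0.13): locally the formulation
only partially replaces/dilates tissue. The local RCS decays sigmoidally
with distance from the needle tip,

    RCS(r) = (RCS_max/2)(1 + erf((α·WFX − β·r)/WFX)),

evaluated on the elliptical radius so the iso-RCS surfaces are scaled copies
of the waterfront ellipsoid. A global scale factor enforces exact dose
conservation on the voxelised field, so α, β act only on the profile shape.
Mobile interstitial proteins are flushed by the incoming formulation: their
initial field is the complement of the (unscaled) RCS profile.

Only the initial condition is produced here; later diffusion/absorption
dynamics are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "DEFAULT_EPSILON",
    "RCSProfileParams",
    "DepotGeometry",
    "VoxelGrid",
    "elongation",
    "waterfronts",
    "depot_geometry",
    "geometry_series",
    "rcs_profile",
    "build_fields",
]

#: Default average RCS ε (bleb-size studies; other datasets report 0.14-0.31).
DEFAULT_EPSILON = 0.13

_E_COEF = 0.574
_E_EXP = 0.4828


@dataclass(frozen=True)
class RCSProfileParams:
    """Shape parameters of the sigmoidal RCS(r) profile.

    Defaults put RCS(0) ≈ rcs_max and RCS(waterfront) ≈ 0 with a mid-depot
    inflection; exact dose conservation is guaranteed by the rescale in
    :func:`build_fields` regardless of these values.
    """

    rcs_max: float = 0.2
    alpha: float = 2.0
    beta: float = 2.2

    def __post_init__(self):
        if not 0.0 < self.rcs_max <= 1.0:
            raise InvalidInputError("rcs_max must be in (0, 1]")


@dataclass(frozen=True)
class DepotGeometry:
    """Depot state at one time point. Lengths mm, volumes mL, time s."""

    time: float
    wfv: float
    wfh: float
    elongation: float
    rcs_avg: float
    v_injected: float
    v_apparent: float


@dataclass
class VoxelGrid:
    """Cubic voxel fields centred on the needle tip.

    ``drug_field`` holds the scaled local RCS (volume fraction of
    formulation); ``drug_concentration`` the drug amount per voxel volume
    (dose units per mL); ``protein_field`` the mobile-protein concentration
    as a fraction of its baseline. Voxel centres sit at half-integer offsets
    from the grid corner; the needle tip is the grid centre.
    """

    n: int
    voxel_edge: float  # mm
    drug_field: np.ndarray = field(repr=False)
    protein_field: np.ndarray = field(repr=False)
    drug_concentration: np.ndarray = field(repr=False)
    scale: float = 1.0  # dose-conservation rescale applied to the RCS profile

    @property
    def voxel_volume_ml(self) -> float:
        return (self.voxel_edge * 0.1) ** 3  # mm³ -> mL via (mm/10 cm)³

    def to_frame(self) -> pd.DataFrame:
        """Flat (x, y, z, rcs, protein, drug_conc) table, coordinates in mm."""
        half = self.n / 2.0
        idx = (np.arange(self.n) + 0.5 - half) * self.voxel_edge
        x, y, z = np.meshgrid(idx, idx, idx, indexing="ij")
        return pd.DataFrame(
            {
                "x_mm": x.ravel(),
                "y_mm": y.ravel(),
                "z_mm": z.ravel(),
                "rcs": self.drug_field.ravel(),
                "protein_rel": self.protein_field.ravel(),
                "drug_conc": self.drug_concentration.ravel(),
            }
        )


def elongation(v_inj: float, q_inj: float) -> float:
    """Depot elongation E = WFH/WFV for volume v_inj (mL) at rate q_inj (μL/min).

    Clamped at 1 (spherical regime) when the empirical expression falls
    below 1 at small volume-rate products.
    """
    if v_inj < 0:
        raise InvalidInputError("injected volume must be >= 0")
    if q_inj <= 0:
        raise InvalidInputError("injection rate must be > 0")
    if v_inj == 0.0:
        return 1.0
    expr = _E_COEF * (v_inj * q_inj ** (1.0 / 3.0)) ** _E_EXP
    return max(expr, 1.0)


def waterfronts(v_inj_ml: float, epsilon: float, e: float) -> tuple[float, float]:
    """(WFV, WFH) in mm enclosing apparent volume v_inj/ε at elongation e.

    WFV = (3 V_app / (4π E²))^{1/3}, WFH = E·WFV, so that
    (4/3)π·WFH²·WFV = V_inj/ε exactly.
    """
    if epsilon <= 0:
        raise InvalidInputError("epsilon must be > 0")
    if v_inj_ml < 0:
        raise InvalidInputError("injected volume must be >= 0")
    v_app_mm3 = v_inj_ml / epsilon * 1000.0
    wfv = (3.0 * v_app_mm3 / (4.0 * math.pi * e * e)) ** (1.0 / 3.0)
    return wfv, e * wfv


def depot_geometry(
    t: float, v_inj_ml: float, q_inj: float, epsilon: float = DEFAULT_EPSILON
) -> DepotGeometry:
    """Geometry of the depot at time ``t`` (s) once ``v_inj_ml`` mL have been
    delivered at ``q_inj`` μL/min."""
    e = elongation(v_inj_ml, q_inj)
    wfv, wfh = waterfronts(v_inj_ml, epsilon, e)
    return DepotGeometry(
        time=t,
        wfv=wfv,
        wfh=wfh,
        elongation=e,
        rcs_avg=epsilon,
        v_injected=v_inj_ml,
        v_apparent=v_inj_ml / epsilon,
    )


def geometry_series(
    v_inj_ml: float,
    q_inj: float,
    epsilon: float = DEFAULT_EPSILON,
    n_points: int = 101,
) -> pd.DataFrame:
    """Time series of the growing depot over the injection window.

    Columns: t_s, wfv_mm, wfh_mm, elongation, v_injected_mL, v_apparent_mL.
    """
    t_end = v_inj_ml * 1000.0 / q_inj * 60.0  # s
    out = []
    for t in np.linspace(0.0, t_end, n_points):
        v = q_inj / 60.0 * t / 1000.0  # mL delivered
        g = depot_geometry(t, v, q_inj, epsilon)
        out.append((t, g.wfv, g.wfh, g.elongation, g.v_injected, g.v_apparent))
    return pd.DataFrame(
        out,
        columns=["t_s", "wfv_mm", "wfh_mm", "elongation", "v_injected_mL", "v_apparent_mL"],
    )


def rcs_profile(r, wfx: float, params: RCSProfileParams = RCSProfileParams()):
    """Local relative content of solution at distance r (mm) from the needle
    tip along an axis whose waterfront is ``wfx`` (mm). Non-increasing in r."""
    if wfx <= 0:
        raise InvalidInputError("waterfront must be > 0")
    r = np.asarray(r, dtype=float)
    out = params.rcs_max / 2.0 * (1.0 + erf((params.alpha * wfx - params.beta * r) / wfx))
    return out if out.ndim else float(out)


def build_fields(
    geometry: DepotGeometry,
    params: RCSProfileParams = RCSProfileParams(),
    dose: float = 1.0,
    n: int = 50,
    voxel_edge: float | None = None,
    span_factor: float = 1.2,
) -> VoxelGrid:
    """Voxelise the end-of-injection depot into drug and protein fields.

    The RCS profile is evaluated on the normalised elliptical radius
    u = sqrt((x²+y²)/WFH² + z²/WFV²) and cut at the waterfront (u > 1 → 0).
    The drug field is rescaled so the enclosed formulation volume equals the
    injected volume to 1e-6 relative (hence the enclosed drug mass equals
    ``dose``). The protein field is baseline × (1 − RCS/RCS_max) of the
    unscaled profile, clipped to [0, 1].
    """
    if n < 2:
        raise ConfigurationError("grid must have at least 2 voxels per side")
    if voxel_edge is None:
        voxel_edge = 2.0 * span_factor * geometry.wfh / n
    half_span = n * voxel_edge / 2.0
    if half_span < geometry.wfh or half_span < geometry.wfv:
        raise ConfigurationError(
            f"grid half-span {half_span:.3g} mm does not contain waterfronts "
            f"(WFH={geometry.wfh:.3g}, WFV={geometry.wfv:.3g} mm)"
        )
    centres = (np.arange(n) + 0.5) * voxel_edge - half_span
    x, y, z = np.meshgrid(centres, centres, centres, indexing="ij")
    u = np.sqrt((x * x + y * y) / geometry.wfh**2 + z * z / geometry.wfv**2)
    profile = params.rcs_max / 2.0 * (1.0 + erf(params.alpha - params.beta * u))
    profile[u > 1.0] = 0.0

    vox_ml = (voxel_edge * 0.1) ** 3
    enclosed = float(profile.sum()) * vox_ml
    if enclosed <= 0:
        raise ConfigurationError("depot does not overlap the voxel grid")
    scale = geometry.v_injected / enclosed
    drug = profile * scale
    conc = drug * (dose / geometry.v_injected)
    protein = np.clip(1.0 - profile / params.rcs_max, 0.0, 1.0)
    protein[u > 1.0] = 1.0
    return VoxelGrid(
        n=n,
        voxel_edge=voxel_edge,
        drug_field=drug,
        protein_field=protein,
        drug_concentration=conc,
        scale=scale,
    )
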
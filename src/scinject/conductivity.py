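"""Specific hydraulic conductivity of subcutaneous tissue.

Darcy flow through the extracellular matrix is controlled by the tissue's
specific hydraulic conductivity K (m²). Following the Carman-Kozeny picture,
each fibre population i (GAG, proteoglycan, collagen, cells) contributes

    K_i = θ_EC³ / (G S_i²),        S_i = 2 φ_i / r_i

where θ_EC is the extracellular void fraction, G the Kozeny factor for a
random arrangement of cylinders (Happel-Brenner), φ_i the fibre volume
fraction and r_i the fibre radius. Resistances add in series:
K_app = 1 / Σ 1/K_i, dominated by the thinnest fibres (collagen).

The shipped fibre table gives K_app ≈ 5.7e-17 m² at θ_EC = 0.103. The fibre
volume fractions are stored as literals (with the %w/w and fluid-uptake
provenance columns) because the mass→volume conversion chain is not fully
specified; a measured rat value of 7.12e-18 m² is a useful lower comparator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .errors import InvalidInputError

__all__ = [
    "FiberSpec",
    "TissueConductivity",
    "DEFAULT_THETA_EC",
    "DEFAULT_FIBERS",
    "DEFAULT_TISSUE_K",
    "kozeny_factor",
    "wetted_surface",
    "fiber_conductivity",
    "apparent_conductivity",
    "tissue_conductivity",
]

#: Default extracellular void fraction of subcutaneous tissue.
DEFAULT_THETA_EC = 0.103

#: Printed apparent conductivity used as the pressure-module default (m²).
DEFAULT_TISSUE_K = 5.67e-17


@dataclass(frozen=True)
class FiberSpec:
    """One fibre population of the extracellular matrix.

    radius in m; volume_fraction dimensionless; pct_ww_ecm and
    fluid_uptake_ml_g are provenance columns (not used in the computation).
    """

    name: str
    radius: float
    volume_fraction: float
    pct_ww_ecm: Optional[float] = None
    fluid_uptake_ml_g: Optional[float] = None

    def __post_init__(self):
        if self.radius <= 0:
            raise InvalidInputError(f"fiber {self.name}: radius must be > 0")
        if not 0.0 <= self.volume_fraction < 1.0:
            raise InvalidInputError(
                f"fiber {self.name}: volume fraction must be in [0, 1)"
            )

    @property
    def wetted_surface(self) -> float:
        return wetted_surface(self.volume_fraction, self.radius)

    def conductivity(self, theta: float = DEFAULT_THETA_EC) -> float:
        return fiber_conductivity(theta, kozeny_factor(theta), self.wetted_surface)


@dataclass(frozen=True)
class TissueConductivity:
    void_fraction: float
    kozeny_factor: float
    apparent_k: float  # m²


#: Fibre composition of the subcutaneous extracellular matrix.
DEFAULT_FIBERS: tuple[FiberSpec, ...] = (
    FiberSpec("GAG", 1.48e-7, 2.37e-4, pct_ww_ecm=0.26, fluid_uptake_ml_g=0.65),
    FiberSpec("proteoglycan", 1.16e-7, 5.01e-4, pct_ww_ecm=0.55, fluid_uptake_ml_g=0.65),
    FiberSpec("collagen", 3.70e-8, 3.67e-2, pct_ww_ecm=15.1, fluid_uptake_ml_g=1.735),
    FiberSpec("cells", 5e-5, 0.86),
)


def kozeny_factor(theta: float) -> float:
    """Happel-Brenner Kozeny factor for randomly arranged cylindrical fibres.

    One third of the fibres are taken parallel to the flow and two thirds
    perpendicular; each orientation contributes its own drag term. Valid for
    void fraction θ in (0, 1). G(0.103) ≈ 4.84.
    """
    if not 0.0 < theta < 1.0:
        raise InvalidInputError("void fraction must be in (0, 1)")
    e = 1.0 - theta  # solid fraction
    ln_term = math.log(1.0 / e)
    parallel = 2.0 * theta**3 / (e * (2.0 * ln_term - 3.0 + 4.0 * e - e * e))
    perpendicular = 2.0 * theta**3 / (e * (ln_term - (1.0 - e * e) / (1.0 + e * e)))
    return parallel / 3.0 + 2.0 * perpendicular / 3.0


def wetted_surface(phi: float, r_f: float) -> float:
    """Wetted surface area per unit volume, S = 2φ/r_f (m⁻¹)."""
    if r_f <= 0:
        raise InvalidInputError("fiber radius must be > 0")
    return 2.0 * phi / r_f


def fiber_conductivity(theta: float, g: float, s: float) -> float:
    """Specific hydraulic conductivity K = θ³/(G·S²) of one fibre population.

    A fibre with zero wetted surface offers no resistance; its conductivity
    is reported as ``math.inf`` and ignored by :func:`apparent_conductivity`.
    """
    if s == 0:
        return math.inf
    return theta**3 / (g * s * s)


def apparent_conductivity(fibers: Sequence[FiberSpec] | Iterable[float],
                          theta: float = DEFAULT_THETA_EC) -> float:
    """Series (harmonic) combination K_app = 1/Σ(1/K_i) over fibre populations.

    Accepts either :class:`FiberSpec` objects or precomputed conductivities
    (m²); infinite conductivities (zero-resistance fibres) are excluded.
    """
    items = list(fibers)
    if not items:
        raise InvalidInputError("at least one fiber is required")
    ks = [
        f.conductivity(theta) if isinstance(f, FiberSpec) else float(f)
        for f in items
    ]
    inv = sum(1.0 / k for k in ks if math.isfinite(k))
    if inv == 0.0:
        return math.inf
    return 1.0 / inv


def tissue_conductivity(
    fibers: Sequence[FiberSpec] = DEFAULT_FIBERS, theta: float = DEFAULT_THETA_EC
) -> TissueConductivity:
    return TissueConductivity(
        void_fraction=theta,
        kozeny_factor=kozeny_factor(theta),
        apparent_k=apparent_conductivity(fibers, theta),
    )
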
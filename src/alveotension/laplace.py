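"""Tension laws for the spherical alveolar model.

Thin-wall LaPlace tension T = PR/2, its thick-wall modification
T = PR/2z (dimensionally a wall *stress*), the tissue-conserving thinning
of the wall along inflation, finite versus differential tension
increments, and the hemisphere force-balance identity that underwrites
all of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Callable, NamedTuple, Optional

import numpy as np

from .errors import DomainError, UsageError
from .geometry import _check_nonnegative, _check_positive, _scalarize

__all__ = [
    "WallMode",
    "WallModel",
    "TensionIncrement",
    "tension_thin",
    "wall_thickness_at",
    "wall_stress_thick",
    "finite_tension_increment",
    "force_balance_residual",
]


class WallMode(str, Enum):
    THIN = "thin"
    THICK = "thick"


@dataclass(frozen=True)
class WallModel:
    """Wall description for a sphere.

    ``thin`` mode carries no thickness parameters.  ``thick`` mode pins the
    wall thickness ``z0`` at a reference radius ``R0`` and derives the
    thickness at any other radius from a thinning law.  The default law is
    thin-shell tissue-volume conservation (4 pi R^2 z constant, so
    z = z0 (R0/R)^2): the wall is a fixed quantity of tissue that thins as
    the sphere expands and thickens as it contracts.  The reference state
    (R0, z0) is explicit rather than implied, and ``thinning_law`` is a
    strategy hook so a mid-surface or incompressible thick-shell law can
    replace the default.
    """

    mode: WallMode = WallMode.THIN
    R0: Optional[float] = None
    z0: Optional[float] = None
    #: optional override z(R, wall); defaults to z0*(R0/R)**2
    thinning_law: Optional[Callable[[float, "WallModel"], float]] = None

    def __post_init__(self) -> None:
        mode = WallMode(self.mode)
        object.__setattr__(self, "mode", mode)
        if mode is WallMode.THICK:
            if self.R0 is None or self.z0 is None:
                raise DomainError("thick wall mode requires R0 and z0")
            _check_positive("R0", self.R0)
            _check_positive("z0", self.z0)
        elif self.R0 is not None or self.z0 is not None:
            raise DomainError("thin wall mode carries no thickness parameters (R0/z0)")


def tension_thin(P, R):
    """Thin-wall LaPlace wall tension T = PR/2 (cmH2O*cm).

    The larger the sphere, the more tension its membrane must carry for a
    given internal pressure.
    """
    _check_nonnegative("P", P)
    _check_positive("R", R)
    return _scalarize(np.asarray(P, dtype=float) * np.asarray(R, dtype=float) / 2.0)


def wall_thickness_at(R, wall: WallModel):
    """Wall thickness z at radius ``R`` under the wall's thinning law.

    Default law: tissue-volume conservation of a thin shell,
    4 pi R^2 z = 4 pi R0^2 z0, hence z = z0 (R0/R)^2 — the wall thickens
    on contraction and thins on expansion.

    Raises
    ------
    UsageError
        If called with a thin-mode wall (which has no thickness).
    """
    if WallMode(wall.mode) is not WallMode.THICK:
        raise UsageError("wall_thickness_at requires a thick-mode WallModel")
    _check_positive("R", R)
    if wall.thinning_law is not None:
        return wall.thinning_law(R, wall)
    R = np.asarray(R, dtype=float)
    return _scalarize(wall.z0 * (wall.R0 / R) ** 2)


def wall_stress_thick(P, R, z):
    """Modified LaPlace quantity PR/2z for a wall of thickness ``z``.

    PR/2z has pressure (stress) units, so it is named wall *stress* here
    even though it plays the role tension plays in the thin-wall law; the
    identity stress * z = thin-wall tension holds by construction.  At
    matched P and R, a thicker wall bears strictly less stress.
    """
    _check_positive("z", z)
    # computed as (PR/2)/z so stress*z recovers tension_thin to within 1 ulp
    return _scalarize(np.asarray(tension_thin(P, R)) / np.asarray(z, dtype=float))


class TensionIncrement(NamedTuple):
    """Finite tension change between two thin-wall states.

    ``exact`` is the product-difference (P2 R2 - P1 R1)/2, the value used
    in computations.  ``differential`` is the first-order form
    (R1 dP + P1 dR)/2; the two differ by exactly dP*dR/2.
    """

    exact: float
    differential: float


def finite_tension_increment(P1, R1, P2, R2) -> TensionIncrement:
    """Tension increment between thin-wall states (P1, R1) and (P2, R2).

    Expanding (P1+dP)(R1+dR)/2 - P1 R1/2 shows the exact increment exceeds
    the differential form R1 dP/2 + P1 dR/2 by the second-order term
    dP dR / 2, which vanishes quadratically as the increments shrink.
    """
    _check_nonnegative("P1", P1)
    _check_positive("R1", R1)
    _check_nonnegative("P2", P2)
    _check_positive("R2", R2)
    exact = (P2 * R2 - P1 * R1) / 2.0
    differential = 0.5 * R1 * (P2 - P1) + 0.5 * P1 * (R2 - R1)
    return TensionIncrement(exact=exact, differential=differential)


def force_balance_residual(P, R, T):
    """Net outward force on a hemispherical cap: pi R^2 P - 2 pi R T.

    Under static no-flow conditions the outward push of pressure on the
    equatorial disc must be exactly countered by the circumferential
    tension pulling along the cut rim, whatever the radius.  The residual
    is zero iff T = PR/2, positive when pressure wins, negative when
    tension wins (linear in T).

    Implementation note: evaluated in the factored form pi*R*(P*R - 2*T),
    algebraically identical, so that T = P*R/2 cancels exactly in floating
    point and the equilibrium residual is a true zero.
    """
    _check_nonnegative("P", P)
    _check_positive("R", R)
    P = np.asarray(P, dtype=float)
    R = np.asarray(R, dtype=float)
    T = np.asarray(T, dtype=float)
    return _scalarize(math.pi * R * (P * R - 2.0 * T))
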
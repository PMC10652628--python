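"""Elastic energy of tidal inflation on both of its descriptions.

The same conserved (elastic) energy can be written radially, as the area
under the pressure-volume curve, or at the alveolar boundary, as the
accumulated tension x surface-area product; for a sphere the two integrals
are identical (T dA = (PR/2)(8 pi R dR) = P 4 pi R^2 dR = P dV).  On top
of that identity this module computes the *damaging* part of the per-breath
energy — the part delivered above a pressure threshold Pt — the damaging
power f x DE, and the mapping between a pressure threshold and the wall
tension it implies.

Closed forms (exact for the constant-compliance model) are the primary
computation; trapezoidal path integration exists as the verification
oracle and for user-supplied nonlinear paths.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .errors import ConvergenceError, DomainError
from .geometry import J_PER_ML_CMH2O, SphereState, radius_from_volume

__all__ = [
    "Convention",
    "InflationPath",
    "EnergyReport",
    "elastic_energy_radial",
    "elastic_energy_surface",
    "damaging_energy",
    "damaging_power",
    "tension_threshold_from_pressure",
    "pressure_threshold_from_tension",
]


class Convention(str, Enum):
    """Accounting convention for energy above the threshold Pt.

    ``delivered``: all energy delivered while P > Pt (the default — energy
    delivered at alveolar pressures above the threshold potentially
    contributes to injury).
    ``excess``: only the energy in excess of what the same volume would
    store at P = Pt.
    """

    DELIVERED = "delivered"
    EXCESS = "excess"


@dataclass(frozen=True)
class InflationPath:
    """Ordered sequence of sphere states from end-expiration to end-inspiration.

    Volumes must be strictly increasing; each state is internally
    consistent by construction of :class:`SphereState`.
    """

    states: Tuple[SphereState, ...]

    def __post_init__(self) -> None:
        states = tuple(self.states)
        object.__setattr__(self, "states", states)
        if len(states) < 2:
            raise DomainError("InflationPath requires at least 2 states")
        vols = np.array([s.V for s in states])
        if not np.all(np.diff(vols) > 0):
            raise DomainError("InflationPath volumes must be strictly increasing")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def volumes(self) -> np.ndarray:
        return np.array([s.V for s in self.states])

    @property
    def pressures(self) -> np.ndarray:
        return np.array([s.P for s in self.states])

    @property
    def areas(self) -> np.ndarray:
        return np.array([s.A_s for s in self.states])

    @property
    def tensions(self) -> np.ndarray:
        return np.array([s.T for s in self.states])

    @classmethod
    def from_linear_compliance(
        cls,
        C: float,
        P_start: float,
        P_end: float,
        V_rest: float,
        n_states: int = 10_001,
    ) -> "InflationPath":
        """Discretise the linear-compliance trajectory V = V_rest + C*P.

        ``n_states`` thin-wall states at equally spaced pressures between
        ``P_start`` and ``P_end``.
        """
        if C <= 0:
            raise DomainError(f"C must be positive, got {C!r}")
        if V_rest <= 0:
            raise DomainError(f"V_rest must be positive, got {V_rest!r}")
        if not 0 <= P_start < P_end:
            raise DomainError(
                f"need 0 <= P_start < P_end, got P_start={P_start!r}, P_end={P_end!r}"
            )
        if n_states < 2:
            raise DomainError(f"n_states must be >= 2, got {n_states!r}")
        P = np.linspace(P_start, P_end, n_states)
        return cls(tuple(SphereState.thin(p, V_rest + C * p) for p in P))


def elastic_energy_radial(C: float, P_start: float, P_end: float) -> float:
    """Tidal elastic energy as the area under the linear P-V curve.

    For constant compliance C the integral of P dV from P_start to P_end
    is C (P_end^2 - P_start^2) / 2 (mL*cmH2O).  Deflation energetics are
    out of scope, so P_end < P_start is rejected.
    """
    if C <= 0:
        raise DomainError(f"C must be positive, got {C!r}")
    if P_start < 0:
        raise DomainError(f"P_start must be non-negative, got {P_start!r}")
    if P_end < P_start:
        raise DomainError(
            f"P_end must be >= P_start, got P_end={P_end!r} < P_start={P_start!r}"
        )
    return C * (P_end**2 - P_start**2) / 2.0


def elastic_energy_surface(path: InflationPath) -> float:
    """Surface-side elastic energy: trapezoidal accumulation of T dA_s.

    Converges quadratically to the radial energy of the same trajectory as
    the discretisation refines — the two descriptions of the conserved
    elastic energy must sum to the same value.
    """
    return float(np.trapezoid(path.tensions, path.areas))


def _validate_threshold_inputs(C: float, PEEP: float, P_plat: float, Pt: float) -> None:
    if C <= 0:
        raise DomainError(f"C must be positive, got {C!r}")
    if PEEP < 0:
        raise DomainError(f"PEEP must be non-negative, got {PEEP!r}")
    if P_plat < PEEP:
        raise DomainError(f"P_plat={P_plat!r} must be >= PEEP={PEEP!r}")
    if Pt < 0:
        raise DomainError(f"Pt must be non-negative, got {Pt!r}")


def damaging_energy(
    C: float,
    PEEP: float,
    P_plat: float,
    Pt: float,
    convention: Convention | str = Convention.DELIVERED,
) -> float:
    """Per-breath elastic energy above the pressure threshold Pt (mL*cmH2O).

    The tidal cycle delivers energy only from V(PEEP) upward (the
    PEEP-stored volume's energy is not re-counted each cycle), so the lower
    integration bound is P_lo = max(Pt, PEEP).  Zero whenever
    P_plat <= Pt.

    delivered : C (P_plat^2 - P_lo^2) / 2
    excess    : C [ (P_plat^2 - P_lo^2)/2 - Pt (P_plat - P_lo) ]
    """
    _validate_threshold_inputs(C, PEEP, P_plat, Pt)
    convention = Convention(convention)
    if P_plat <= Pt:
        return 0.0
    P_lo = max(Pt, PEEP)
    delivered = C * (P_plat**2 - P_lo**2) / 2.0
    if convention is Convention.DELIVERED:
        return delivered
    return delivered - C * Pt * (P_plat - P_lo)


def damaging_power(f: float, DE: float) -> float:
    """Damaging power f x DE (mL*cmH2O/min) for frequency f (breaths/min)."""
    if f < 0:
        raise DomainError(f"f must be non-negative, got {f!r}")
    if DE < 0:
        raise DomainError(f"DE must be non-negative, got {DE!r}")
    return f * DE


def power_to_J_per_min(power: float) -> float:
    """Display conversion of power from mL*cmH2O/min to J/min."""
    return power * J_PER_ML_CMH2O


def tension_threshold_from_pressure(Pt: float, V_rest: float, C: float) -> float:
    """Wall tension at the moment alveolar pressure crosses Pt (cmH2O*cm).

    On the linear-compliance trajectory the sphere holds V_rest + C*Pt at
    that moment, so Tt = Pt * R(V_rest + C*Pt) / 2.  Strictly increasing
    in Pt: both pressure and radius grow.
    """
    if Pt < 0:
        raise DomainError(f"Pt must be non-negative, got {Pt!r}")
    if V_rest <= 0:
        raise DomainError(f"V_rest must be positive, got {V_rest!r}")
    if C <= 0:
        raise DomainError(f"C must be positive, got {C!r}")
    return Pt * radius_from_volume(V_rest + C * Pt) / 2.0


#: Upper pressure bound used when inverting a tension threshold, cmH2O.
PRESSURE_CAP = 500.0


def pressure_threshold_from_tension(
    Tt: float, V_rest: float, C: float, cap: float = PRESSURE_CAP
) -> float:
    """Monitorable pressure threshold equivalent to a tension threshold Tt.

    The unique P >= 0 with tension_threshold_from_pressure(P) = Tt
    (uniqueness from strict monotonicity), found by bracketed root-finding
    to 1e-8 cmH2O.  A tension-defined safety limit thereby becomes a
    bedside pressure.

    Raises
    ------
    ConvergenceError
        If no P below ``cap`` (default 500 cmH2O) reaches Tt.
    """
    if Tt < 0:
        raise DomainError(f"Tt must be non-negative, got {Tt!r}")
    if Tt == 0:
        # validate remaining inputs through the forward map
        tension_threshold_from_pressure(0.0, V_rest, C)
        return 0.0

    def f(P: float) -> float:
        return tension_threshold_from_pressure(P, V_rest, C) - Tt

    if f(cap) < 0:
        raise ConvergenceError(
            f"tension threshold Tt={Tt!r} not reachable below the pressure cap {cap!r} cmH2O"
        )
    return float(brentq(f, 0.0, cap, xtol=1e-10, rtol=8.9e-16))


_CSV_FIELDS = (
    "E_total_mlcmH2O",
    "DE_mlcmH2O",
    "DE_convention",
    "power_mlcmH2O_min",
    "power_J_min",
    "Pt_cmH2O",
    "Tt_cmH2Ocm",
)


@dataclass(frozen=True)
class EnergyReport:
    """Per-breath energetics of one ventilation scenario.

    Fields are in the package units; ``power_J_min`` is the display
    conversion of the damaging power.  Under the delivered convention with
    PEEP >= 0, 0 <= DE <= E_total, and power = f x DE exactly.
    """

    E_total: float
    DE: float
    convention: Convention
    power: float
    Pt: float
    Tt: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "convention", Convention(self.convention))

    @property
    def power_J_min(self) -> float:
        return power_to_J_per_min(self.power)

    def to_dict(self) -> dict:
        return {
            "E_total_mlcmH2O": self.E_total,
            "DE_mlcmH2O": self.DE,
            "DE_convention": self.convention.value,
            "power_mlcmH2O_min": self.power,
            "power_J_min": self.power_J_min,
            "Pt_cmH2O": self.Pt,
            "Tt_cmH2Ocm": self.Tt,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @staticmethod
    def csv_header() -> str:
        return ",".join(_CSV_FIELDS)

    def to_csv_row(self) -> str:
        d = self.to_dict()
        return ",".join(str(d[k]) for k in _CSV_FIELDS)
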
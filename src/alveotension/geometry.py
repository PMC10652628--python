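"""Sphere geometry for the single-compartment alveolar model.

The aerated lung (or any of its subunits) is idealised as one thin-walled,
balloon-like hollow sphere, so every state of inflation is fully described
by a radius.  This module holds the volume/radius/surface-area conversions
and the incremental area-to-volume strain ratio that the tension and energy
layers build on.

Units are fixed package-wide: lengths in cm, volumes in mL (== cm^3),
pressures in cmH2O, wall tension in cmH2O*cm, energy in mL*cmH2O.  The two
conversion constants below are display conversions only; no internal
computation leaves the cm/mL/cmH2O system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = [
    "J_PER_ML_CMH2O",
    "N_PER_M_PER_CMH2O_CM",
    "COINCIDENT_RTOL",
    "SphereState",
    "radius_from_volume",
    "volume_from_radius",
    "surface_area",
    "area_volume_increment_ratio",
]

#: 1 mL*cmH2O expressed in joules (g*cm of water column -> SI).
J_PER_ML_CMH2O = 9.80665e-5

#: 1 cmH2O*cm of wall tension expressed in N/m.
N_PER_M_PER_CMH2O_CM = 0.980665

#: Relative radius separation below which two radii are treated as coincident
#: by :func:`area_volume_increment_ratio`, which then returns the analytic
#: limit 2/R1 instead of evaluating a 0/0 quotient.
COINCIDENT_RTOL = 1e-9

# Internal-consistency tolerance for SphereState invariants.
_RTOL = 1e-12


def _check_positive(name: str, value) -> None:
    if isinstance(value, (int, float)):  # scalar fast path (hot in path building)
        if not (math.isfinite(value) and value > 0):
            raise DomainError(f"{name} must be positive and finite, got {value!r}")
        return
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)) or not np.all(arr > 0):
        raise DomainError(f"{name} must be positive and finite, got {value!r}")


def _check_nonnegative(name: str, value) -> None:
    if isinstance(value, (int, float)):
        if not (math.isfinite(value) and value >= 0):
            raise DomainError(f"{name} must be non-negative and finite, got {value!r}")
        return
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)) or not np.all(arr >= 0):
        raise DomainError(f"{name} must be non-negative and finite, got {value!r}")


def _scalarize(arr: np.ndarray):
    return float(arr) if arr.ndim == 0 else arr


def radius_from_volume(V):
    """Radius of the sphere holding volume ``V``: R = (3V/4pi)^(1/3).

    Parameters
    ----------
    V : float or array_like
        Absolute gas volume, mL.  Must be strictly positive.

    Returns
    -------
    float or ndarray
        Radius in cm.  Round-trips with :func:`volume_from_radius` to
        relative 1e-12.
    """
    _check_positive("V", V)
    if isinstance(V, (int, float)):
        return math.cbrt(3.0 * V / (4.0 * math.pi))
    return _scalarize(np.cbrt(3.0 * np.asarray(V, dtype=float) / (4.0 * math.pi)))


def volume_from_radius(R):
    """Volume of a sphere of radius ``R``: V = 4 pi R^3 / 3 (mL)."""
    _check_positive("R", R)
    if isinstance(R, (int, float)):
        return 4.0 * math.pi * R**3 / 3.0
    R = np.asarray(R, dtype=float)
    return _scalarize(4.0 * math.pi * R**3 / 3.0)


def surface_area(R):
    """Surface area of a sphere of radius ``R``: A_s = 4 pi R^2 (cm^2).

    This is the area of the shell-like cellular membrane (SLM) on which
    wall tension acts.
    """
    _check_positive("R", R)
    if isinstance(R, (int, float)):
        return 4.0 * math.pi * R * R
    R = np.asarray(R, dtype=float)
    return _scalarize(4.0 * math.pi * R**2)


def area_volume_increment_ratio(R1, R2):
    """Finite-increment ratio dA_s/dV between radii ``R1`` and ``R2``.

    Evaluates 3 (R2^2 - R1^2) / (R2^3 - R1^3), which equals
    (A_s(R2) - A_s(R1)) / (V(R2) - V(R1)) for a sphere.  Area strain is
    the 2/3 power of volume strain at the margin, so this ratio — not
    unity — is what links tidal volume to membrane-area stretch.

    When ``|R2 - R1| < COINCIDENT_RTOL * max(R1, R2)`` the analytic limit
    2/R1 (the pointwise dA/dV of a sphere) is returned instead of a 0/0
    quotient; the switch preserves continuity.

    Returns
    -------
    float or ndarray
        Ratio in 1/cm.
    """
    _check_positive("R1", R1)
    _check_positive("R2", R2)
    R1 = np.asarray(R1, dtype=float)
    R2 = np.asarray(R2, dtype=float)
    coincident = np.abs(R2 - R1) < COINCIDENT_RTOL * np.maximum(R1, R2)
    denom = np.where(coincident, 1.0, R2**3 - R1**3)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(coincident, 2.0 / R1, 3.0 * (R2**2 - R1**2) / denom)
    return _scalarize(ratio)


def _isclose(a: float, b: float) -> bool:
    return math.isclose(a, b, rel_tol=_RTOL, abs_tol=1e-300)


@dataclass(frozen=True)
class SphereState:
    """One sphere at one instant of inflation.

    Attributes
    ----------
    P : float
        Elastic (alveolar) pressure, cmH2O.  Non-negative: this is an
        inflation model and negative pressures are rejected rather than
        interpreted.
    R : float
        Radius, cm.
    V : float
        Volume, mL; must satisfy V = 4 pi R^3 / 3.
    A_s : float
        Surface area, cm^2; must satisfy A_s = 4 pi R^2.
    T : float
        Wall tension, cmH2O*cm (thin wall, T = PR/2) or wall stress,
        cmH2O (thick wall, T = PR/2z).
    z : float, optional
        Wall thickness, cm.  Absent means the thin-wall idealisation.
    """

    P: float
    R: float
    V: float
    A_s: float
    T: float
    z: float | None = None

    def __post_init__(self) -> None:
        _check_nonnegative("P", self.P)
        _check_positive("R", self.R)
        _check_positive("V", self.V)
        _check_positive("A_s", self.A_s)
        if self.z is not None:
            _check_positive("z", self.z)
        if not _isclose(self.V, 4.0 * math.pi * self.R**3 / 3.0):
            raise DomainError(
                f"V={self.V!r} inconsistent with R={self.R!r} (V must equal 4*pi*R^3/3)"
            )
        if not _isclose(self.A_s, 4.0 * math.pi * self.R**2):
            raise DomainError(
                f"A_s={self.A_s!r} inconsistent with R={self.R!r} (A_s must equal 4*pi*R^2)"
            )
        expected_T = (
            self.P * self.R / 2.0 if self.z is None else self.P * self.R / (2.0 * self.z)
        )
        if not math.isclose(self.T, expected_T, rel_tol=_RTOL, abs_tol=1e-15):
            kind = "tension P*R/2" if self.z is None else "wall stress P*R/(2z)"
            raise DomainError(f"T={self.T!r} inconsistent with {kind} = {expected_T!r}")

    @classmethod
    def thin(cls, P: float, V: float) -> "SphereState":
        """Build an internally consistent thin-wall state from (P, V)."""
        _check_nonnegative("P", P)
        R = radius_from_volume(V)
        return cls(P=float(P), R=R, V=float(V), A_s=surface_area(R), T=float(P) * R / 2.0)

    @property
    def tension_N_per_m(self) -> float:
        """Display conversion of T to N/m (thin wall only; meaningless for stress)."""
        return self.T * N_PER_M_PER_CMH2O_CM
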
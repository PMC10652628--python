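"""Clinical layer: the ARDS "baby lung" resolved into spherical subunits.

In ARDS the aerated remnant of the lung behaves as a small lung of
quasi-normal subunits: observed compliance tracks the *number* n of open
units, not their stiffness.  This module estimates the resting (zero-PEEP)
volume from the compliance ratio, assembles absolute volumes from the
ventilator settings (V = FRC + PEEP*C + V_T), builds whole-lung and
per-subunit sphere states at end-expiration and end-inspiration, and
carries the scaling law that compares wall tensions within and between
lungs: at matched cumulative volume and pressure, subunit tension scales
as n^(-1/3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from enum import Enum
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, UsageError
from .geometry import SphereState, radius_from_volume, surface_area
from .laplace import WallMode, WallModel, wall_stress_thick, wall_thickness_at
from . import energy as _energy

__all__ = [
    "LungModel",
    "VentSettings",
    "Phase",
    "StrainMetrics",
    "estimate_resting_volume",
    "absolute_volumes",
    "whole_lung_state",
    "subunit_state",
    "tension_ratio_between_lungs",
    "strain_metrics",
    "prediction_sweep",
]

#: Normal respiratory-system compliance range, mL/cmH2O; values outside it
#: trigger a warning (not an error) because C_norm anchors the resting-volume
#: estimate.
C_NORM_RANGE = (80.0, 100.0)


def estimate_resting_volume(C_obs: float, C_norm: float, FRC_pred: float) -> float:
    """Resting (unstressed, zero-PEEP) baby-lung volume, mL.

    V_rest = (C_obs / C_norm) * FRC_pred: if compliance tracks the number
    of quasi-normal open units, the observed-to-normal compliance ratio is
    also the fraction of the predicted healthy FRC that remains aerated.
    A reasonable though imprecise estimate.
    """
    for name, v in (("C_obs", C_obs), ("C_norm", C_norm), ("FRC_pred", FRC_pred)):
        if v <= 0:
            raise DomainError(f"{name} must be positive, got {v!r}")
    return (C_obs / C_norm) * FRC_pred


@dataclass(frozen=True)
class LungModel:
    """Patient-level parameters of the baby-lung sphere model.

    Parameters
    ----------
    C_obs : float
        Observed respiratory-system compliance, mL/cmH2O.
    C_norm : float
        Normal reference compliance, mL/cmH2O (usually 80-100).
    FRC_pred : float
        Predicted healthy FRC, mL.  Reference equations for it depend on
        age, sex and body size; supply the value from whichever predictor
        you use (no formula is hard-coded).
    V_rest : float, optional
        Resting (zero-PEEP) aerated volume, mL.  If omitted it is
        estimated as (C_obs/C_norm) * FRC_pred.
    n : int, optional
        Number of identical spherical subunits.  If omitted and ``v0`` is
        given, n = round(V_rest / v0); otherwise n = 1.  Absolute subunit
        tensions are scale-dependent on n; cross-lung comparisons are
        ratio-based and independent of it.
    v0 : float, optional
        Per-subunit resting volume, mL, used only to derive n.
    wall : WallModel, optional
        Wall-thickness model; omitted means thin-wall.
    """

    C_obs: float
    C_norm: float
    FRC_pred: float
    V_rest: Optional[float] = None
    n: Optional[int] = None
    v0: Optional[float] = None
    wall: Optional[WallModel] = None

    def __post_init__(self) -> None:
        for name in ("C_obs", "C_norm", "FRC_pred"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive, got {getattr(self, name)!r}")
        if not C_NORM_RANGE[0] <= self.C_norm <= C_NORM_RANGE[1]:
            warnings.warn(
                f"C_norm={self.C_norm} mL/cmH2O outside the normal range "
                f"{C_NORM_RANGE[0]:.0f}-{C_NORM_RANGE[1]:.0f} mL/cmH2O",
                stacklevel=2,
            )
        if self.V_rest is None:
            object.__setattr__(
                self,
                "V_rest",
                estimate_resting_volume(self.C_obs, self.C_norm, self.FRC_pred),
            )
        elif self.V_rest <= 0:
            raise DomainError(f"V_rest must be positive, got {self.V_rest!r}")
        if self.n is None:
            if self.v0 is not None:
                if self.v0 <= 0:
                    raise DomainError(f"v0 must be positive, got {self.v0!r}")
                n = round(self.V_rest / self.v0)
                if n < 1:
                    raise DomainError(
                        f"v0={self.v0!r} implies subunit count {n} < 1 for V_rest={self.V_rest!r}"
                    )
                object.__setattr__(self, "n", n)
            else:
                object.__setattr__(self, "n", 1)
        elif self.n < 1:
            raise DomainError(f"n must be >= 1, got {self.n!r}")

    @property
    def subunit_resting_volume(self) -> float:
        """Resting volume per subunit, mL."""
        return self.V_rest / self.n


@dataclass(frozen=True)
class VentSettings:
    """Ventilator settings of one scenario.

    P_plat and DP are derived from the lung's compliance:
    P_plat = PEEP + V_T/C_obs and DP = V_T/C_obs.
    """

    V_T: float
    PEEP: float
    f: float
    Pt: Optional[float] = None

    def __post_init__(self) -> None:
        if self.V_T < 0:
            raise DomainError(f"V_T must be non-negative, got {self.V_T!r}")
        if self.PEEP < 0:
            raise DomainError(f"PEEP must be non-negative, got {self.PEEP!r}")
        if self.f < 0:
            raise DomainError(f"f must be non-negative, got {self.f!r}")
        if self.Pt is not None and self.Pt < 0:
            raise DomainError(f"Pt must be non-negative, got {self.Pt!r}")

    def driving_pressure(self, C_obs: float) -> float:
        """DP = V_T / C_obs, cmH2O."""
        if C_obs <= 0:
            raise DomainError(f"C_obs must be positive, got {C_obs!r}")
        return self.V_T / C_obs

    def plateau_pressure(self, C_obs: float) -> float:
        """P_plat = PEEP + V_T / C_obs, cmH2O."""
        return self.PEEP + self.driving_pressure(C_obs)

    def peep_volume(self, C_obs: float) -> float:
        """V_PEEP = C_obs * PEEP, mL."""
        if C_obs <= 0:
            raise DomainError(f"C_obs must be positive, got {C_obs!r}")
        return C_obs * self.PEEP


class Phase(str, Enum):
    END_EXP = "end_exp"
    END_INSP = "end_insp"


def absolute_volumes(lung: LungModel, vent: VentSettings) -> tuple[float, float]:
    """Absolute sphere volumes at end-expiration and end-inspiration, mL.

    V_ee = V_rest + C_obs * PEEP (unstressed FRC plus the PEEP-related
    increment); V_ei = V_ee + V_T.
    """
    V_ee = lung.V_rest + vent.peep_volume(lung.C_obs)
    return V_ee, V_ee + vent.V_T


def _state_at(P: float, V: float, wall: Optional[WallModel]) -> SphereState:
    if wall is None or WallMode(wall.mode) is WallMode.THIN:
        return SphereState.thin(P, V)
    R = radius_from_volume(V)
    z = wall_thickness_at(R, wall)
    return SphereState(
        P=float(P), R=R, V=float(V), A_s=surface_area(R),
        T=wall_stress_thick(P, R, z), z=z,
    )


def whole_lung_state(lung: LungModel, vent: VentSettings, phase: Phase | str) -> SphereState:
    """Whole-baby-lung sphere state at the requested breath phase.

    Pressure is PEEP at end-expiration and P_plat at end-inspiration;
    volume comes from :func:`absolute_volumes`; radius and area follow from
    sphere geometry; T is PR/2 (thin wall) or the wall stress PR/2z under
    the lung's WallModel.
    """
    phase = Phase(phase)
    V_ee, V_ei = absolute_volumes(lung, vent)
    if phase is Phase.END_EXP:
        return _state_at(vent.PEEP, V_ee, lung.wall)
    return _state_at(vent.plateau_pressure(lung.C_obs), V_ei, lung.wall)


def subunit_state(whole: SphereState, n: int) -> SphereState:
    """One of ``n`` identical subunits sharing the whole sphere's volume.

    Same pressure; volume V/n; radius R/n^(1/3); hence tension T/n^(1/3) —
    the tighter curvature of a smaller sphere achieves force balance with
    less wall tension.  A thick wall's thickness is unchanged by the
    resolution, so stress also scales as n^(-1/3).
    """
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n!r}")
    if n == 1:
        return whole
    scale = float(np.cbrt(float(n)))
    R = whole.R / scale
    return SphereState(
        P=whole.P,
        R=R,
        V=whole.V / n,
        A_s=surface_area(R),
        T=whole.T / scale,
        z=whole.z,
    )


def tension_ratio_between_lungs(nA: int, nB: int) -> float:
    """T_B / T_A for two lungs of equal cumulative volume and pressure.

    Lung A is resolved into nA subunits and lung B into nB; the ratio is
    (nB/nA)^(-1/3): the same volume split into more (hence smaller) units
    carries less wall tension per unit.
    """
    if nA < 1:
        raise DomainError(f"nA must be >= 1, got {nA!r}")
    if nB < 1:
        raise DomainError(f"nB must be >= 1, got {nB!r}")
    return float((nB / nA) ** (-1.0 / 3.0))


class StrainMetrics(NamedTuple):
    """Relative increments over one tidal inflation.

    ``dT_rel`` is None when the end-expiratory tension is zero (PEEP = 0),
    where a relative tension change is undefined.
    """

    dV_rel: float
    dA_rel: float
    dT_rel: Optional[float]


def strain_metrics(ee: SphereState, ei: SphereState) -> StrainMetrics:
    """Volumetric, areal and tensile strain between end-exp and end-insp.

    For a sphere dA_rel = (1 + dV_rel)^(2/3) - 1 identically; with any
    resting volume and PEEP > 0, tension outpaces area: dT_rel > dA_rel.
    """
    if not ei.V > ee.V:
        raise DomainError(
            f"end-inspiratory volume {ei.V!r} must exceed end-expiratory {ee.V!r}"
        )
    dV_rel = (ei.V - ee.V) / ee.V
    dA_rel = (ei.A_s - ee.A_s) / ee.A_s
    dT_rel = (ei.T - ee.T) / ee.T if ee.T > 0 else None
    return StrainMetrics(dV_rel=dV_rel, dA_rel=dA_rel, dT_rel=dT_rel)


class SweepVariable(str, Enum):
    FRC = "FRC"
    PEEP = "PEEP"
    V_T = "V_T"
    N = "n"
    PRESSURE = "pressure"


#: Long-format sweep table columns (unit suffixes are part of the contract).
SWEEP_COLUMNS = (
    "variable",
    "value",
    "P_plat_cmH2O",
    "V_ee_ml",
    "V_ei_ml",
    "T_whole_cmH2Ocm",
    "T_sub_cmH2Ocm",
    "A_s_whole_cm2",
    "A_s_sub_cm2",
    "dV_rel",
    "dA_rel",
    "dT_rel",
    "DE_mlcmH2O",
    "power_mlcmH2O_min",
)


def _sweep_row(lung: LungModel, vent: VentSettings, variable: str, value: float) -> dict:
    ee = whole_lung_state(lung, vent, Phase.END_EXP)
    ei = whole_lung_state(lung, vent, Phase.END_INSP)
    ee_sub = subunit_state(ee, lung.n)
    ei_sub = subunit_state(ei, lung.n)
    if ei.V > ee.V:
        sm = strain_metrics(ee, ei)
    else:
        sm = StrainMetrics(0.0, 0.0, 0.0 if ee.T > 0 else None)
    P_plat = vent.plateau_pressure(lung.C_obs)
    if vent.Pt is not None:
        DE = _energy.damaging_energy(lung.C_obs, vent.PEEP, P_plat, vent.Pt)
        power = _energy.damaging_power(vent.f, DE)
    else:
        DE = float("nan")
        power = float("nan")
    return {
        "variable": variable,
        "value": value,
        "P_plat_cmH2O": P_plat,
        "V_ee_ml": ee.V,
        "V_ei_ml": ei.V,
        "T_whole_cmH2Ocm": ei.T,
        "T_sub_cmH2Ocm": ei_sub.T,
        "A_s_whole_cm2": ei.A_s,
        "A_s_sub_cm2": ei_sub.A_s,
        "dV_rel": sm.dV_rel,
        "dA_rel": sm.dA_rel,
        "dT_rel": np.nan if sm.dT_rel is None else sm.dT_rel,
        "DE_mlcmH2O": DE,
        "power_mlcmH2O_min": power,
    }


def prediction_sweep(
    lung: LungModel,
    vent: VentSettings,
    variable: SweepVariable | str,
    grid: Sequence[float],
) -> pd.DataFrame:
    """Sweep one scenario variable over a grid; one row per grid point.

    Variables
    ---------
    ``FRC``
        V_rest takes each grid value; compliance is re-coupled through
        constant specific compliance, C_obs = C_norm * FRC / FRC_pred, and
        the subunit count scales with it (fixed per-subunit resting
        volume), since compliance tracks the number of open units.
    ``PEEP``, ``V_T``, ``n``
        The corresponding setting or count takes each grid value.
    ``pressure``
        End-inspiratory pressure takes each grid value (>= PEEP); tidal
        volume is implied, V_T = C_obs * (P - PEEP).
    """
    variable = SweepVariable(variable)
    grid = list(grid)
    if len(grid) < 1:
        raise UsageError("sweep grid must contain at least one value")
    rows = []
    for value in grid:
        if variable is SweepVariable.FRC:
            if value <= 0:
                raise DomainError(f"FRC grid values must be positive, got {value!r}")
            v0 = lung.subunit_resting_volume
            n = max(1, round(value / v0))
            C = lung.C_norm * value / lung.FRC_pred
            lung_i = replace(lung, V_rest=value, C_obs=C, n=n, v0=None)
            vent_i = vent
        elif variable is SweepVariable.PEEP:
            lung_i, vent_i = lung, replace(vent, PEEP=value)
        elif variable is SweepVariable.V_T:
            lung_i, vent_i = lung, replace(vent, V_T=value)
        elif variable is SweepVariable.N:
            lung_i, vent_i = replace(lung, n=int(value), v0=None), vent
        else:  # pressure
            if value < vent.PEEP:
                raise DomainError(
                    f"pressure grid value {value!r} below PEEP={vent.PEEP!r}"
                )
            lung_i = lung
            vent_i = replace(vent, V_T=lung.C_obs * (value - vent.PEEP))
        rows.append(_sweep_row(lung_i, vent_i, variable.value, value))
    return pd.DataFrame(rows, columns=list(SWEEP_COLUMNS))
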
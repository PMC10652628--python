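import math
from dataclasses import replace

import numpy as np
import pytest

from alveotension import (
    DomainError,
    LungModel,
    Phase,
    SphereState,
    UsageError,
    VentSettings,
    WallMode,
    WallModel,
    absolute_volumes,
    estimate_resting_volume,
    force_balance_residual,
    prediction_sweep,
    radius_from_volume,
    strain_metrics,
    subunit_state,
    tension_ratio_between_lungs,
    tension_thin,
    whole_lung_state,
)


class TestRestingVolumeEstimate:
    def test_healthy_lung_recovers_predicted_frc(self):
        assert estimate_resting_volume(90.0, 90.0, 2400.0) == pytest.approx(2400.0)

    def test_half_compliance_half_volume(self):
        assert estimate_resting_volume(40.0, 80.0, 2400.0) == pytest.approx(1200.0)

    def test_linear_in_observed_compliance(self):
        base = estimate_resting_volume(20.0, 80.0, 2400.0)
        assert estimate_resting_volume(60.0, 80.0, 2400.0) == pytest.approx(3 * base)

    def test_domain(self):
        with pytest.raises(DomainError, match="C_norm"):
            estimate_resting_volume(40.0, 0.0, 2400.0)


class TestLungModel:
    def test_estimated_resting_volume_is_exact(self, ards_lung):
        assert ards_lung.V_rest == (40.0 / 80.0) * 2400.0

    def test_subunit_count_from_per_unit_volume(self):
        lung = LungModel(C_obs=40.0, C_norm=80.0, FRC_pred=2400.0, v0=0.003)
        assert lung.n == round(1200.0 / 0.003)

    def test_abnormal_reference_compliance_warns_not_errors(self):
        with pytest.warns(UserWarning, match="80-100"):
            LungModel(C_obs=40.0, C_norm=120.0, FRC_pred=2400.0)

    def test_invalid_subunit_count(self):
        with pytest.raises(DomainError):
            LungModel(C_obs=40.0, C_norm=80.0, FRC_pred=2400.0, n=0)


class TestVentSettings:
    def test_derived_pressures(self, vent):
        assert vent.driving_pressure(40.0) == 400.0 / 40.0
        assert vent.plateau_pressure(40.0) == 10.0 + 10.0
        assert vent.peep_volume(40.0) == 400.0

    def test_domain(self):
        with pytest.raises(DomainError):
            VentSettings(V_T=-1.0, PEEP=0.0, f=10.0)


class TestAbsoluteVolumes:
    def test_zeep_zero_tidal(self, ards_lung):
        V_ee, V_ei = absolute_volumes(ards_lung, VentSettings(V_T=0.0, PEEP=0.0, f=10.0))
        assert V_ee == V_ei == ards_lung.V_rest

    def test_clinical_terms_equation(self, ards_lung, vent):
        # V = FRC + PEEP*C + V_T
        assert absolute_volumes(ards_lung, vent) == (1600.0, 2000.0)

    def test_tidal_volume_conserved(self, ards_lung, rng):
        for _ in range(20):
            v = VentSettings(
                V_T=rng.uniform(0, 700), PEEP=rng.uniform(0, 24), f=15.0
            )
            V_ee, V_ei = absolute_volumes(ards_lung, v)
            assert V_ei - V_ee == pytest.approx(v.V_T, rel=1e-12, abs=1e-9)


class TestWholeLungState:
    def test_zeep_end_expiration_is_resting_sphere(self, ards_lung):
        st = whole_lung_state(
            ards_lung, VentSettings(V_T=400.0, PEEP=0.0, f=20.0), Phase.END_EXP
        )
        assert st.P == 0.0
        assert st.T == 0.0
        assert st.V == ards_lung.V_rest

    def test_states_satisfy_force_balance(self, ards_lung, vent):
        for phase in Phase:
            st = whole_lung_state(ards_lung, vent, phase)
            assert force_balance_residual(st.P, st.R, st.T) == 0.0

    def test_end_inspiration_worked_example(self, ards_lung, vent):
        st = whole_lung_state(ards_lung, vent, Phase.END_INSP)
        assert st.P == pytest.approx(20.0)
        assert st.V == pytest.approx(2000.0)
        assert st.T == pytest.approx(10.0 * radius_from_volume(2000.0), rel=1e-12)
        assert st.T == pytest.approx(78.159, rel=1e-4)

    def test_thick_wall_state_carries_stress(self, vent):
        wall = WallModel(mode=WallMode.THICK, R0=7.0, z0=0.5)
        lung = LungModel(C_obs=40.0, C_norm=80.0, FRC_pred=2400.0, wall=wall)
        st = whole_lung_state(lung, vent, Phase.END_INSP)
        assert st.z == pytest.approx(0.5 * (7.0 / st.R) ** 2, rel=1e-12)
        assert st.T * st.z == pytest.approx(tension_thin(st.P, st.R), rel=1e-12)


class TestSubunitState:
    def test_single_unit_is_whole(self):
        whole = SphereState.thin(20.0, 2000.0)
        assert subunit_state(whole, 1) is whole

    def test_eight_subunits_halve_tension_brute_force(self):
        """Oracle: build the 8 spheres explicitly and compute PR/2 for each."""
        whole = SphereState.thin(20.0, 2000.0)
        oracle = tension_thin(20.0, radius_from_volume(2000.0 / 8))
        sub = subunit_state(whole, 8)
        assert sub.T == pytest.approx(oracle, rel=1e-12)
        assert sub.T == pytest.approx(whole.T / 2, rel=1e-12)

    def test_volume_conserved(self):
        whole = SphereState.thin(20.0, 2000.0)
        for n in (2, 7, 64, 1000):
            assert n * subunit_state(whole, n).V == pytest.approx(whole.V, rel=1e-12)

    def test_rejects_fractional_lung(self):
        with pytest.raises(DomainError):
            subunit_state(SphereState.thin(20.0, 2000.0), 0)


class TestTensionRatioBetweenLungs:
    def test_equal_counts(self):
        assert tension_ratio_between_lungs(5, 5) == 1.0

    def test_eightfold_units_halve_tension(self):
        assert tension_ratio_between_lungs(1, 8) == pytest.approx(0.5, rel=1e-12)

    def test_agrees_with_explicit_construction_on_grid(self):
        whole = SphereState.thin(15.0, 1500.0)
        for nA in (1, 2, 3, 8, 27, 64):
            for nB in (1, 2, 3, 8, 27, 64):
                explicit = subunit_state(whole, nB).T / subunit_state(whole, nA).T
                assert tension_ratio_between_lungs(nA, nB) == pytest.approx(
                    explicit, rel=1e-12
                )

    def test_power_law_slope(self):
        """log T_sub vs log n has slope -1/3 at matched volume and pressure."""
        whole = SphereState.thin(20.0, 2000.0)
        ns = np.array([1, 2, 4, 8, 27, 64, 1000], dtype=float)
        T = np.array([subunit_state(whole, int(n)).T for n in ns])
        slope = np.polyfit(np.log(ns), np.log(T), 1)[0]
        assert slope == pytest.approx(-1.0 / 3.0, abs=1e-12)


class TestStrainMetrics:
    def test_sphere_scaling_identity(self, ards_lung, vent):
        ee = whole_lung_state(ards_lung, vent, Phase.END_EXP)
        ei = whole_lung_state(ards_lung, vent, Phase.END_INSP)
        sm = strain_metrics(ee, ei)
        assert sm.dA_rel == pytest.approx((1 + sm.dV_rel) ** (2 / 3) - 1, rel=1e-12)

    def test_zero_peep_tension_strain_undefined(self, ards_lung):
        v = VentSettings(V_T=400.0, PEEP=0.0, f=20.0)
        sm = strain_metrics(
            whole_lung_state(ards_lung, v, Phase.END_EXP),
            whole_lung_state(ards_lung, v, Phase.END_INSP),
        )
        assert sm.dT_rel is None

    def test_tension_strain_exceeds_area_strain(self, rng):
        for _ in range(200):
            lung = LungModel(
                C_obs=rng.uniform(15, 80), C_norm=90.0, FRC_pred=rng.uniform(1800, 3000)
            )
            v = VentSettings(
                V_T=rng.uniform(100, 600), PEEP=rng.uniform(1, 20), f=15.0
            )
            sm = strain_metrics(
                whole_lung_state(lung, v, Phase.END_EXP),
                whole_lung_state(lung, v, Phase.END_INSP),
            )
            assert sm.dT_rel > sm.dA_rel

    def test_deflation_rejected(self, ards_lung, vent):
        ee = whole_lung_state(ards_lung, vent, Phase.END_EXP)
        ei = whole_lung_state(ards_lung, vent, Phase.END_INSP)
        with pytest.raises(DomainError):
            strain_metrics(ei, ee)


class TestPredictionSweep:
    def test_pressure_sweep_tension_disproportionate(self, ards_lung):
        """T/P strictly increases with pressure: T ~ P (V_rest + CP)^(1/3)."""
        vent = VentSettings(V_T=0.0, PEEP=0.0, f=20.0, Pt=15.0)
        table = prediction_sweep(
            ards_lung, vent, "pressure", np.linspace(1.0, 40.0, 100)
        )
        ratio = table["T_whole_cmH2Ocm"] / table["P_plat_cmH2O"]
        assert np.all(np.diff(ratio) > 0)

    def test_frc_sweep_subunit_tension_inverse(self, vent):
        """Under constant specific compliance, more FRC means less subunit tension."""
        lung = LungModel(C_obs=40.0, C_norm=80.0, FRC_pred=2400.0, v0=0.004)
        vent0 = VentSettings(V_T=400.0, PEEP=0.0, f=20.0, Pt=15.0)
        table = prediction_sweep(lung, vent0, "FRC", np.linspace(600.0, 3000.0, 25))
        assert np.all(np.diff(table["T_sub_cmH2Ocm"]) < 0)

    def test_single_point_grid_echoes_whole_lung_state(self, ards_lung, vent):
        table = prediction_sweep(ards_lung, vent, "PEEP", [vent.PEEP])
        assert len(table) == 1
        st = whole_lung_state(ards_lung, vent, Phase.END_INSP)
        assert table.loc[0, "T_whole_cmH2Ocm"] == pytest.approx(st.T, rel=1e-12)
        assert table.loc[0, "V_ei_ml"] == pytest.approx(st.V, rel=1e-12)

    def test_empty_grid_rejected(self, ards_lung, vent):
        with pytest.raises(UsageError):
            prediction_sweep(ards_lung, vent, "PEEP", [])

    def test_subunit_count_sweep(self, ards_lung, vent):
        table = prediction_sweep(ards_lung, vent, "n", [1, 8, 64])
        T = table["T_sub_cmH2Ocm"].to_numpy()
        assert T[1] == pytest.approx(T[0] / 2, rel=1e-12)
        assert T[2] == pytest.approx(T[0] / 4, rel=1e-12)
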
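import math
import warnings
from dataclasses import replace

import numpy as np
import pytest
from scipy import optimize

from seedsim.diffusivity import DiffusivityParams, diffusivity
from seedsim.isotherm import IsothermParams, equilibrium_moisture
from seedsim.material import air_properties, saturation_pressure
from seedsim.solver import (
    AirSchedule,
    DryingCurve,
    SimulationConfig,
    _get_aw_evaluators,
    _rates,
    _surface_aw,
    compute_biot,
    coat_flux,
    evaporative_flux,
    heat_step,
    initialize,
    internal_fluxes,
    run,
    step,
    transfer_coefficients,
)

AIR = (298.15, 0.30, 0.235)


class TestInitialize:
    def test_shell_volumes_fill_the_sphere(self):
        cfg = SimulationConfig()
        st = initialize(cfg)
        assert st.V.sum() == pytest.approx(4 / 3 * math.pi * cfg.R0**3, rel=1e-12)
        # equal-volume shells at t = 0
        np.testing.assert_allclose(st.V, st.V[0], rtol=1e-12)

    def test_uniform_concentration(self):
        st = initialize(SimulationConfig())
        np.testing.assert_allclose(st.c_w, st.c_w[0], rtol=1e-12)

    def test_moisture_round_trip(self):
        cfg = SimulationConfig(MC0=0.367)
        st = initialize(cfg)
        assert st.mc_total == pytest.approx(0.367, abs=1e-10)

    def test_radii_strictly_increasing(self):
        st = initialize(SimulationConfig(N=7))
        assert np.all(np.diff(st.r_outer) > 0)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            SimulationConfig(N=2)
        with pytest.raises(ValueError):
            SimulationConfig(MC0=1.2)


class TestTransferCoefficients:
    def test_pure_diffusion_limit(self):
        # U = 0 collapses Sherwood and Nusselt to 2
        st = initialize(SimulationConfig())
        air = (298.15, 0.30, 0.0)
        beta, _ = transfer_coefficients(st, air)
        props = air_properties(298.15)
        assert beta == pytest.approx(2.0 * props.D_air / (2 * st.radius), rel=1e-12)

    def test_series_resistance_bound(self):
        st = initialize(SimulationConfig())
        _, h_eff = transfer_coefficients(st, AIR)
        props = air_properties(298.15)
        Re = 0.235 * 2 * st.radius / props.nu_air
        Nu = 2 + 0.6 * math.sqrt(Re) * props.Pr**0.33
        h_ext = Nu * props.lambda_air / (2 * st.radius)
        assert h_eff < h_ext

    def test_hand_evaluation_oracle(self):
        # independent arithmetic of the Ranz-Marshall closures
        st = initialize(SimulationConfig())
        beta, h_eff = transfer_coefficients(st, AIR)
        R = st.radius
        props = air_properties(298.15)
        Re = 0.235 * 2 * R / props.nu_air
        Sc = props.nu_air / props.D_air
        Sh = 2 + 0.6 * math.sqrt(Re) * Sc**0.33
        assert beta == pytest.approx(Sh * props.D_air / (2 * R), rel=1e-12)
        from seedsim.material import effective_thermal

        lam, _, _ = effective_thermal(
            st.config.composition, st.T, st.config.constants
        )
        h_int = lam / (0.25 * R)
        Nu = 2 + 0.6 * math.sqrt(Re) * props.Pr**0.33
        h_ext = Nu * props.lambda_air / (2 * R)
        assert h_eff == pytest.approx(1 / (1 / h_int + 1 / h_ext), rel=1e-12)


class TestEvaporativeFlux:
    def test_zero_at_activity_equilibrium(self):
        st = initialize(SimulationConfig())
        assert evaporative_flux(st, (298.15, 0.7, 0.235), 0.06, 0.7) == 0.0

    def test_boundary_layer_temperature_weighting(self):
        # T_avg = (T_air + 2 T)/3 enters the denominator
        st = initialize(SimulationConfig())
        st.T = 293.15
        air = (303.15, 0.30, 0.235)
        J = evaporative_flux(st, air, 1.0, 1.0)
        c = st.config.constants
        T_avg = (303.15 + 2 * 293.15) / 3
        assert T_avg == pytest.approx(296.483, abs=1e-3)
        expected = c.M_w / (c.R_gas * T_avg) * saturation_pressure(293.15) * (1.0 - 0.30)
        assert J == pytest.approx(expected, rel=1e-12)

    def test_condensation_allowed(self):
        st = initialize(SimulationConfig())
        assert evaporative_flux(st, (298.15, 0.9, 0.235), 0.06, 0.2) < 0


class TestInternalFluxes:
    def test_uniform_concentration_gives_zero(self):
        st = initialize(SimulationConfig())
        np.testing.assert_allclose(internal_fluxes(st), 0.0, atol=1e-25)

    def test_two_shell_toy_hand_oracle(self):
        # prescribed concentrations and constant D against the flux formula
        cfg = SimulationConfig(N=3, linear_mode=True, linear_D=2e-10)
        st = initialize(cfg)
        st.m_water = st.m_water * np.array([1.2, 1.0, 0.8])
        st.update_geometry()
        c = st.c_w
        flows = internal_fluxes(st)
        for k in range(2):
            area = 4 * math.pi * st.r_outer[k] ** 2
            expected = (
                -2e-10 * (c[k + 1] - c[k]) / (st.r_centroid[k + 1] - st.r_centroid[k]) * area
            )
            assert flows[k] == pytest.approx(expected, rel=1e-12)

    def test_flux_follows_gradient_outward(self):
        cfg = SimulationConfig(N=5)
        st = initialize(cfg)
        st.m_water = st.m_water * np.linspace(1.3, 0.7, 5)  # wetter core
        st.update_geometry()
        assert np.all(internal_fluxes(st) > 0)


class TestCoatFlux:
    def _mid_drying_state(self, mode, beta="auto"):
        iso = IsothermParams(model="FH_LS", chi_ws=1.244)
        cfg = SimulationConfig(
            N=10,
            material_mode=mode,
            isotherm=iso,
            isotherm_coat=replace(iso) if mode == "two_material" else None,
            beta_int=beta,
        )
        sched = AirSchedule.constant(*AIR)
        curve = run(cfg, sched, t_end=900.0)
        return curve.final_state

    def test_identical_materials_limit(self):
        # activity-driven flux reduces to the concentration-driven one
        st = self._mid_drying_state("two_material")
        J_aw = coat_flux(st)
        one = replace(st.config, material_mode="one_material", isotherm_coat=None)
        st_one = initialize(one)
        st_one.m_water = st.m_water.copy()
        st_one.T = st.T
        st_one.update_geometry()
        J_conc = internal_fluxes(st_one)[-1]
        assert J_aw == pytest.approx(J_conc, rel=0.01)

    def test_zero_at_equal_activity(self):
        st = self._mid_drying_state("two_material")
        st.m_water[-1] = st.m_water[-2] * st.m_solid[-1] / st.m_solid[-2]
        st.update_geometry()
        # identical isotherms and equal y_w on both sides -> equal a_w
        # (tolerance: rounding in y leaves a ~1e-16 relative activity gap)
        assert coat_flux(st) == pytest.approx(0.0, abs=1e-18)

    def test_water_flows_down_activity_gradient(self):
        st = self._mid_drying_state("two_material")
        emb, coat = _get_aw_evaluators(st)
        y = st.y_w_shell
        a_in = emb(float(y[-2]), st.T)
        a_out = coat(float(y[-1]), st.T)
        J = coat_flux(st)
        assert math.copysign(1.0, J) == math.copysign(1.0, a_in - a_out)


class TestHeatStep:
    def test_thermal_equilibrium_is_stationary(self):
        st = initialize(SimulationConfig())
        assert heat_step(st, AIR, 60.0, 0.0) == 0.0

    def test_seed_warms_toward_air(self):
        st = initialize(SimulationConfig(T0_seed=288.15))
        assert heat_step(st, AIR, 60.0, 0.0) > 0

    def test_strict_sign_switch_cools_instead(self):
        cfg = SimulationConfig(T0_seed=288.15, strict_heat_sign=True)
        st = initialize(cfg)
        assert heat_step(st, AIR, 60.0, 0.0) < 0

    def test_pseudo_wet_bulb_depression(self):
        """During active drying the seed sits below air temperature,
        near the root of h_eff (T_air - T) = L J_evap(T)."""
        cfg = SimulationConfig(
            N=5, R0=5e-4, isotherm=IsothermParams(model="FH_LS", chi_ws=1.244)
        )
        sched = AirSchedule.constant(*AIR)
        curve = run(cfg, sched, t_end=1800.0)
        assert curve.temp_seed_K.min() < 298.15 - 0.5

        # steady-state balance with a saturated surface bounds the dip
        st = initialize(cfg)

        def balance(T):
            st.T = T
            beta, h_eff = transfer_coefficients(st, AIR)
            c = cfg.constants
            T_avg = (AIR[0] + 2 * T) / 3
            J = beta * c.M_w / (c.R_gas * T_avg) * saturation_pressure(T) * (1.0 - 0.30)
            L = c.dH_evap0 + (c.c_p_v - c.c_p_w) * (T - c.T_0)
            return h_eff * (AIR[0] - T) - L * J

        T_wb = optimize.brentq(balance, 273.16, 298.15)
        assert curve.temp_seed_K.min() > T_wb - 0.5


class TestStep:
    def test_equilibrium_fixed_point(self, comp):
        # air in equilibrium with the seed: nothing moves
        iso = IsothermParams(model="FH_LS", chi_ws=1.244)
        mc_eq = equilibrium_moisture(0.30, 298.15, comp, iso)
        cfg = SimulationConfig(MC0=mc_eq, isotherm=iso)
        st = initialize(cfg)
        m0 = st.m_water.copy()
        for _ in range(1000):
            step(st, AIR, 1.0)
        np.testing.assert_allclose(st.m_water, m0, rtol=1e-9)
        assert st.T == pytest.approx(298.15, abs=1e-6)

    def test_single_step_mass_audit(self):
        cfg = SimulationConfig()
        st = initialize(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            dm, _, J, _, _ = _rates(st, AIR)
            total_before = st.total_water
            step(st, AIR, 0.5)
        # total change equals evaporative loss (internal flows cancel)
        assert total_before - st.total_water == pytest.approx(
            st.evaporated, rel=1e-12
        )

    def test_oversized_step_aborts(self):
        cfg = SimulationConfig()
        st = initialize(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            with pytest.raises(RuntimeError, match="too large"):
                step(st, AIR, 1e6)

    def test_solid_mass_untouched(self):
        cfg = SimulationConfig()
        st = initialize(cfg)
        solid0 = st.m_solid.copy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for _ in range(50):
                step(st, AIR, 0.2)
        np.testing.assert_array_equal(st.m_solid, solid0)


class TestRun:
    def test_radius_shrinks_monotonically(self, baseline_run):
        # net drying: water leaves, the sphere contracts
        assert baseline_run.mc_wb[-1] < baseline_run.mc_wb[0]
        assert baseline_run.final_state.radius < baseline_run.final_state.config.R0

    def test_monotone_drying_under_dry_air(self, baseline_run):
        assert np.all(np.diff(baseline_run.mc_wb) <= 1e-12)

    def test_water_conservation(self, baseline_run):
        assert baseline_run.audit["water_conservation_residual"] < 1e-8

    def test_solid_mass_invariant(self, baseline_run):
        assert baseline_run.audit["solid_mass_drift"] < 1e-12

    def test_grid_convergence_first_order(self, baseline_schedule):
        # deviation from the fine grid shrinks as shells double
        iso = IsothermParams(model="FH_LS", chi_ws=1.244)
        curves = {}
        for N in (5, 10, 20):
            cfg = SimulationConfig(
                N=N,
                R0=5e-4,
                isotherm=iso,
                diffusivity=DiffusivityParams(floor=1e-11),
                output_interval=300.0,
            )
            curves[N] = run(cfg, baseline_schedule, t_end=3000.0)
        t = curves[20].time_s
        ref = curves[20].mc_wb
        err5 = np.max(np.abs(np.interp(t, curves[5].time_s, curves[5].mc_wb) - ref))
        err10 = np.max(np.abs(np.interp(t, curves[10].time_s, curves[10].mc_wb) - ref))
        assert err10 < err5

    def test_two_material_identical_matches_one_material(self, baseline_schedule):
        iso = IsothermParams(model="FH_LS", chi_ws=1.244)
        base = dict(N=10, R0=5e-4, isotherm=iso,
                    diffusivity=DiffusivityParams(floor=1e-11),
                    output_interval=600.0)
        one = run(SimulationConfig(material_mode="one_material", **base),
                  baseline_schedule, t_end=5400.0)
        two = run(SimulationConfig(material_mode="two_material",
                                   isotherm_coat=replace(iso), **base),
                  baseline_schedule, t_end=5400.0)
        mc_two = np.interp(one.time_s, two.time_s, two.mc_wb)
        assert np.max(np.abs(mc_two - one.mc_wb) / one.mc_wb) < 0.01

    def test_two_material_distinct_coat_changes_prediction(self, baseline_schedule):
        emb = IsothermParams(model="FH_LS", chi_ws=1.302)
        coat = replace(emb, chi_ws=0.465)
        base = dict(N=10, R0=5e-4,
                    diffusivity=DiffusivityParams(floor=1e-11),
                    output_interval=600.0)
        one = run(SimulationConfig(material_mode="one_material", isotherm=emb, **base),
                  baseline_schedule, t_end=3600.0)
        two = run(SimulationConfig(material_mode="two_material", isotherm=emb,
                                   isotherm_coat=coat, **base),
                  baseline_schedule, t_end=3600.0)
        assert abs(two.mc_wb[-1] - one.mc_wb[-1]) > 1e-4


class TestBiot:
    def test_still_air_limit(self):
        # U = 0: Bi -> (Nu=2) lambda_air / lambda_eff
        st = initialize(SimulationConfig())
        from seedsim.material import effective_thermal

        lam_eff, _, _ = effective_thermal(st.config.composition, st.T, st.config.constants)
        props = air_properties(298.15)
        assert compute_biot(st, (298.15, 0.3, 0.0)) == pytest.approx(
            props.lambda_air / lam_eff, rel=1e-12
        )

    def test_lumped_temperature_justified(self):
        st = initialize(SimulationConfig())
        assert compute_biot(st, AIR) < 0.4

    def test_increases_with_air_speed(self):
        st = initialize(SimulationConfig())
        bi = [compute_biot(st, (298.15, 0.3, u)) for u in (0.0, 0.235, 1.0)]
        assert bi[0] < bi[1] < bi[2]


class TestAirSchedule:
    def test_constant(self):
        s = AirSchedule.constant(313.15, 0.2, 0.5)
        assert s.at(0.0) == (313.15, 0.2, 0.5)
        assert s.at(1e6) == (313.15, 0.2, 0.5)

    def test_interpolation_and_hold(self):
        s = AirSchedule(
            times=[0.0, 100.0], T_air=[300.0, 310.0], RH_air=[0.2, 0.4], U=[0.2, 0.2]
        )
        T, rh, _ = s.at(50.0)
        assert T == pytest.approx(305.0)
        assert rh == pytest.approx(0.3)
        assert s.at(500.0)[0] == pytest.approx(310.0)  # held beyond the end

    def test_csv_round_trip(self, tmp_path):
        s = AirSchedule(
            times=[0.0, 60.0, 120.0],
            T_air=[298.15, 299.15, 300.15],
            RH_air=[0.3, 0.32, 0.29],
            U=[0.235] * 3,
        )
        p = tmp_path / "sched.csv"
        s.write_csv(p)
        back = AirSchedule.read_csv(p)
        np.testing.assert_allclose(back.T_air, s.T_air)
        np.testing.assert_allclose(back.RH_air, s.RH_air)

    def test_validation(self):
        with pytest.raises(ValueError):
            AirSchedule(times=[0.0, 0.0], T_air=[300, 300], RH_air=[0.3, 0.3], U=[0, 0])
        with pytest.raises(ValueError):
            AirSchedule(times=[0.0], T_air=[300], RH_air=[1.5], U=[0.2])

    def test_time_varying_run(self):
        # measured-air input mode: ramping temperature changes the outcome
        iso = IsothermParams(model="FH_LS", chi_ws=1.244)
        base = dict(N=5, R0=5e-4, isotherm=iso,
                    diffusivity=DiffusivityParams(floor=1e-11),
                    output_interval=600.0)
        ramp = AirSchedule(
            times=[0.0, 3600.0],
            T_air=[288.15, 308.15],
            RH_air=[0.3, 0.3],
            U=[0.235, 0.235],
        )
        const = AirSchedule.constant(288.15, 0.3)
        c_ramp = run(SimulationConfig(**base), ramp, t_end=3600.0)
        c_const = run(SimulationConfig(**base), const, t_end=3600.0)
        assert c_ramp.mc_wb[-1] < c_const.mc_wb[-1]  # warmer air dries faster
        assert c_ramp.temp_seed_K[-1] > c_const.temp_seed_K[-1]


class TestDryingCurveIO:
    def test_csv_round_trip(self, tmp_path, baseline_run):
        p = tmp_path / "curve.csv"
        baseline_run.write_csv(p)
        back = DryingCurve.read_csv(p)
        np.testing.assert_allclose(back.mc_wb, baseline_run.mc_wb)
        np.testing.assert_allclose(back.temp_seed_K, baseline_run.temp_seed_K)

    def test_missing_columns(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("t,mc\n0,0.3\n")
        with pytest.raises(ValueError):
            DryingCurve.read_csv(p)


def test_config_from_yaml(tmp_path):
    cfg_text = """
N: 8
R0: 0.0008
MC0: 0.3
isotherm:
  model: FH_LS
  chi_ws: 1.302
  CK:
    T_g_s: 400.0
diffusivity:
  a: 3.0e-11
  b: 9.0e-11
  floor: 1.0e-12
"""
    p = tmp_path / "cfg.yaml"
    p.write_text(cfg_text)
    cfg = SimulationConfig.from_yaml(p)
    assert cfg.N == 8
    assert cfg.isotherm.chi_ws == 1.302
    assert cfg.isotherm.CK.T_g_s == 400.0
    assert cfg.diffusivity.floor == 1e-12
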
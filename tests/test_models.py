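import numpy as np
import pytest

import viaspace as v
from conftest import (
    ACDC_BISTABLE,
    ACDC_OSC,
    ACDC_Y0,
    DFF_COUNTER,
    REP_Y0,
    REPRESSILATOR_OSC,
    point,
)


class TestRHS:
    def test_empty_system_fixed_point(self, repressilator):
        theta = point(repressilator, {**REPRESSILATOR_OSC, "alpha": 0.0, "alpha0": 0.0})
        d = v.rhs(repressilator, np.zeros(6), 0.0, theta)
        assert np.allclose(d, 0.0)

    def test_mrna_nullcline(self, repressilator):
        # with Z = 0 the mX equation balances at (alpha + alpha0) / delta_m
        theta = point(repressilator, REPRESSILATOR_OSC)
        mx_star = (REPRESSILATOR_OSC["alpha"] + REPRESSILATOR_OSC["alpha0"]) / \
            REPRESSILATOR_OSC["delta_m"]
        state = np.array([mx_star, 0.0, 0.0, 0.0, 0.0, 0.0])
        d = v.rhs(repressilator, state, 0.0, theta)
        assert d[0] == pytest.approx(0.0, abs=1e-10)

    def test_protein_decay_term(self, repressilator):
        # X = 150 nM, mX = 0: dX/dt = -delta_p * X = -117 nM/h
        theta = point(repressilator, REPRESSILATOR_OSC)
        state = np.array([0.0, 0.0, 0.0, 150.0, 0.0, 0.0])
        d = v.rhs(repressilator, state, 0.0, theta)
        assert d[3] == pytest.approx(-117.0, rel=1e-12)

    def test_dimension_mismatch_rejected(self, repressilator):
        theta = point(repressilator, REPRESSILATOR_OSC)
        with pytest.raises(ValueError):
            v.rhs(repressilator, np.zeros(4), 0.0, theta)

    def test_negative_kd_rejected(self, repressilator):
        theta = point(repressilator, {**REPRESSILATOR_OSC, "Kd": -1.0})
        with pytest.raises(ValueError):
            v.rhs(repressilator, np.zeros(6), 0.0, theta)

    def test_flipflop_omega_variants_differ(self):
        space = v.parameter_space(v.get_model("dflipflop", 0, 0))
        vals = {**DFF_COUNTER, "K_M": 50.0, "E_prot": 100.0}
        theta = v.ParameterPoint(np.array([vals[n] for n in space.names]))
        state = np.array([10.0, 5.0, 20.0, 2.0])
        d_mich = v.rhs(v.get_model("dflipflop", 0, 0), state, 1.0, theta)
        lin = v.get_model("dflipflop", 0, 1)
        theta_lin = point(lin, DFF_COUNTER)
        d_lin = v.rhs(lin, state, 1.0, theta_lin)
        assert not np.allclose(d_mich, d_lin)


class TestClk:
    @pytest.mark.parametrize(
        "t,expected", [(0.0, 100.0), (13.0, 0.0), (24.5, 100.0), (11.9, 100.0)]
    )
    def test_square_wave_convention(self, t, expected):
        assert v.clk_signal(t, period=24.0, amplitude=100.0, duty=0.5) == expected

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            v.clk_signal(0.0, period=-1.0, amplitude=100.0)
        with pytest.raises(ValueError):
            v.clk_signal(0.0, period=24.0, amplitude=100.0, duty=1.5)


class TestBounds:
    def test_boundary_inclusive(self, repressilator):
        space = v.parameter_space(repressilator)
        assert v.check_bounds(v.ParameterPoint(space.lower.copy()), space)
        assert v.check_bounds(v.ParameterPoint(space.upper.copy()), space)

    def test_degradation_above_range(self, repressilator):
        space = v.parameter_space(repressilator)
        vals = {**REPRESSILATOR_OSC, "delta_p": 60.0}
        assert not v.check_bounds(point(repressilator, vals), space)

    def test_hill_below_range(self, repressilator):
        vals = {**REPRESSILATOR_OSC, "n": 0.5}
        assert not v.check_bounds(point(repressilator, vals),
                                  v.parameter_space(repressilator))


class TestSimulate:
    def test_zero_production_zero_trajectory(self, acdc):
        theta = point(acdc, {**ACDC_OSC, "alpha": 0.0})
        traj = v.simulate(acdc, theta, np.zeros(6), 10.0, dt_out=0.1)
        assert np.allclose(traj.y, 0.0)

    @pytest.mark.parametrize("model_id", ["repressilator", "acdc", "dflipflop"])
    def test_pure_decay_is_monotone(self, model_id):
        model = v.get_model(model_id)
        space = v.parameter_space(model)
        base = {"repressilator": REPRESSILATOR_OSC, "acdc": ACDC_OSC,
                "dflipflop": DFF_COUNTER}[model_id]
        vals = dict(base)
        for k in ("alpha", "alpha0", "alpha1", "alpha2", "alpha3", "alpha4",
                  "beta"):
            if k in vals:
                vals[k] = 0.0
        theta = v.ParameterPoint(np.array([vals[n] for n in space.names]))
        y0 = np.full(len(model.species), 50.0)
        traj = v.simulate(model, theta, y0, 20.0, dt_out=0.1)
        diffs = np.diff(traj.y, axis=0)
        assert np.all(diffs <= 1e-9)
        assert np.all(traj.y[-1] < y0)

    def test_constant_repressor_steady_state(self, repressilator):
        # freeze Z by zeroing translation and protein decay: mX must converge
        # to the closed-form limit (alpha/(1+(Z/Kd)^n) + alpha0) / delta_m
        vals = {**REPRESSILATOR_OSC, "beta": 0.0, "delta_p": 0.0}
        theta = point(repressilator, vals)
        z0 = 80.0
        y0 = np.array([0.0, 0.0, 0.0, 0.0, 0.0, z0])
        traj = v.simulate(repressilator, theta, y0, 30.0, dt_out=0.1)
        expected = (vals["alpha"] / (1.0 + (z0 / vals["Kd"]) ** vals["n"])
                    + vals["alpha0"]) / vals["delta_m"]
        assert traj.column("mX")[-1] == pytest.approx(expected, rel=1e-3)

    def test_flipflop_degradation_forms_agree_in_degenerate_limit(self):
        # with K_M >> P the Michaelian rate is effectively constant; a linear
        # model with delta = delta*E/K_M + dilution must match the decay
        km, eprot = 250.0, 100.0
        ddil = 0.6
        d_eff = 1.5
        d_mich = d_eff * km / eprot  # so that d_mich*E/K_M = d_eff
        mich = v.get_model("dflipflop", 1, 0)
        sp_m = v.parameter_space(mich)
        vals_m = {"alpha1": 0.0, "alpha2": 0.0, "alpha3": 0.0, "alpha4": 0.0,
                  "delta1": d_mich, "delta2": d_mich, "Kd": 10.0, "n": 2.0,
                  "K_M": km, "E_prot": eprot}
        th_m = v.ParameterPoint(np.array([vals_m[n] for n in sp_m.names]))
        lin = v.get_model("dflipflop", 1, 1)
        sp_l = v.parameter_space(lin)
        vals_l = {"alpha1": 0.0, "alpha2": 0.0, "alpha3": 0.0, "alpha4": 0.0,
                  "delta1": d_eff + ddil, "delta2": d_eff + ddil,
                  "Kd": 10.0, "n": 2.0}
        th_l = v.ParameterPoint(np.array([vals_l[n] for n in sp_l.names]))
        y0 = np.array([0.1, 0.1, 0.1, 0.1])  # P << K_M throughout
        tr_m = v.simulate(mich, th_m, y0, 5.0, dt_out=0.05)
        tr_l = v.simulate(lin, th_l, y0, 5.0, dt_out=0.05)
        assert np.allclose(tr_m.y, tr_l.y, rtol=0.01, atol=1e-4)

    def test_tolerance_halving_stability(self, repressilator):
        theta = point(repressilator, REPRESSILATOR_OSC)
        t1 = v.simulate(repressilator, theta, REP_Y0, 48.0)
        t2 = v.simulate(repressilator, theta, REP_Y0, 48.0, rtol=5e-7, atol=5e-10)
        m1 = v.measure_oscillation(t1, "X")
        m2 = v.measure_oscillation(t2, "X")
        assert m1["period"] == pytest.approx(m2["period"], rel=5e-3)
        assert m1["amplitude"] == pytest.approx(m2["amplitude"], rel=5e-3)

    def test_independent_integrator_agrees(self, repressilator):
        # cross-check LSODA against an implicit Radau integration of the
        # same right-hand side
        from scipy.integrate import solve_ivp

        theta = point(repressilator, REPRESSILATOR_OSC)
        space = v.parameter_space(repressilator)
        traj = v.simulate(repressilator, theta, REP_Y0, 30.0, dt_out=0.1)
        sol = solve_ivp(
            lambda t, y: v.rhs(repressilator, np.clip(y, 0, None), t, theta),
            (0.0, 30.0), REP_Y0, method="Radau", rtol=1e-8, atol=1e-10,
            t_eval=traj.t,
        )
        assert sol.success
        scale = np.abs(sol.y.T).max()
        assert np.allclose(traj.y, sol.y.T, atol=5e-3 * scale)

    def test_negative_initial_state_rejected(self, repressilator):
        theta = point(repressilator, REPRESSILATOR_OSC)
        with pytest.raises(ValueError):
            v.simulate(repressilator, theta, -REP_Y0, 1.0)

    def test_bistable_caption_settles_at_printed_levels(self, acdc_bistable_traj):
        final = acdc_bistable_traj.y[-1]
        species = acdc_bistable_traj.species
        assert final[species.index("Y")] == pytest.approx(400.0, abs=8.0)
        assert final[species.index("X")] == pytest.approx(0.0, abs=5.0)
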
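"""Unit tests of the single-junction mechanochemical model."""

import dataclasses
import math

import numpy as np
import pytest

from mechanofeedback import model as M


@pytest.mark.parametrize("field,value", [
    ("friction_gamma", 0.0),
    ("turnover_tau", -1.0),
    ("rest_remodel_tau", 0.0),
    ("dt", 0.0),
    ("feedback_c", -0.5),
    ("noise_sigma", -0.1),
    ("contractile_saturation", 0.0),
])
def test_params_invariants_rejected(field, value):
    with pytest.raises(ValueError):
        M.ModelParams(**{field: value})


def test_infinite_turnover_allowed():
    p = M.ModelParams(turnover_tau=math.inf)
    assert p.turnover_tau == math.inf


class TestStep:
    def test_force_balance_is_fixed_point(self, quiet_params, balanced_state,
                                          balanced_tension):
        after = M.step(balanced_state, quiet_params, balanced_tension)
        assert after.time == pytest.approx(balanced_state.time
                                           + quiet_params.dt)
        assert after.length == balanced_state.length
        assert after.myosin_density == balanced_state.myosin_density
        assert after.rest_length == balanced_state.rest_length
        assert after.target_density == balanced_state.target_density

    def test_dilution_conserves_total_myosin(self, quiet_params):
        p = dataclasses.replace(quiet_params, turnover_tau=math.inf)
        state = M.JunctionState(0.0, 11.0, 10.0, 1.3, 1.0)
        after = M.step(state, p, t_ext=25.0)
        before_mass = state.length * state.myosin_density
        after_mass = after.length * after.myosin_density
        assert after_mass == pytest.approx(before_mass, rel=1e-14)

    def test_extension_raises_target_density_with_feedback(self, quiet_params):
        p = dataclasses.replace(quiet_params, feedback_enabled=True,
                                turnover_tau=math.inf)
        state = M.default_state(p)
        t_ext = M.fixed_point_tension(p, state) + 5.0   # net pull
        after = M.step(state, p, t_ext)
        assert after.length > state.length
        assert after.target_density > state.target_density

    def test_nonfinite_state_rejected(self, quiet_params):
        state = M.JunctionState(0.0, 10.0, 10.0, 1.0, 1.0)
        with pytest.raises(ValueError, match="non-finite"):
            M.step(state, quiet_params, t_ext=math.nan)

    def test_length_collapse_advises_smaller_dt(self, quiet_params):
        p = dataclasses.replace(quiet_params, dt=50.0)
        state = M.JunctionState(0.0, 1.0, 10.0, 4.0, 1.0)
        with pytest.raises(FloatingPointError, match="reduce dt"):
            M.step(state, p, t_ext=0.0)


class TestSimulate:
    def test_fixed_point_gives_constant_trace(self, quiet_params,
                                              balanced_state,
                                              balanced_tension):
        tr = M.simulate(quiet_params,
                        M.TensionProtocol.constant(balanced_tension),
                        duration=20.0, initial=balanced_state)
        assert tr.times.size == int(20.0 / quiet_params.dt) + 1
        assert np.all(tr.length == balanced_state.length)
        assert np.all(tr.myosin_density == balanced_state.myosin_density)

    def test_seed_determinism_bitwise(self):
        p = M.ModelParams()
        prot = M.TensionProtocol.constant(20.5)
        a = M.simulate(p, prot, 60.0, seed=42)
        b = M.simulate(p, prot, 60.0, seed=42)
        assert np.array_equal(a.myosin_density, b.myosin_density)
        assert np.array_equal(a.length, b.length)
        c = M.simulate(p, prot, 60.0, seed=43)
        assert not np.array_equal(a.myosin_density, c.myosin_density)

    def test_first_step_matches_step_function(self, quiet_params):
        state = M.JunctionState(0.0, 10.4, 10.0, 1.1, 1.0)
        prot = M.TensionProtocol.constant(22.0)
        tr = M.simulate(quiet_params, prot, 1.0, initial=state)
        manual = M.step(state, quiet_params, 22.0)
        assert tr.length[1] == pytest.approx(manual.length, rel=1e-15)
        assert tr.myosin_density[1] == pytest.approx(manual.myosin_density,
                                                     rel=1e-15)

    def test_feedback_power_law_under_tension_step(self):
        p = M.ModelParams(noise_sigma=0.0, turnover_tau=math.inf,
                          feedback_c=0.8, feedback_enabled=True,
                          remodeling_enabled=False)
        state = M.default_state(p)
        base = M.fixed_point_tension(p, state)
        prot = M.TensionProtocol.step(10.0, base, base + 4.0)
        tr = M.simulate(p, prot, 400.0, initial=state)
        fold = tr.length[-1] / tr.length[0]
        assert fold > 1.05  # the step actually extends the edge
        expected = tr.target_density[0] * fold ** p.feedback_c
        assert tr.target_density[-1] == pytest.approx(expected, rel=1e-2)

    def test_duration_shorter_than_dt_rejected(self, quiet_params):
        with pytest.raises(ValueError):
            M.simulate(quiet_params, M.TensionProtocol.constant(1.0),
                       duration=quiet_params.dt / 2)


class TestLinearStability:
    def test_no_contractility_relaxes_without_oscillation(self):
        p = M.ModelParams(contractility_beta=0.0, noise_sigma=0.0)
        res = M.linear_stability(p, t_ext=0.0)
        assert not res.oscillatory
        assert not res.unstable
        assert all(ev.real < 0 for ev in res.eigenvalues)

    def test_time_constant_scaling_scales_period(self, quiet_params):
        res1 = M.linear_stability(quiet_params, t_ext=19.6)
        scaled = dataclasses.replace(
            quiet_params,
            friction_gamma=quiet_params.friction_gamma * 3.0,
            turnover_tau=quiet_params.turnover_tau * 3.0,
        )
        res3 = M.linear_stability(scaled, t_ext=19.6)
        assert res3.period == pytest.approx(3.0 * res1.period, rel=1e-9)

    def test_out_of_range_fixed_point_raises(self, quiet_params):
        with pytest.raises(ValueError, match="no admissible fixed point"):
            M.linear_stability(quiet_params, t_ext=1e6)

    def test_fixed_point_is_stationary_when_stable(self):
        p = M.ModelParams(contractility_beta=30.0, noise_sigma=0.0,
                          feedback_enabled=False, remodeling_enabled=False)
        state = M.default_state(p)
        tension = M.fixed_point_tension(p, state)
        res = M.linear_stability(p, tension)
        assert max(ev.real for ev in res.eigenvalues) < 0
        tr = M.simulate(p, M.TensionProtocol.constant(tension),
                        duration=1e4 * p.dt, initial=state)
        assert np.max(np.abs(tr.length - state.length)) < 1e-8
        assert np.max(np.abs(tr.myosin_density
                             - state.myosin_density)) < 1e-8


class TestEnsemble:
    def test_single_run_equals_simulate_with_derived_seed(self):
        p = M.ModelParams()
        prot = M.TensionProtocol.constant(20.5)
        (tr,) = M.ensemble_simulate(p, prot, n_runs=1, duration=30.0, seed=7)
        derived = int(np.random.SeedSequence(7).generate_state(1)[0])
        ref = M.simulate(p, prot, 30.0, seed=derived)
        assert np.array_equal(tr.myosin_density, ref.myosin_density)

    def test_noise_free_runs_identical(self, quiet_params, balanced_state,
                                       balanced_tension):
        traces = M.ensemble_simulate(
            quiet_params, M.TensionProtocol.constant(balanced_tension),
            n_runs=3, duration=10.0, initial=balanced_state, seed=0)
        for tr in traces[1:]:
            assert np.array_equal(tr.length, traces[0].length)

    def test_run_i_independent_of_ensemble_size(self):
        p = M.ModelParams()
        prot = M.TensionProtocol.constant(20.5)
        small = M.ensemble_simulate(p, prot, 2, 10.0, seed=5)
        large = M.ensemble_simulate(p, prot, 4, 10.0, seed=5)
        assert np.array_equal(small[1].myosin_density,
                              large[1].myosin_density)


def test_tension_protocols_evaluate_piecewise():
    step = M.TensionProtocol.step(5.0, 1.0, 3.0)
    assert step(4.9) == 1.0 and step(5.1) == 3.0
    ramp = M.TensionProtocol.ramp(0.0, 10.0, 0.0, 10.0)
    assert ramp(5.0) == pytest.approx(5.0)
    assert ramp(-1.0) == 0.0 and ramp(11.0) == 10.0
    with pytest.raises(ValueError):
        M.TensionProtocol.ramp(5.0, 5.0, 0.0, 1.0)


def test_hopf_threshold_separates_regimes(quiet_params):
    beta_c = M.hopf_contractility(quiet_params)
    below = dataclasses.replace(quiet_params, contractility_beta=0.95 * beta_c)
    above = dataclasses.replace(quiet_params, contractility_beta=1.05 * beta_c)
    t_below = M.active_tension(below, below.baseline_density)
    t_above = M.active_tension(above, above.baseline_density)
    assert not M.linear_stability(below, t_below).unstable
    assert M.linear_stability(above, t_above).unstable
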
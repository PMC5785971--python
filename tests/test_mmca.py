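import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duplexsis import (
    EpidemicParams,
    MeanFieldConfig,
    MeanFieldState,
    MultiplexNetwork,
    NodeProbabilityState,
    infection_pressure,
    make_random_regular,
    make_random_regular_multiplex,
    recovery_probability,
    run,
    step,
    step_mf,
)


class TestRecoveryProbability:
    def test_zero_prevalence_gives_certain_recovery(self):
        assert recovery_probability(0.0, 0.5) == 1.0

    def test_closed_form(self):
        assert recovery_probability(0.1, 0.1) == pytest.approx(math.exp(-1), abs=1e-12)
        assert recovery_probability(0.3, 0.6, c=2.0) == pytest.approx(
            math.exp(-1), abs=1e-12
        )

    def test_no_resource_means_no_recovery(self):
        assert recovery_probability(0.3, 0.0) == 0.0

    def test_monotonicity(self):
        rho = np.linspace(0, 1, 50)
        values = recovery_probability(rho, 0.4)
        assert np.all(np.diff(values) <= 0)
        res = np.linspace(0.01, 1, 50)
        values = recovery_probability(0.3, res)
        assert np.all(np.diff(values) >= 0)

    @pytest.mark.parametrize("rho,res", [(-0.1, 0.5), (1.1, 0.5), (0.5, -0.1), (0.5, 2.0)])
    def test_out_of_range_rejected(self, rho, res):
        with pytest.raises(ValueError):
            recovery_probability(rho, res)


class TestInfectionPressure:
    def test_zero_transmission_gives_unit_escape(self, small_multiplex):
        params = EpidemicParams(0.0, 0.0, 0.1, 0.1, 0.5)
        state = NodeProbabilityState.uniform(small_multiplex.n_nodes, 0.3, 0.3)
        pressure = infection_pressure(state, small_multiplex, params)
        assert np.all(pressure.q1 == 1.0)
        assert np.all(pressure.q2 == 1.0)

    def test_uninfected_neighbours_give_unit_escape(self, small_multiplex, default_params):
        state = NodeProbabilityState.uniform(small_multiplex.n_nodes, 0.0, 0.0)
        pressure = infection_pressure(state, small_multiplex, default_params)
        assert np.all(pressure.q1 == 1.0)

    def test_regular_uniform_closed_form(self):
        net = make_random_regular_multiplex(100, 30, 30, seed=1)
        params = EpidemicParams(0.02, 0.02, 0.0, 0.0, 0.5)
        state = NodeProbabilityState.uniform(100, 0.1, 0.1)
        pressure = infection_pressure(state, net, params)
        expected = (1 - 0.02 * 0.1) ** 30  # 0.998**30
        assert pressure.q1 == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.941708, abs=1e-6)

    def test_dimension_mismatch_rejected(self, small_multiplex, default_params):
        state = NodeProbabilityState.uniform(3, 0.1, 0.1)
        with pytest.raises(ValueError, match="nodes"):
            infection_pressure(state, small_multiplex, default_params)


class TestStep:
    def test_disease_free_state_is_absorbing(self, small_multiplex, default_params):
        state = NodeProbabilityState.uniform(small_multiplex.n_nodes, 0.0, 0.0)
        new = step(state, small_multiplex, default_params)
        assert np.all(new.p1 == 0.0) and np.all(new.p2 == 0.0)

    @pytest.mark.parametrize("resource", [0.05, 0.2, 0.9])
    def test_pure_recovery_decay(self, small_multiplex, resource):
        params = EpidemicParams(0.0, 0.0, 0.0, 0.0, resource)
        state = NodeProbabilityState.uniform(small_multiplex.n_nodes, 0.1, 0.1)
        new = step(state, small_multiplex, params)
        expected = (1 - math.exp(-0.1 / resource)) * 0.1
        assert new.p1 == pytest.approx(expected, abs=1e-12)

    def test_uniform_regular_step_matches_mean_field(self):
        net = make_random_regular_multiplex(120, 30, 30, seed=9)
        params = EpidemicParams(0.02, 0.02, 0.08, 0.08, 0.2)
        config = MeanFieldConfig(params=params, k1=30, k2=30)
        state = NodeProbabilityState.uniform(120, 0.1, 0.1)
        mf = MeanFieldState(0.1, 0.1)
        for _ in range(100):
            state = step(state, net, params)
            mf = step_mf(mf, config)
            assert np.max(np.abs(state.p1 - mf.rho1)) < 1e-12
            assert np.max(np.abs(state.p2 - mf.rho2)) < 1e-12

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        beta=st.floats(0, 1),
        gamma=st.floats(0, 1),
        resource=st.floats(0, 1),
        p0=st.floats(0, 1),
    )
    def test_probabilities_stay_in_unit_interval(self, beta, gamma, resource, p0):
        net = make_random_regular_multiplex(30, 4, 6, seed=0)
        params = EpidemicParams(beta, beta, gamma, gamma, resource)
        state = NodeProbabilityState.uniform(30, p0, p0)
        for _ in range(30):
            state = step(state, net, params)
            assert np.all((state.p1 >= 0) & (state.p1 <= 1))
            assert np.all((state.p2 >= 0) & (state.p2 <= 1))


class TestRun:
    def test_zero_initial_state_converges_immediately(self, small_multiplex, default_params):
        trajectory, state = run(small_multiplex, default_params, 0.0, 0.0, max_steps=10)
        assert trajectory.converged
        assert trajectory.n_steps == 1
        assert trajectory.final == (0.0, 0.0)

    def test_si_limit_saturates(self):
        net = make_random_regular_multiplex(200, 30, 30, seed=4)
        params = EpidemicParams(0.02, 0.02, 0.08, 0.08, 0.0)
        trajectory, _ = run(net, params, 0.1, 0.1, max_steps=2000)
        assert trajectory.converged
        assert trajectory.final[0] == pytest.approx(1.0, abs=1e-6)

    def test_layer_swap_symmetry(self):
        layer_a = make_random_regular(80, 4, seed=1)
        layer_b = make_random_regular(80, 8, seed=2)
        params = EpidemicParams(0.05, 0.02, 0.03, 0.09, 0.3)
        t_ab, _ = run(
            MultiplexNetwork(layer_a, layer_b), params, 0.2, 0.05, max_steps=200
        )
        t_ba, _ = run(
            MultiplexNetwork(layer_b, layer_a), params.swap_layers(), 0.05, 0.2,
            max_steps=200,
        )
        assert np.array_equal(t_ab.rho1_series, t_ba.rho2_series)
        assert np.array_equal(t_ab.rho2_series, t_ba.rho1_series)

    def test_decoupled_layers_evolve_independently(self):
        layer_a = make_random_regular(60, 4, seed=1)
        layer_b = make_random_regular(60, 6, seed=2)
        layer_c = make_random_regular(60, 8, seed=3)
        params = EpidemicParams(0.1, 0.1, 0.0, 0.0, 0.3)
        t1, _ = run(MultiplexNetwork(layer_a, layer_b), params, 0.1, 0.5, max_steps=150)
        t2, _ = run(MultiplexNetwork(layer_a, layer_c), params, 0.1, 0.9, max_steps=150)
        n = min(t1.n_steps, t2.n_steps)
        assert np.array_equal(t1.rho1_series[: n + 1], t2.rho1_series[: n + 1])

    def test_trajectory_export_columns(self, small_multiplex, default_params, tmp_path):
        trajectory, _ = run(small_multiplex, default_params, 0.1, 0.1, max_steps=20)
        path = tmp_path / "trajectory.csv"
        trajectory.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "t,rho1,rho2,mu1,mu2"
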
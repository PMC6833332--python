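"""Core compartment model: ladders, derivatives, integration, doublings."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import replisen as rs
from replisen.errors import IntegrationError, ParameterError
from replisen.model import PopulationState, transition_matrix


def zero_exit_params(n_ages=10, div=0.0):
    return rs.ModelParameters.from_endpoints(
        div=(div, div), sen=(0, 0), arr=(0, 0), apo=(0, 0), m_GS=0, m_AD=0, n_ages=n_ages
    )


class TestRateLadder:
    @pytest.mark.parametrize(
        "first,last,n,checks",
        [
            (0.0259, 0.0063, 50, {0: 0.0259, 49: 0.0063}),
            (0.002, 0.002, 50, {i: 0.002 for i in range(0, 50, 7)}),
            (0.0, 0.01, 11, {0: 0.0, 5: 0.005, 10: 0.01}),
        ],
    )
    def test_endpoints_and_linearity(self, first, last, n, checks):
        ladder = rs.linear_rate_ladder(first, last, n)
        assert ladder.shape == (n,)
        for i, v in checks.items():
            assert ladder[i] == pytest.approx(v, abs=1e-15)
        # every entry on the straight line through the endpoints
        i = np.arange(n)
        expected = first + i * (last - first) / (n - 1)
        np.testing.assert_allclose(ladder, expected, atol=1e-15)

    @pytest.mark.parametrize("args", [(-0.1, 0.01, 50), (0.01, -0.1, 50), (0.01, 0.01, 1)])
    def test_invalid_inputs_rejected(self, args):
        with pytest.raises(ParameterError):
            rs.linear_rate_ladder(*args)


class TestDerivative:
    def test_no_transitions_no_change(self):
        params = zero_exit_params()
        state = rs.PopulationState(P=np.linspace(1, 0.1, 10), G=0.5, A=0.4, S=0.3, D=0.2)
        rates = rs.derivative(state, params)
        assert np.all(rates.P == 0)
        assert rates.G == rates.A == rates.S == rates.D == 0

    def test_single_division_doubles_daughters(self):
        # one division removes the mother and adds two daughters downstream
        m = 0.03
        params = rs.ModelParameters(
            div_ladder=[m, 0.0], sen_ladder=[0, 0], arr_ladder=[0, 0],
            apo_ladder=[0, 0], m_GS=0, m_AD=0, n_ages=2,
        )
        rates = rs.derivative(rs.PopulationState(P=[1.0, 0.0]), params)
        assert rates.P[0] == pytest.approx(-m)
        assert rates.P[1] == pytest.approx(2 * m)

    def test_apoptotic_clearance_routes_to_dead_pool(self):
        params = rs.ModelParameters.from_endpoints(
            div=(0, 0), sen=(0, 0), arr=(0, 0), apo=(0, 0), m_GS=0, m_AD=0.0010, n_ages=3
        )
        rates = rs.derivative(rs.PopulationState(P=np.zeros(3), A=1.0), params)
        assert rates.A == pytest.approx(-0.0010)
        assert rates.D == pytest.approx(0.0010)
        assert np.all(rates.P == 0) and rates.G == 0 and rates.S == 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            rs.derivative(rs.PopulationState(P=np.ones(5)), zero_exit_params(10))

    @given(
        endpoints=st.lists(st.floats(0, 0.05), min_size=8, max_size=8),
        scalars=st.lists(st.floats(0, 0.05), min_size=2, max_size=2),
        n_ages=st.integers(2, 8),
        seed=st.integers(0, 10**6),
    )
    def test_source_accounting(self, endpoints, scalars, n_ages, seed):
        # total cell production rate (dead pool included) equals the mitosis
        # gain: d(sum P + G + A + S + D)/dt = sum_i div_i P_i
        e = endpoints
        params = rs.ModelParameters.from_endpoints(
            div=(e[0], e[1]), sen=(e[2], e[3]), arr=(e[4], e[5]), apo=(e[6], e[7]),
            m_GS=scalars[0], m_AD=scalars[1], n_ages=n_ages,
        )
        rng = np.random.default_rng(seed)
        state = rs.PopulationState(
            P=rng.random(n_ages), G=rng.random(), A=rng.random(), S=rng.random()
        )
        rates = rs.derivative(state, params)
        total_rate = rates.P.sum() + rates.G + rates.A + rates.S + rates.D
        expected = float(params.div_ladder @ state.P)
        assert total_rate == pytest.approx(expected, rel=1e-9, abs=1e-12)
        assert expected >= 0


class TestSimulate:
    def test_all_rates_zero_conserves_state(self):
        params = zero_exit_params()
        init = rs.PopulationState(P=np.linspace(1, 0.1, 10), G=0.3, A=0.2, S=0.1)
        traj = rs.simulate(params, 1000.0, np.linspace(0, 1000, 11), initial=init)
        assert np.abs(traj.states - traj.states[0]).max() < 1e-9
        np.testing.assert_allclose(traj.TP, init.live_total, rtol=1e-9)

    def test_conservation_without_division(self):
        # transitions only move cells between pools; only mitosis creates them
        params = rs.ModelParameters.from_endpoints(
            div=(0, 0), sen=(0.002, 0.005), arr=(0.001, 0.004), apo=(0.003, 0.001),
            m_GS=0.01, m_AD=0.02, n_ages=10,
        )
        init = rs.PopulationState(P=np.linspace(1, 0.1, 10), G=0.3, A=0.2, S=0.1, D=0.05)
        traj = rs.simulate(params, 2000.0, np.linspace(0, 2000, 21), initial=init)
        total = traj.states.sum(axis=1)
        np.testing.assert_allclose(total, total[0], rtol=1e-8)

    def test_two_compartment_closed_form(self):
        # N=1: P_0 divides straight into S; TP(t) = 2 - exp(-m t)
        m = 0.01
        params = rs.ModelParameters(
            div_ladder=[m], sen_ladder=[0.0], arr_ladder=[0.0], apo_ladder=[0.0],
            m_GS=0, m_AD=0, n_ages=1,
        )
        traj = rs.simulate(params, 500.0, np.linspace(0, 500, 51))
        exact = 2.0 - np.exp(-m * traj.times)
        np.testing.assert_allclose(traj.TP, exact, rtol=1e-6)

    def test_exponential_growth_limit(self):
        # no exits, constant division rate: TP = e^{mt} while the oldest
        # age class is (relatively) unpopulated
        m = 0.02
        params = zero_exit_params(n_ages=80, div=m)
        traj = rs.simulate(params, 1000.0, np.linspace(0, 1000, 21))
        assert traj.P[:, -1].max() / traj.TP[-1] < 1e-6
        np.testing.assert_allclose(traj.TP, np.exp(m * traj.times), rtol=1e-4)

    def test_nonnegativity_and_absorbing_senescence(self, ref, ref_trajectory):
        assert np.all(ref_trajectory.states >= -1e-9)
        assert np.all(np.diff(ref_trajectory.S) >= -1e-12)

    def test_terminal_state_reference_parameters(self, ref_trajectory):
        # after 5000 h only senescent and growth-arrested cells remain
        tp = ref_trajectory.TP[-1]
        assert ref_trajectory.P_total[-1] / tp < 0.01
        assert (ref_trajectory.S[-1] + ref_trajectory.G[-1]) / tp > 0.98

    def test_accuracy_contract_tolerance_halving(self, ref):
        params, _ = ref
        grid = np.linspace(0, 5000, 11)
        a = rs.simulate(params, 5000.0, grid, rtol=1e-8, atol=1e-10)
        b = rs.simulate(params, 5000.0, grid, rtol=5e-9, atol=5e-11)
        scale = np.abs(b.states).max(axis=1)
        rel = np.abs(a.states - b.states).max(axis=1) / scale
        assert rel.max() < 1e-6

    def test_adaptive_matches_fixed_step_rk4_oracle(self, ref):
        # independent classical RK4 at h = 0.01 h over the full window
        params, _ = ref
        grid = np.linspace(0, 5000, 11)
        traj = rs.simulate(params, 5000.0, grid)
        M = transition_matrix(params)
        h = 0.01
        x = PopulationState.seed(params.n_ages).to_vector()
        snaps = [x.copy()]
        next_idx = 1
        for k in range(1, int(round(5000 / h)) + 1):
            k1 = M @ x
            k2 = M @ (x + 0.5 * h * k1)
            k3 = M @ (x + 0.5 * h * k2)
            k4 = M @ (x + h * k3)
            x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            if next_idx < grid.size and abs(k * h - grid[next_idx]) < h / 2:
                snaps.append(x.copy())
                next_idx += 1
        snaps = np.array(snaps)
        rel = np.abs(traj.states - snaps).max(axis=1) / np.abs(snaps).max(axis=1)
        assert rel.max() < 1e-5

    def test_expm_propagator_matches_adaptive(self, ref):
        params, _ = ref
        grid = np.linspace(0, 2400, 16)
        a = rs.simulate(params, 2400.0, grid, method="adaptive")
        b = rs.simulate(params, 2400.0, grid, method="expm")
        rel = np.abs(a.states - b.states).max(axis=1) / np.abs(b.states).max(axis=1)
        assert rel.max() < 1e-7

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"t_end": -5.0},
            {"t_end": 100.0, "output_times": [0.0, 150.0]},
            {"t_end": 100.0, "output_times": [50.0, 10.0]},
            {"t_end": 100.0, "method": "simplex"},
        ],
    )
    def test_invalid_simulation_requests(self, ref, kwargs):
        params, _ = ref
        with pytest.raises(ParameterError):
            rs.simulate(params, **kwargs)

    def test_integration_failure_raises_with_time(self):
        # a near-overflow seed pushed through the doubling cascade leaves
        # the representable range mid-integration
        params = rs.ModelParameters.from_endpoints(
            div=(1.0, 1.0), sen=(0, 0), arr=(0, 0), apo=(0, 0),
            m_GS=0, m_AD=0, n_ages=50,
        )
        seed = rs.PopulationState.seed(50, total=1e300)
        with pytest.raises(IntegrationError) as err:
            rs.simulate(params, 100.0, np.linspace(0, 100, 5), initial=seed)
        assert err.value.time is not None


class TestPopulationDoublings:
    def test_log2_of_fold_change(self):
        times = np.array([0.0, 1.0, 2.0])
        states = np.zeros((3, 6))
        states[:, 0] = [1.0, 1.0, 8.0]
        traj = rs.Trajectory(times=times, states=states, n_ages=2)
        np.testing.assert_allclose(rs.population_doublings(traj), [0.0, 0.0, 3.0])

    def test_pure_exponential_rate(self):
        # net growth m per hour gives PD(t) = m t / ln 2
        m = 0.02
        traj = rs.simulate(zero_exit_params(80, div=m), 1000.0, np.linspace(0, 1000, 21))
        np.testing.assert_allclose(
            rs.population_doublings(traj), m * traj.times / np.log(2), rtol=1e-4
        )

    def test_zero_initial_population_rejected(self):
        traj = rs.Trajectory(times=np.array([0.0, 1.0]), states=np.zeros((2, 6)), n_ages=2)
        with pytest.raises(ParameterError):
            rs.population_doublings(traj)

    def test_dead_pool_excluded_from_live_total(self):
        states = np.zeros((2, 6))
        states[0] = [1, 0, 0, 0, 0, 0]
        states[1] = [0, 0, 0, 0, 1, 5]  # all live mass senescent, large dead pool
        traj = rs.Trajectory(times=np.array([0.0, 1.0]), states=states, n_ages=2)
        np.testing.assert_allclose(traj.TP, [1.0, 1.0])
        np.testing.assert_allclose(rs.population_doublings(traj), [0.0, 0.0])


def test_trajectory_export_table(ref_trajectory):
    frame = ref_trajectory.to_frame()
    assert list(frame.columns) == ["time_h", "P_total", "G", "A", "S", "D", "TP", "PD"]
    np.testing.assert_allclose(frame["TP"], frame[["P_total", "G", "A", "S"]].sum(axis=1))
    assert frame["PD"].iloc[0] == 0.0
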
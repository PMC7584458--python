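import numpy as np
import pytest

from proteonet.equilibria import stationary_states
from proteonet.graphs import ConnectomeGraph, cubic_lattice
from proteonet.netsim import (
    Seed,
    StateVector,
    Trajectory,
    homogeneous_simulate,
    initial_condition,
    resolve_nodes,
    rhs,
    simulate,
)
from proteonet.params import DamageParams


def uniform_state(graph, values, q=0.0):
    u, ut, v, vt = values
    n = graph.n_nodes
    return StateVector(
        u=np.full(n, u), ut=np.full(n, ut), v=np.full(n, v),
        vt=np.full(n, vt), q=np.full(n, q),
    )


class TestInitialCondition:
    def test_no_seeds_everywhere_healthy(self, small_lattice, table1):
        s = initial_condition(small_lattice, table1)
        assert np.all(s.u == 0.75) and np.all(s.v == 0.5)
        assert not s.ut.any() and not s.vt.any() and not s.q.any()

    def test_coordinate_seed_selects_planes(self, table1):
        g = cubic_lattice(30, 6, 3)
        s = initial_condition(
            g, table1, [Seed(lambda lab, c: c[0] <= 4, "ut", 0.05)]
        )
        assert (s.ut == 0.05).sum() == 90  # 5 planes x 18 nodes
        assert (s.ut == 0).sum() == 450

    def test_zero_amount_seed_is_identity(self, small_lattice, table1):
        s0 = initial_condition(small_lattice, table1)
        s1 = initial_condition(small_lattice, table1, [Seed([0, 1], "vt", 0.0)])
        assert np.array_equal(s0.vt, s1.vt)

    def test_set_mode_overwrites(self, small_lattice, table1):
        s = initial_condition(small_lattice, table1, [Seed([2], "u", 0.1, mode="set")])
        assert s.u[2] == 0.1 and s.u[0] == 0.75

    def test_label_selector_and_empty_selector_error(self, small_lattice, table1):
        assert resolve_nodes(small_lattice, "2,1,0") == [
            small_lattice.labels.index("2,1,0")
        ]
        with pytest.raises(ValueError, match="no node"):
            initial_condition(small_lattice, table1, [Seed("not-a-label", "ut", 0.1)])

    def test_per_node_params_set_local_healthy_state(self, table1):
        g = cubic_lattice(3, 1, 1)
        per_node = [table1, table1.replace(a0=1.5), table1]
        s = initial_condition(g, per_node)
        assert s.u[1] == pytest.approx(1.5) and s.u[0] == pytest.approx(0.75)


class TestRhs:
    def test_homogeneous_healthy_state_is_stationary(self, small_lattice, table1):
        eq = stationary_states(table1)
        d = rhs(small_lattice, table1, None, uniform_state(small_lattice, eq[1]))
        for arr in (d.u, d.ut, d.v, d.vt):
            assert np.abs(arr).max() <= 1e-12

    def test_matches_homogeneous_rhs_at_uniform_state(self, small_lattice, table1):
        from proteonet.equilibria import homogeneous_rhs

        state = (0.7, 0.1, 0.45, 0.2)
        d = rhs(small_lattice, table1, None, uniform_state(small_lattice, state))
        expected = homogeneous_rhs(table1, state)
        for arr, want in zip((d.u, d.ut, d.v, d.vt), expected):
            assert np.abs(arr - want).max() <= 1e-12

    def test_single_node_hand_value(self, table1):
        g = cubic_lattice(1, 1, 1)
        s = StateVector(u=[0.75], ut=[0.05], v=[0.5], vt=[0.0], q=[0.0])
        d = rhs(g, table1, None, s)
        assert d.u[0] == pytest.approx(-0.0375)  # a0 - a1*u - a2*u*ut
        assert d.ut[0] == pytest.approx(-0.6 * 0.05 + 0.75 * 0.05)

    def test_saturated_damage_stops(self, small_lattice, table1):
        s = uniform_state(small_lattice, (0.6, 0.25, 0.32, 0.45), q=1.0)
        d = rhs(small_lattice, table1, DamageParams(), s)
        assert np.abs(d.q).max() == 0.0

    def test_damage_neighbor_sum_uses_damage_adjacency(self, table1):
        g = ConnectomeGraph(2, [(0, 1, 2.0, 4.0)])  # A_01 = 0.5, W_01 = 0.125
        s = StateVector(u=[0, 0], ut=[0, 0], v=[0, 0], vt=[0, 0], q=[0.0, 0.8])
        d = rhs(g, table1, DamageParams(k1=0, k2=0, k3=0, k4=2.0), s)
        assert d.q[0] == pytest.approx(2.0 * 0.5 * 0.8)


class TestSimulate:
    def test_first_state_equals_initial_condition(self, small_lattice, table1):
        init = initial_condition(small_lattice, table1, [Seed([0], "ut", 0.05)])
        traj = simulate(small_lattice, table1, None, init, 5.0, n_out=11)
        s0 = traj.state_at(0)
        assert np.array_equal(s0.ut, init.ut) and np.array_equal(s0.u, init.u)

    def test_homogeneity_preserved(self, table1, rng):
        """Uniform data on a connected graph reproduces the 1-node run."""
        g = cubic_lattice(4, 3, 2)
        init4 = (0.75, 0.01, 0.5, 0.01)
        t = np.linspace(0, 60, 61)
        ref = homogeneous_simulate(table1, init4, 60, t_eval=t)
        net = simulate(g, table1, None, uniform_state(g, init4), 60, t_eval=t)
        err = np.abs(net.data[:, :4, :] - ref.data[:, :4, :]).max()
        assert err <= 1e-8

    def test_terminal_state_matches_equilibria(self, table1):
        g = cubic_lattice(6, 2, 1)
        init = initial_condition(g, table1, [Seed([0], "ut", 0.05), Seed([0], "vt", 0.05)])
        traj = simulate(g, table1, None, init, 400.0)
        eq = stationary_states(table1)
        final = traj.final_state
        got = np.array([final.u, final.ut, final.v, final.vt])
        want = np.array(eq[4])[:, None]
        assert np.abs(got - want).max() <= 1e-6

    def test_positivity_maintained(self, small_lattice, table1):
        init = initial_condition(small_lattice, table1, [Seed([0], "ut", 0.05)])
        traj = simulate(small_lattice, table1, None, init, 100.0)
        assert traj.data[:, :4, :].min() >= -1e-9

    def test_secondary_without_amyloid_heals(self, secondary):
        """A pure toxic-tau seed decays in the secondary regime.

        The tau eigenvalue at the healthy state is b2*v1 - b1t = -0.025 < 0,
        so without toxic amyloid the perturbation relaxes (slowly) back."""
        traj = homogeneous_simulate(secondary, (0.75, 0.0, 0.5, 0.05), 800.0)
        final = traj.final_state
        assert final.vt[0] == pytest.approx(0.0, abs=1e-7)
        assert final.v[0] == pytest.approx(0.5, abs=1e-6)

    def test_damage_monotone_and_saturating(self, table1):
        g = cubic_lattice(3, 2, 1)
        init = initial_condition(g, table1, [Seed([0], "ut", 0.05), Seed([0], "vt", 0.05)])
        traj = simulate(g, table1, DamageParams(), init, 600.0, rtol=1e-8, atol=1e-10)
        q = traj.series("q")
        assert np.all(np.diff(q, axis=0) >= -1e-9)
        assert q[-1].min() > 0.99
        assert q.max() <= 1 + 1e-9

    def test_analytic_jacobian_matches_finite_differences(self, table1, rng):
        from proteonet.netsim import _System

        g = cubic_lattice(3, 2, 1)
        sys = _System(g, table1, DamageParams())
        y = np.concatenate([
            rng.uniform(0.0, 1.0, 4 * g.n_nodes),
            rng.uniform(0.0, 0.9, g.n_nodes),
        ])
        J = sys.jac(0.0, y).toarray()
        h = 1e-7
        num = np.zeros_like(J)
        for k in range(y.size):
            dp, dm = y.copy(), y.copy()
            dp[k] += h
            dm[k] -= h
            num[:, k] = (sys.rhs(0, dp) - sys.rhs(0, dm)) / (2 * h)
        assert np.abs(J - num).max() <= 1e-6

    def test_invalid_initial_condition_rejected(self, small_lattice, table1):
        init = initial_condition(small_lattice, table1)
        init.ut[0] = -0.5
        with pytest.raises(ValueError, match="negative"):
            simulate(small_lattice, table1, None, init, 1.0)


class TestHomogeneousSimulate:
    def test_exact_healthy_start_stays_constant(self, table1):
        eq = stationary_states(table1)
        traj = homogeneous_simulate(table1, eq[1], 50.0)
        assert np.abs(traj.data[:, :4, 0] - np.array(eq[1])).max() <= 1e-8

    def test_perturbed_primary_reaches_fully_toxic(self, table1):
        traj = homogeneous_simulate(table1, (0.75, 0.005, 0.5, 0.005), 300.0)
        final = traj.final_state
        assert final.vt[0] == pytest.approx(0.45, abs=1e-6)
        assert final.ut[0] == pytest.approx(0.25, abs=1e-6)

    def test_fig22_epsilon_perturbation_goes_fully_toxic(self, fig22):
        eq = stationary_states(fig22)
        u1, _, v1, _ = eq[1]
        traj = homogeneous_simulate(fig22, (u1, 0.005, v1, 0.005), 400.0)
        want = np.array(eq[4])
        got = traj.data[-1, :4, 0]
        assert np.abs(got - want).max() <= 1e-6


class TestTrajectory:
    def test_times_must_increase(self):
        with pytest.raises(ValueError):
            Trajectory(times=np.array([0.0, 0.0]), data=np.zeros((2, 5, 1)))

    def test_tidy_dataframe_shape(self, small_lattice, table1):
        init = initial_condition(small_lattice, table1)
        traj = simulate(small_lattice, table1, None, init, 1.0, n_out=5)
        df = traj.to_dataframe()
        assert len(df) == 5 * small_lattice.n_nodes
        assert set(df.columns) == {"time", "node", "u", "ut", "v", "vt", "q"}
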
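"""Transition matrices, RWR equilibria and the smoothing matrix."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import progeni as pg
from progeni.network import ConvergenceError

from conftest import random_network


class TestBuildTransition:
    def test_single_edge_column_normalization(self, two_node_net):
        B = pg.build_transition(two_node_net)
        assert np.allclose(B.B, [[0, 1], [1, 0]])

    def test_unit_triangle_splits_columns_evenly(self, triangle_net):
        B = pg.build_transition(triangle_net).B
        assert np.allclose(B.sum(axis=0), 1.0)
        assert np.allclose(B[B > 0], 0.5)

    def test_isolated_node_gets_uniform_column(self):
        net = pg.GeneNetwork(
            node_ids=["g1", "g2", "g3"],
            adjacency=np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]], dtype=float),
        )
        B = pg.build_transition(net).B
        assert np.allclose(B[:, 2], 1 / 3)
        assert np.allclose(B.sum(axis=0), 1.0)

    def test_empty_edge_list_rejected(self):
        with pytest.raises(ValueError, match="no nodes"):
            pg.GeneNetwork.from_edges([])

    def test_self_loops_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="self-loop"):
            net = pg.GeneNetwork.from_edges([("a", "a", 1.0), ("a", "b", 1.0)])
        assert net.n_nodes == 2
        assert net.adjacency[0, 0] == 0

    def test_duplicate_edges_keep_max_weight(self):
        with pytest.warns(UserWarning, match="duplicate"):
            net = pg.GeneNetwork.from_edges(
                [("a", "b", 0.3), ("b", "a", 0.7)]
            )
        assert net.adjacency[0, 1] == 0.7


class TestRwr:
    def test_single_node_fixed_point(self):
        net = pg.GeneNetwork(node_ids=["g"], adjacency=np.zeros((1, 1)))
        B = pg.build_transition(net)
        for p in (0.1, 0.5, 1.0):
            assert np.allclose(pg.rwr(B, np.array([1.0]), p=p).v, [1.0])

    def test_two_node_equilibrium_hand_solved(self, two_node_net):
        # v = 0.5 B v + 0.5 e1 with B = [[0,1],[1,0]] solves to [2/3, 1/3]
        B = pg.build_transition(two_node_net)
        v = pg.rwr(B, np.array([1.0, 0.0]), p=0.5).v
        assert np.allclose(v, [2 / 3, 1 / 3], atol=1e-8)

    def test_regular_graph_uniform_restart_gives_uniform_equilibrium(self):
        # cycle of 6 nodes is 2-regular
        edges = [(f"g{i}", f"g{(i + 1) % 6}", 1.0) for i in range(6)]
        B = pg.build_transition(pg.GeneNetwork.from_edges(edges))
        v = pg.rwr(B, np.full(6, 1 / 6), p=0.5).v
        assert np.allclose(v, 1 / 6, atol=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_iterative_matches_direct_solve(self, seed):
        net = random_network(seed)
        B = pg.build_transition(net)
        rng = np.random.default_rng(seed + 1)
        w = rng.random(net.n_nodes)
        w /= w.sum()
        v_it = pg.rwr(B, w, p=0.5, tol=1e-12).v
        v_dir = pg.rwr_direct(B, w, p=0.5).v
        assert np.max(np.abs(v_it - v_dir)) <= 1e-8

    def test_nonconvergence_carries_last_iterate(self, two_node_net):
        B = pg.build_transition(two_node_net)
        with pytest.raises(ConvergenceError) as err:
            pg.rwr(B, np.array([1.0, 0.0]), p=0.01, tol=1e-15, max_iter=3)
        assert err.value.last_iterate.shape == (2,)
        assert err.value.residual > 0

    def test_invalid_restart_probability(self, two_node_net):
        B = pg.build_transition(two_node_net)
        for p in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError, match="restart probability"):
                pg.rwr(B, np.array([1.0, 0.0]), p=p)

    def test_equilibrium_invariant_to_weight_scaling(self):
        edges = [("a", "b", 0.2), ("b", "c", 0.9), ("a", "c", 0.5)]
        scaled = [(u, v, 1000 * w) for u, v, w in edges]
        B1 = pg.build_transition(pg.GeneNetwork.from_edges(edges))
        B2 = pg.build_transition(pg.GeneNetwork.from_edges(scaled))
        w = np.array([0.5, 0.25, 0.25])
        assert np.allclose(
            pg.rwr_direct(B1, w, 0.5).v, pg.rwr_direct(B2, w, 0.5).v
        )

    def test_permutation_equivariance(self):
        net = random_network(42, n_max=50)
        B = pg.build_transition(net)
        rng = np.random.default_rng(0)
        w = rng.random(net.n_nodes)
        w /= w.sum()
        v = pg.rwr_direct(B, w, 0.5).v
        perm = rng.permutation(net.n_nodes)
        net_p = pg.GeneNetwork(
            node_ids=[net.node_ids[i] for i in perm],
            adjacency=net.adjacency[np.ix_(perm, perm)],
        )
        v_p = pg.rwr_direct(pg.build_transition(net_p), w[perm], 0.5).v
        assert np.allclose(v_p, v[perm], atol=1e-12)

    def test_total_variation_to_restart_shrinks_as_p_grows(self):
        net = random_network(3, n_max=60)
        B = pg.build_transition(net)
        w = np.zeros(net.n_nodes)
        w[0] = 1.0
        tv = [
            0.5 * np.abs(pg.rwr_direct(B, w, p).v - w).sum()
            for p in (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(tv, tv[1:]))
        assert tv[-1] == pytest.approx(0.0, abs=1e-12)


class TestSmoothingMatrix:
    def test_p_equal_one_gives_identity(self, triangle_net):
        V = pg.smoothing_matrix(triangle_net, ["g1", "g2", "g3"], p=1.0)
        assert np.allclose(V.V, np.eye(3))

    def test_columns_sum_to_one(self):
        net = random_network(11, n_max=80)
        expressed = net.node_ids[:: 2]  # half the genes
        V = pg.smoothing_matrix(net, expressed, p=0.5)
        assert V.n_shared == len(expressed)
        assert np.allclose(V.V.sum(axis=0), 1.0, atol=1e-10)

    def test_two_node_column_matches_rwr(self, two_node_net):
        V = pg.smoothing_matrix(two_node_net, ["g1", "g2"], p=0.5)
        assert np.allclose(V.V[:, 0], [2 / 3, 1 / 3])

    def test_no_overlap_is_an_error(self, two_node_net):
        with pytest.raises(ValueError, match="no overlap"):
            pg.smoothing_matrix(two_node_net, ["other"], p=0.5)


class TestGlobalEquilibrium:
    def test_regular_graph_is_uniform(self, triangle_net):
        B = pg.build_transition(triangle_net)
        assert np.allclose(pg.global_equilibrium(B, 0.5).v, 1 / 3)

    def test_equals_rwr_with_uniform_restart(self):
        net = random_network(5, n_max=40)
        B = pg.build_transition(net)
        w = np.full(net.n_nodes, 1 / net.n_nodes)
        assert np.allclose(
            pg.global_equilibrium(B, 0.5).v, pg.rwr_direct(B, w, 0.5).v
        )

    def test_star_graph_hub_exceeds_leaves_exact(self, star_net):
        # oracle: direct 4x4 linear solve of (I - 0.5 B) v = 0.5/4
        B = pg.build_transition(star_net)
        expected = np.linalg.solve(
            np.eye(4) - 0.5 * B.B, np.full(4, 0.5 / 4)
        )
        v = pg.global_equilibrium(B, 0.5).v
        assert np.allclose(v, expected, atol=1e-12)
        hub = star_net.node_ids.index("g0")
        assert all(v[hub] > v[i] for i in range(4) if i != hub)

    def test_cached_per_restart_probability(self, triangle_net):
        B = pg.build_transition(triangle_net)
        assert pg.global_equilibrium(B, 0.5) is pg.global_equilibrium(B, 0.5)


class TestEquilibriumProperties:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        p=st.floats(0.05, 1.0),
        restart_node=st.integers(0, 10**6),
    )
    def test_equilibrium_is_a_probability_distribution(self, seed, p, restart_node):
        net = random_network(seed, n_max=60)
        B = pg.build_transition(net)
        w = np.zeros(net.n_nodes)
        w[restart_node % net.n_nodes] = 1.0
        v = pg.rwr_direct(B, w, p).v
        assert (v >= -1e-12).all()
        assert v.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(pg.rwr(B, w, p, tol=1e-12).v, v, atol=1e-8)
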
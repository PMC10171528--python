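"""Graph-metric battery: closed forms, hand-derived cases, oracle spot checks
and invariance properties. The full 100-graph oracle sweep lives in the
acceptance suite; here each measure is exercised on targeted structures."""

import numpy as np
import pandas as pd
import pytest

import oracles
from connectopred import (
    ConnectomeMatrix,
    community_partition,
    core_periphery_size,
    edge_metrics,
    global_metrics,
    node_metrics,
    shortest_path_lengths,
    small_world_propensity,
    subject_metrics,
)
from connectopred.metrics import (
    ModulePartition,
    _delta,
    core_periphery_quality,
    modularity,
)


def conn(W):
    return ConnectomeMatrix(W=np.asarray(W, float), modality="SC")


def complete(n, w=1.0):
    return conn(w * (np.ones((n, n)) - np.eye(n)))


def star(n=5):
    W = np.zeros((n, n))
    W[0, 1:] = 1.0
    return conn(W + W.T)


def ring_lattice(n=20, k=2):
    W = np.zeros((n, n))
    for i in range(n):
        for d in range(1, k + 1):
            W[i, (i + d) % n] = 1.0
    return conn(np.maximum(W, W.T))


class TestDistances:
    def test_triangle_unit_weights(self):
        D = shortest_path_lengths(complete(3)).D
        assert np.allclose(D + np.eye(3), np.ones((3, 3)))

    def test_inverse_weight_path_sum(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[1, 2] = W[2, 1] = 0.5
        D = shortest_path_lengths(conn(W)).D
        assert D[0, 2] == pytest.approx(4.0)

    def test_disconnected_pairs_infinite(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        D = shortest_path_lengths(conn(W)).D
        assert np.isinf(D[0, 2]) and np.isinf(D[1, 3])
        assert D[0, 1] == 1.0


class TestCommunityPartition:
    def test_two_cliques_recovered(self):
        W = np.zeros((8, 8))
        W[:4, :4] = 1.0
        W[4:, 4:] = 1.0
        np.fill_diagonal(W, 0.0)
        W[3, 4] = W[4, 3] = 0.1
        part = community_partition(conn(W), seed=0)
        assert len(set(part.labels[:4])) == 1
        assert len(set(part.labels[4:])) == 1
        assert part.labels[0] != part.labels[7]
        # optimum confirmed by exhaustive 2-block search
        lab, q = oracles.best_two_block_modularity(W)
        assert part.Q == pytest.approx(q, abs=1e-9)

    def test_single_module_q_zero(self):
        W = complete(5).W
        assert modularity(W, np.zeros(5, dtype=int)) == pytest.approx(0.0)

    def test_relabelling_invariance(self, graph_factory):
        c = graph_factory(11, 10, 0.4)
        part = community_partition(c, seed=0)
        perm = np.random.default_rng(1).permutation(10)
        c2 = ConnectomeMatrix(W=c.W[np.ix_(perm, perm)], modality="SC")
        part2 = community_partition(c2, seed=0)
        # same groups after mapping back
        a = part.labels[perm]
        b = part2.labels
        pairs_a = (a[:, None] == a[None, :])
        pairs_b = (b[:, None] == b[None, :])
        assert np.array_equal(pairs_a, pairs_b)
        assert part.Q == pytest.approx(part2.Q, abs=1e-9)

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError):
            community_partition(conn(np.zeros((4, 4))), seed=0)


class TestNodeMetrics:
    def test_k4_closed_forms(self):
        c = complete(4)
        nd, _, gl = subject_metrics(c, seed=0)
        assert np.all(nd["node_degree"] == 3)
        assert np.all(nd["node_strength"] == 3)
        assert np.allclose(nd["clustering_coefficient"], 1.0)
        assert np.allclose(nd["node_eccentricity"], 1.0)
        assert gl["characteristic_path_length"] == pytest.approx(1.0)
        assert gl["global_efficiency"] == pytest.approx(1.0)
        assert gl["transitivity"] == pytest.approx(1.0)

    def test_star_betweenness(self):
        c = star(5)
        nd = node_metrics(
            c, shortest_path_lengths(c), community_partition(c, seed=0)
        )
        assert nd["betweenness_centrality"].iloc[0] == pytest.approx(6.0)
        assert np.allclose(nd["betweenness_centrality"].iloc[1:], 0.0)

    def test_participation_half_strength_in_two_modules(self):
        # node 0 splits its strength equally between two modules
        W = np.zeros((5, 5))
        W[0, 1] = W[1, 0] = 1.0
        W[0, 3] = W[3, 0] = 1.0
        W[1, 2] = W[2, 1] = 1.0
        W[3, 4] = W[4, 3] = 1.0
        labels = np.array([0, 0, 0, 1, 1])
        part = ModulePartition(labels=labels, Q=0.0)
        nd = node_metrics(conn(W), shortest_path_lengths(conn(W)), part)
        assert nd["participation_coefficient"].iloc[0] == pytest.approx(0.5)

    def test_isolated_node_sentinels(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[1, 2] = W[2, 1] = 1.0
        c = conn(W)
        nd = node_metrics(c, shortest_path_lengths(c), community_partition(c, 0))
        assert nd["node_degree"].iloc[3] == 0
        assert nd["clustering_coefficient"].iloc[3] == 0
        assert nd["participation_coefficient"].iloc[3] == 0
        assert np.isnan(nd["node_eccentricity"].iloc[3])

    def test_oracle_agreement_single_graph(self, graph_factory):
        c = graph_factory(42, 7, 0.5)
        W = c.W
        dist = shortest_path_lengths(c)
        part = community_partition(c, seed=0)
        nd = node_metrics(c, dist, part)
        D, paths = oracles.all_pairs(W)
        assert np.allclose(dist.D, D, atol=1e-9)
        assert np.allclose(nd["betweenness_centrality"], oracles.betweenness(W, paths), atol=1e-9)
        assert np.allclose(nd["clustering_coefficient"], oracles.onnela_clustering(W), atol=1e-9)
        assert np.allclose(nd["eigenvector_centrality"], oracles.eigenvector_centrality(W), atol=1e-9)
        assert np.allclose(nd["local_efficiency"], oracles.local_efficiency(W), atol=1e-9)
        assert np.allclose(nd["participation_coefficient"], oracles.participation(W, part.labels), atol=1e-9)


class TestEdgeMetrics:
    def test_path_edge_betweenness(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        W[1, 2] = W[2, 1] = 1.0
        c = conn(W)
        em = edge_metrics(c, shortest_path_lengths(c))
        assert em["edge_betweenness_centrality"][0, 1] == pytest.approx(2.0)

    def test_matching_index_extremes(self):
        # identical neighbourhoods (excluding each other) -> 1
        W = np.zeros((4, 4))
        W[0, 2] = W[2, 0] = 0.7
        W[1, 2] = W[2, 1] = 0.7
        W[0, 3] = W[3, 0] = 0.3
        W[1, 3] = W[3, 1] = 0.3
        c = conn(W)
        em = edge_metrics(c, shortest_path_lengths(c))
        assert em["matching_index"][0, 1] == pytest.approx(1.0)
        # nodes 2 and 3 share no neighbours' overlap? they both see 0 and 1
        # build a disjoint pair instead
        W2 = np.zeros((4, 4))
        W2[0, 2] = W2[2, 0] = 1.0
        W2[1, 3] = W2[3, 1] = 1.0
        c2 = conn(W2)
        em2 = edge_metrics(c2, shortest_path_lengths(c2))
        assert em2["matching_index"][0, 1] == 0.0

    def test_ranges_and_symmetry(self, graph_factory):
        c = graph_factory(7, 8, 0.5)
        em = edge_metrics(c, shortest_path_lengths(c))
        for name, M in em.items():
            assert np.allclose(M, M.T), name
        assert em["matching_index"].min() >= 0 and em["matching_index"].max() <= 1
        assert em["path_transitivity"].min() >= 0 and em["path_transitivity"].max() <= 1
        assert np.all(em["edge_betweenness_centrality"][c.W == 0] == 0)


class TestGlobalMetrics:
    def test_assortativity_nan_on_regular_graph(self):
        c = ring_lattice(12, 2)
        dist = shortest_path_lengths(c)
        part = community_partition(c, seed=0)
        gl = global_metrics(c, dist, part, swp=0.5, core_size=1)
        assert np.isnan(gl["assortativity"])

    def test_scale_invariance(self, graph_factory):
        c = graph_factory(13, 8, 0.6)
        c2 = ConnectomeMatrix(W=0.37 * c.W, modality="SC")
        part = community_partition(c, seed=0)
        nd = node_metrics(c, shortest_path_lengths(c), part)
        nd2 = node_metrics(c2, shortest_path_lengths(c2), part)
        assert np.array_equal(nd["node_degree"], nd2["node_degree"])
        assert np.allclose(nd2["node_strength"], 0.37 * nd["node_strength"])
        assert np.allclose(
            nd["participation_coefficient"], nd2["participation_coefficient"]
        )
        em = edge_metrics(c, shortest_path_lengths(c))
        em2 = edge_metrics(c2, shortest_path_lengths(c2))
        assert np.allclose(em["matching_index"], em2["matching_index"])
        assert oracles.assortativity(c.W) == pytest.approx(
            oracles.assortativity(c2.W), abs=1e-12
        )


class TestSmallWorldPropensity:
    def test_delta_guards_and_formula(self):
        assert _delta(0.0, 0.0) == 0.0
        assert _delta(1.0, 0.0) == 1.0
        assert _delta(-5.0, 2.0) == 0.0
        assert _delta(5.0, 2.0) == 1.0
        # dC = dL = 1 -> phi = 0; dC = dL = 0 -> phi = 1 (formula worst/best)
        assert 1 - np.sqrt((1 + 1) / 2) == pytest.approx(0.0)
        assert 1 - np.sqrt(0.0) == pytest.approx(1.0)

    def test_ring_lattice_phi_near_formula_value(self):
        phi = small_world_propensity(ring_lattice(24, 2), n_nulls=8, seed=3)
        # dC ~ 0 (lattice-like clustering), dL ~ 1 -> 1 - sqrt(1/2)
        assert phi == pytest.approx(1 - np.sqrt(0.5), abs=0.08)

    def test_bounded_and_deterministic(self, graph_factory):
        c = graph_factory(19, 12, 0.4)
        a = small_world_propensity(c, n_nulls=5, seed=7)
        b = small_world_propensity(c, n_nulls=5, seed=7)
        assert a == b
        assert 0.0 <= a <= 1.0


class TestCorePeriphery:
    def test_star_core_is_centre(self):
        assert core_periphery_size(star(5), seed=0) == 1
        sizes = oracles.exhaustive_core_sizes(star(5).W, core_periphery_quality)
        assert sizes == {1}

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_complete_graph_core_is_everything(self, n):
        assert core_periphery_size(complete(n), seed=0) == n
        sizes = oracles.exhaustive_core_sizes(
            complete(n).W, core_periphery_quality
        )
        assert n in sizes  # all-core ties the optimum on tied landscapes

    def test_matches_exhaustive_optimum(self, graph_factory):
        for seed in range(5):
            c = graph_factory(100 + seed, 7, 0.45)
            size = core_periphery_size(c, seed=1)
            sizes = oracles.exhaustive_core_sizes(c.W, core_periphery_quality)
            assert size in sizes

    def test_relabelling_invariance(self, graph_factory):
        c = graph_factory(55, 8, 0.5)
        perm = np.random.default_rng(2).permutation(8)
        c2 = ConnectomeMatrix(W=c.W[np.ix_(perm, perm)], modality="SC")
        assert core_periphery_size(c, seed=3) == core_periphery_size(c2, seed=3)
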
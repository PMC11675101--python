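import numpy as np
import pytest

from pmnet import (GroupGraph, ThresholdSpec, admit_graphs, aggregate_group,
                   apply_thresholds, characteristic_path_length,
                   clustering_coefficient, is_connected, small_worldness,
                   threshold_weights)
from pmnet.group import AdmissibilityRecord, maslov_sneppen_rewire
from pmnet.io import NormalizedConnectome
from conftest import random_symmetric_weights, random_connected_weights
from oracles import bfs_hop_distances, brute_force_clustering, \
    union_find_n_components


def sym(vals):
    W = np.asarray(vals, dtype=float)
    return (W + W.T) / 2 * 2 - W * 0 if False else W  # placeholder


def edge_graph(n, edges, weight=1.0):
    W = np.zeros((n, n))
    for u, v in edges:
        W[u, v] = W[v, u] = weight
    return W


class TestThresholdSpec:
    def test_default_yields_37_levels(self):
        assert len(ThresholdSpec().thresholds()) == 37

    def test_lo_equal_hi_minus_step_yields_two(self):
        assert len(ThresholdSpec(0.01, 0.0125, 0.0025).thresholds()) == 2

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            ThresholdSpec(lo=0.1, hi=0.01)


class TestAggregation:
    def _nc(self, roiset, W):
        return NormalizedConnectome(W, roiset)

    def test_single_subject_identity(self, toy_roiset, rng):
        W = random_symmetric_weights(rng, 5)
        group = aggregate_group([self._nc(toy_roiset, W)], "mean")
        np.testing.assert_array_equal(group.weights, W)

    def test_mean_of_two(self, toy_roiset):
        a = edge_graph(5, [(0, 2)], 0.2)
        b = edge_graph(5, [(0, 2)], 0.4)
        group = aggregate_group([self._nc(toy_roiset, a),
                                 self._nc(toy_roiset, b)], "mean")
        assert group.weights[0, 2] == pytest.approx(0.3)

    def test_mean_plus_2sd_matches_hand_formula(self, toy_roiset):
        # values 0.2 and 0.4: mean 0.3, sample SD sqrt(0.02)
        a = edge_graph(5, [(0, 2)], 0.2)
        b = edge_graph(5, [(0, 2)], 0.4)
        group = aggregate_group([self._nc(toy_roiset, a),
                                 self._nc(toy_roiset, b)], "mean_plus_2sd")
        expected = 0.3 + 2 * np.sqrt(0.02)
        assert group.weights[0, 2] == pytest.approx(expected)

    def test_mismatched_roisets_rejected(self, toy_roiset, atlas):
        with pytest.raises(ValueError, match="mismatch"):
            aggregate_group([
                self._nc(toy_roiset, np.zeros((5, 5))),
                self._nc(atlas, np.zeros((37, 37)))], "mean")


class TestThresholding:
    def _group(self, roiset, W):
        return GroupGraph(W, roiset, "mean")

    def test_boundary_weight_retained(self, toy_roiset):
        W = edge_graph(5, [(0, 1)], 0.005) + edge_graph(5, [(2, 3)], 0.02)
        out = threshold_weights(W, 0.01)
        assert np.count_nonzero(np.triu(out, 1)) == 1
        assert out[2, 3] == 0.02

    def test_edge_count_non_increasing_over_sweep(self, toy_roiset, rng):
        W = random_symmetric_weights(rng, 5) * 0.1
        graphs = apply_thresholds(self._group(toy_roiset, W))
        counts = [g.n_edges for g in graphs]
        assert counts == sorted(counts, reverse=True)

    def test_lo_equals_hi_yields_one_graph(self, toy_roiset, rng):
        W = random_symmetric_weights(rng, 5)
        spec = ThresholdSpec(0.01, 0.0100001, 0.0025)
        assert len(apply_thresholds(self._group(toy_roiset, W), spec)) == 1


class TestConnectedness:
    def test_path_graph_connected(self):
        W = edge_graph(5, [(0, 1), (1, 2), (2, 3), (3, 4)])
        assert is_connected(W)

    def test_isolated_node_disconnects(self):
        W = edge_graph(5, [(0, 1), (1, 2), (2, 3)])
        assert not is_connected(W)

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError):
            is_connected(np.zeros((0, 0)))

    def test_matches_union_find_oracle(self, rng):
        for _ in range(20):
            W = random_symmetric_weights(rng, 10, density=0.15)
            edges = [tuple(e) for e in np.argwhere(np.triu(W, 1) > 0)]
            expected = union_find_n_components(10, edges) == 1
            assert is_connected(W) == expected


class TestClusteringAndPathLength:
    def test_triangle_fully_clustered(self):
        C, _ = clustering_coefficient(edge_graph(3, [(0, 1), (1, 2), (0, 2)]))
        assert C == 1.0

    def test_star_has_zero_clustering(self):
        C, Ci = clustering_coefficient(
            edge_graph(5, [(0, i) for i in range(1, 5)]))
        assert C == 0.0
        assert np.all(Ci == 0)

    def test_matches_triangle_counting_brute_force(self, rng):
        for _ in range(10):
            W = random_symmetric_weights(rng, 12, density=0.4)
            C, _ = clustering_coefficient(W)
            assert C == pytest.approx(brute_force_clustering(W > 0), abs=1e-12)

    def test_complete_graph_unit_path_length(self):
        n = 6
        W = np.ones((n, n)) - np.eye(n)
        assert characteristic_path_length(W) == pytest.approx(1.0)

    def test_three_node_path(self):
        W = edge_graph(3, [(0, 1), (1, 2)])
        assert characteristic_path_length(W) == pytest.approx(4.0 / 3.0)

    def test_matches_bfs_oracle(self, rng):
        for _ in range(10):
            W = random_connected_weights(rng, 11, density=0.3)
            D = bfs_hop_distances(W > 0)
            off = ~np.eye(11, dtype=bool)
            assert characteristic_path_length(W) == pytest.approx(
                D[off].mean())

    def test_disconnected_path_length_errors(self):
        with pytest.raises(ValueError, match="disconnected"):
            characteristic_path_length(edge_graph(4, [(0, 1)]))


class TestSmallWorldness:
    def test_complete_graph_is_rewiring_invariant(self):
        W = np.ones((6, 6)) - np.eye(6)
        sw = small_worldness(W, n_null=5, seed=0)
        assert sw.C_rand == sw.C
        assert sw.L_rand == sw.L
        assert sw.S == pytest.approx(1.0)

    def test_ring_lattice_with_shortcuts_is_small_world(self):
        # Watts-Strogatz style: ring of 30 with 2 neighbors each side plus
        # a few shortcuts keeps C high while shortcuts shrink L
        n = 30
        W = np.zeros((n, n))
        for i in range(n):
            for d in (1, 2):
                W[i, (i + d) % n] = W[(i + d) % n, i] = 1.0
        for a, b in [(0, 15), (5, 20), (10, 25)]:
            W[a, b] = W[b, a] = 1.0
        sw = small_worldness(W, n_null=30, seed=3)
        assert sw.S > 1.0

    def test_rewiring_preserves_degree_sequence(self, rng):
        W = random_connected_weights(rng, 15, density=0.3)
        null = maslov_sneppen_rewire(W, np.random.default_rng(5))
        np.testing.assert_array_equal((null > 0).sum(axis=1),
                                      (W > 0).sum(axis=1))
        assert np.array_equal(null, null.T)
        assert np.all(np.diag(null) == 0)

    def test_deterministic_for_fixed_seed(self, rng):
        W = random_connected_weights(rng, 12, density=0.4)
        a = small_worldness(W, n_null=10, seed=42)
        b = small_worldness(W, n_null=10, seed=42)
        assert a.S == b.S and a.C_rand == b.C_rand

    def test_clustering_and_path_length_permutation_invariant(self, rng):
        W = random_connected_weights(rng, 12, density=0.4)
        perm = rng.permutation(12)
        Wp = W[np.ix_(perm, perm)]
        assert clustering_coefficient(W)[0] == pytest.approx(
            clustering_coefficient(Wp)[0])
        assert characteristic_path_length(W) == pytest.approx(
            characteristic_path_length(Wp))

    def test_disconnected_graph_rejected(self):
        with pytest.raises(ValueError, match="connected"):
            small_worldness(edge_graph(4, [(0, 1)]), n_null=2, seed=0)


class TestAdmission:
    def _record(self, connected, Q, S):
        admitted = connected and Q > 0.3 and S > 1
        return AdmissibilityRecord(0.01, connected, Q, 0, 0, 0, 0, S,
                                   admitted)

    def test_rule_table(self):
        assert self._record(True, 0.4, 1.2).admitted
        assert not self._record(True, 0.2, 1.5).admitted
        assert not self._record(False, 0.5, 2.0).admitted
        assert not self._record(True, 0.4, 0.9).admitted

    def test_admit_graphs_filters(self):
        records = [self._record(True, 0.4, 1.2), self._record(True, 0.2, 1.5)]
        admitted = admit_graphs(records)
        assert len(admitted) == 1 and admitted[0].Q == 0.4
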
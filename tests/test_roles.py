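import numpy as np
import pytest

from pmnet import (classify_stage1, classify_stage2, identify_peripheral,
                   node_betweenness, node_strength, participation_coefficient,
                   within_module_degree_z, ThresholdMetrics)
from pmnet.paths import weights_to_lengths
from conftest import random_connected_weights
from oracles import brute_force_betweenness


def edge_graph(n, edges):
    W = np.zeros((n, n))
    for u, v, w in edges:
        W[u, v] = W[v, u] = w
    return W


class TestParticipationCoefficient:
    def test_all_links_in_one_module_zero(self):
        W = edge_graph(4, [(0, 1, 1.0), (0, 2, 1.0)])
        aff = np.array([0, 0, 0, 1])
        assert participation_coefficient(W, aff)[0] == 0.0

    def test_equal_split_two_modules(self):
        W = edge_graph(3, [(0, 1, 1.0), (0, 2, 1.0)])
        aff = np.array([0, 0, 1])  # node 0 shares module with node 1
        # node 0: half its weight inside module 0, half in module 1
        assert participation_coefficient(W, aff)[0] == pytest.approx(0.5)

    @pytest.mark.parametrize("m", [3, 4, 5])
    def test_equal_split_m_modules_closed_form(self, m):
        # hub node 0 with one unit link into each of m modules
        n = m + 1
        W = edge_graph(n, [(0, i, 1.0) for i in range(1, n)])
        aff = np.concatenate([[m], np.arange(m)])
        y = participation_coefficient(W, aff)
        assert y[0] == pytest.approx(1.0 - 1.0 / m)

    def test_isolated_node_zero(self):
        W = edge_graph(3, [(0, 1, 1.0)])
        y = participation_coefficient(W, np.array([0, 0, 1]))
        assert y[2] == 0.0

    def test_range_invariant(self, rng):
        W = random_connected_weights(rng, 12)
        aff = rng.integers(0, 3, 12)
        y = participation_coefficient(W, aff)
        n_mod = len(np.unique(aff))
        assert np.all(y >= -1e-12)
        assert np.all(y <= 1 - 1.0 / n_mod + 1e-12)


class TestWithinModuleDegreeZ:
    def test_node_at_module_mean_zero(self):
        # module {0,1,2}: within-degrees 2,1,1 -> node 1 and 2 below mean
        W = edge_graph(4, [(0, 1, 1.0), (0, 2, 1.0)])
        aff = np.array([0, 0, 0, 1])
        z = within_module_degree_z(W, aff)
        assert z[0] > 0 > z[1]
        assert z[1] == z[2]

    def test_uniform_within_degrees_all_zero(self):
        W = edge_graph(3, [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0)])
        z = within_module_degree_z(W, np.zeros(3, dtype=int))
        np.testing.assert_array_equal(z, 0.0)

    def test_singleton_module_zero(self):
        W = edge_graph(3, [(0, 1, 1.0)])
        z = within_module_degree_z(W, np.array([0, 0, 1]))
        assert z[2] == 0.0

    def test_zero_mean_within_modules(self, rng):
        W = random_connected_weights(rng, 15)
        aff = rng.integers(0, 3, 15)
        z = within_module_degree_z(W, aff)
        for m in np.unique(aff):
            members = aff == m
            if members.sum() > 1 and z[members].std() > 0:
                assert z[members].mean() == pytest.approx(0.0, abs=1e-12)


class TestStrength:
    def test_sum_of_incident_weights(self):
        W = edge_graph(3, [(0, 1, 0.2), (0, 2, 0.3)])
        assert node_strength(W)[0] == pytest.approx(0.5)

    def test_isolated_zero(self):
        assert node_strength(np.zeros((3, 3)))[2] == 0.0

    def test_handshake_identity(self, rng):
        W = random_connected_weights(rng, 10)
        total_weight = np.triu(W, 1).sum()
        assert node_strength(W).sum() == pytest.approx(2 * total_weight)


class TestBetweenness:
    def test_star_center_unit(self):
        W = edge_graph(5, [(0, i, 1.0) for i in range(1, 5)])
        b = node_betweenness(W)
        assert b[0] == pytest.approx(1.0)
        np.testing.assert_allclose(b[1:], 0.0)

    def test_complete_graph_zero(self):
        W = np.ones((5, 5)) - np.eye(5)
        np.testing.assert_allclose(node_betweenness(W), 0.0)

    def test_degree_one_node_zero(self, rng):
        W = random_connected_weights(rng, 8)
        W[7, :] = W[:, 7] = 0.0
        W[7, 0] = W[0, 7] = 0.5
        assert node_betweenness(W)[7] == 0.0

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_matches_path_enumeration_oracle(self, seed):
        # integer lengths make equal-length ties exact for the oracle
        rng = np.random.default_rng(seed)
        n = 8
        lengths = np.full((n, n), np.inf)
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.45:
                    lengths[i, j] = lengths[j, i] = float(
                        rng.integers(1, 5))
        for a, b in zip(range(n), list(range(1, n)) + [0]):
            if np.isinf(lengths[a, b]):
                lengths[a, b] = lengths[b, a] = float(rng.integers(1, 5))
        W = np.where(np.isfinite(lengths), 1.0 / lengths, 0.0)
        np.fill_diagonal(W, 0.0)
        np.testing.assert_allclose(node_betweenness(W),
                                   brute_force_betweenness(lengths),
                                   atol=1e-10)


def metrics(threshold, y, z):
    y = np.asarray(y, dtype=float)
    return ThresholdMetrics(threshold, y, np.asarray(z, dtype=float),
                            np.zeros(len(y), dtype=int))


class TestStageOne:
    # 8 nodes; Q3 of [0..7] is 5.25, so only values > 5.25 pass
    base = np.arange(8.0)

    def test_pc_above_q3_at_both_endpoints_is_connector(self):
        y = self.base.copy()
        ms = [metrics(0.01, y, self.base), metrics(0.05, y, self.base)]
        hub_type, _ = classify_stage1(ms)
        assert hub_type[7] == "connector"

    def test_pc_above_q3_at_one_endpoint_only_is_nonhub(self):
        y_low = self.base.copy()
        y_high = self.base[::-1].copy()
        z = np.zeros(8)
        ms = [metrics(0.01, y_low, z), metrics(0.05, y_high, z)]
        hub_type, _ = classify_stage1(ms)
        assert hub_type[7] == "nonhub"

    def test_wmdz_above_q3_with_low_pc_is_provincial(self):
        y = np.zeros(8)
        ms = [metrics(0.01, y, self.base), metrics(0.05, y, self.base)]
        hub_type, _ = classify_stage1(ms)
        assert hub_type[7] == "provincial"

    def test_dual_qualification_prefers_connector(self):
        ms = [metrics(0.01, self.base, self.base),
              metrics(0.05, self.base, self.base)]
        hub_type, dual = classify_stage1(ms)
        assert hub_type[7] == "connector"
        assert dual[7]

    def test_intermediate_thresholds_ignored(self):
        y_mid = self.base[::-1].copy()
        ms = [metrics(0.01, self.base, np.zeros(8)),
              metrics(0.03, y_mid, np.zeros(8)),
              metrics(0.05, self.base, np.zeros(8))]
        hub_type, _ = classify_stage1(ms)
        assert hub_type[7] == "connector"

    def test_fewer_than_two_thresholds_errors(self):
        with pytest.raises(ValueError, match="2 admitted"):
            classify_stage1([metrics(0.01, self.base, self.base)])

    def test_quartile_cutoff_sanity(self, rng):
        values = rng.random(37)
        above = values > np.quantile(values, 0.75)
        assert above.sum() <= int(np.ceil(37 / 4))


class TestStageTwo:
    def test_fig2_mapping(self):
        hub_type = np.array(["connector"] * 4 + ["nonhub"] * 4)
        strength = np.array([10, 10, 1, 1, 5, 5, 5, 5.0])
        betweenness = np.array([10, 1, 10, 1, 5, 5, 5, 5.0])
        subtype = classify_stage2(hub_type, strength, betweenness)
        assert list(subtype[:4]) == ["rich_central", "rich",
                                     "poor_central", "poor"]
        assert set(subtype[4:]) == {"unclassified"}

    def test_every_hub_gets_exactly_one_subtype(self, rng):
        hub_type = np.array(["connector", "provincial", "nonhub"] * 4)
        strength = rng.random(12)
        betweenness = rng.random(12)
        subtype = classify_stage2(hub_type, strength, betweenness)
        hubs = hub_type != "nonhub"
        assert np.all(np.isin(subtype[hubs],
                              ["rich_central", "rich", "poor_central",
                               "poor"]))
        assert np.all(subtype[~hubs] == "unclassified")


class TestPeripheral:
    def test_nonhub_below_both_q1_is_peripheral(self):
        hub_type = np.array(["nonhub"] * 8)
        strength = np.arange(8.0) + 1
        betweenness = np.arange(8.0) + 1
        peripheral = identify_peripheral(hub_type, strength, betweenness)
        # Q1 of 1..8 is 2.75: nodes with value 1 and 2 are strictly below
        assert list(np.flatnonzero(peripheral)) == [0, 1]

    def test_hub_with_low_metrics_not_peripheral(self):
        hub_type = np.array(["connector"] + ["nonhub"] * 7)
        strength = np.arange(8.0) + 1
        betweenness = np.arange(8.0) + 1
        peripheral = identify_peripheral(hub_type, strength, betweenness)
        assert not peripheral[0]

    def test_requires_both_metrics_low(self):
        hub_type = np.array(["nonhub"] * 8)
        strength = np.arange(8.0) + 1
        betweenness = strength[::-1].copy()
        peripheral = identify_peripheral(hub_type, strength, betweenness)
        assert not peripheral.any()
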
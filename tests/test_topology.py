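import numpy as np
import pytest

from peptinet import topology as topo

from _oracles import (
    brute_betweenness,
    brute_closeness,
    brute_shortest_paths,
    random_signed_graph,
)
from conftest import make_multilayer, make_net


class TestStrengthAndInfluence:
    def test_strength_sums_absolute_weights(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.4
        W[0, 2] = W[2, 0] = -0.1
        assert topo.strength(make_net(W))[0] == pytest.approx(0.5)

    def test_expected_influence_keeps_signs(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.4
        W[0, 2] = W[2, 0] = -0.1
        ei = topo.expected_influence(make_net(W))
        assert ei[0] == pytest.approx(0.3)
        assert ei[2] == pytest.approx(-0.1)

    def test_isolated_node_has_zero_strength(self, triangle_net):
        W = np.zeros((4, 4))
        W[:3, :3] = triangle_net.W
        s = topo.strength(make_net(W))
        assert s[3] == 0

    def test_triangle_strengths(self, triangle_net):
        assert np.allclose(topo.strength(triangle_net), 0.4)

    def test_influence_equals_strength_on_positive_networks(self, rng):
        for _ in range(10):
            W = np.abs(random_signed_graph(rng, 6))
            net = make_net(W)
            assert np.allclose(topo.expected_influence(net), topo.strength(net))


class TestShortestPaths:
    def test_two_hop_path_adds_inverse_weights(self, path3_net):
        D = topo.shortest_path_lengths(path3_net)
        assert D[0, 2] == pytest.approx(4.0)  # 1/0.5 + 1/0.5

    def test_disconnected_pair_infinite(self):
        W = np.zeros((2, 2))
        assert np.isinf(topo.shortest_path_lengths(make_net(W))[0, 1])

    def test_single_edge_reciprocal(self):
        W = np.array([[0, 0.25], [0.25, 0]])
        assert topo.shortest_path_lengths(make_net(W))[0, 1] == pytest.approx(4.0)

    def test_matches_floyd_warshall_oracle(self, rng):
        for _ in range(10):
            W = random_signed_graph(rng, 7)
            assert np.allclose(topo.shortest_path_lengths(make_net(W)),
                               brute_shortest_paths(W))


class TestCloseness:
    def test_three_node_path_unit_lengths(self):
        W = np.array([[0, 1.0, 0], [1.0, 0, 1.0], [0, 1.0, 0]])
        c = topo.closeness(make_net(W))
        assert np.allclose(c, [1 / 3, 1 / 2, 1 / 3])

    def test_complete_graph_symmetry(self):
        W = np.full((4, 4), 0.5)
        np.fill_diagonal(W, 0)
        c = topo.closeness(make_net(W))
        assert np.allclose(c, 1.0 / (3 * 2.0))  # (p-1) neighbors at length 2

    def test_isolated_node_zero(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        assert topo.closeness(make_net(W))[2] == 0


class TestBetweenness:
    def test_middle_of_path_scores_one(self, path3_net):
        assert np.allclose(topo.betweenness(path3_net), [0, 1, 0])

    def test_four_cycle_ties_share_credit(self):
        W = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 2), (2, 3), (3, 0)]:
            W[i, j] = W[j, i] = 0.5
        assert np.allclose(topo.betweenness(make_net(W)), 0.5)

    def test_star_center_covers_all_pairs(self):
        W = np.zeros((5, 5))
        W[0, 1:] = W[1:, 0] = 0.3
        b = topo.betweenness(make_net(W))
        assert b[0] == pytest.approx(6.0)  # C(4, 2)
        assert np.allclose(b[1:], 0.0)


class TestHubs:
    def test_clear_outlier_flagged(self):
        b = np.array([0.0] * 9 + [30.0])
        assert list(topo.identify_hubs(b)) == [9]

    def test_moderate_outlier_below_two_sd_not_flagged(self):
        b = np.array([0.0, 0, 0, 0, 10.0])  # threshold mean + 2 sd = 10.94
        assert list(topo.identify_hubs(b)) == []

    def test_equal_betweenness_gives_no_hubs(self):
        assert list(topo.identify_hubs(np.full(5, 2.0))) == []

    def test_invariant_to_node_relabeling(self, rng):
        b = rng.random(12) * np.array([1] * 11 + [50])
        perm = rng.permutation(12)
        hubs = set(topo.identify_hubs(b))
        hubs_perm = set(perm[list(topo.identify_hubs(b[perm]))]) if len(hubs) else set()
        assert {int(i) for i in hubs_perm} == {int(i) for i in hubs}


class TestConnectivity:
    layers3 = ["synaptic_peptide", "synaptic_peptide", "pathological_peptide"]

    def test_global_sums_absolute_weights_once(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[1, 2] = W[2, 1] = -0.3
        W[0, 2] = W[2, 0] = 0.2
        assert topo.global_connectivity(make_net(W)) == pytest.approx(1.0)

    def test_empty_network_zero(self):
        assert topo.global_connectivity(make_net(np.zeros((4, 4)))) == 0

    def test_doubling_weights_doubles_connectivity(self, rng):
        W = random_signed_graph(rng, 6)
        assert topo.global_connectivity(make_net(2 * W)) == pytest.approx(
            2 * topo.global_connectivity(make_net(W))
        )

    def test_interlayer_single_cross_edge(self):
        W = np.zeros((3, 3))
        W[0, 2] = W[2, 0] = -0.4
        net = make_multilayer(W, self.layers3)
        assert topo.interlayer_connectivity(
            net, "synaptic_peptide", "pathological_peptide"
        ) == pytest.approx(0.4)

    def test_no_cross_edges_zero(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.9
        net = make_multilayer(W, self.layers3)
        assert topo.interlayer_connectivity(
            net, "synaptic_peptide", "pathological_peptide"
        ) == 0

    def test_layer_pairs_partition_global(self, rng):
        W = random_signed_graph(rng, 8)
        layers = (["synaptic_peptide"] * 3 + ["ppi_complex"] * 2
                  + ["pathological_peptide"] * 3)
        net = make_multilayer(W, layers)
        total = sum(topo.connectivity_by_layer_pair(net).values())
        assert total == pytest.approx(topo.global_connectivity(net))

    def test_unknown_layer_rejected(self):
        net = make_multilayer(np.zeros((2, 2)), ["synaptic_peptide"] * 2)
        with pytest.raises(KeyError):
            topo.interlayer_connectivity(net, "synaptic_peptide", "cellular_pathology")


class TestDiameter:
    def test_single_edge_hops(self):
        W = np.array([[0, 0.5], [0.5, 0]])
        assert topo.diameter(make_net(W), "hops") == 1

    def test_path_hops(self, path3_net):
        assert topo.diameter(path3_net, "hops") == 2

    def test_weighted_convention(self, path3_net):
        assert topo.diameter(path3_net) == pytest.approx(4.0)

    def test_unknown_convention_rejected(self, path3_net):
        with pytest.raises(ValueError):
            topo.diameter(path3_net, "parsecs")


class TestCentralityTable:
    def test_columns_and_hub_flag(self, rng):
        W = random_signed_graph(rng, 8, connected=True)
        net = make_multilayer(W, ["synaptic_peptide"] * 8)
        tab = topo.centrality_table(net)
        assert len(tab) == 8
        for col in ("strength", "closeness", "betweenness", "expected_influence"):
            assert col in tab.columns and f"{col}_z" in tab.columns
        z = tab["strength_z"]
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)


def test_centralities_match_bruteforce_on_random_graphs(rng):
    """Dijkstra/Brandes results agree with exhaustive path enumeration."""
    for _ in range(15):
        W = random_signed_graph(rng, 6, connected=True)
        net = make_net(W)
        assert np.allclose(topo.betweenness(net), brute_betweenness(W), atol=1e-9)
        assert np.allclose(topo.closeness(net), brute_closeness(W), atol=1e-12)
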
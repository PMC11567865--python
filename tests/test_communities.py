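import itertools

import numpy as np
import pytest

from peptinet.communities import (
    PartitionResult,
    module_attribute_anova,
    module_composition,
    signed_modularity,
    spinglass_hamiltonian,
    spinglass_partition,
    structural_equivalence,
    transitivity,
)

from _oracles import brute_transitivity, random_signed_graph
from conftest import make_net


def two_cliques_net(neg_bridge=-0.4):
    W = np.zeros((8, 8))
    for block in (range(4), range(4, 8)):
        for a, b in itertools.combinations(block, 2):
            W[a, b] = W[b, a] = 0.5
    W[0, 4] = W[4, 0] = neg_bridge
    return make_net(W)


class TestSpinglass:
    def test_two_positive_cliques_split_by_negative_bridge(self):
        net = two_cliques_net()
        for seed in range(3):
            part = spinglass_partition(net, seed=seed, n_restarts=5)
            labels = [part.assignment[f"n{i}"] for i in range(8)]
            assert part.K == 2
            assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
            assert labels[0] != labels[4]

    def test_uniform_positive_clique_is_one_module(self):
        W = np.full((6, 6), 0.4)
        np.fill_diagonal(W, 0)
        part = spinglass_partition(make_net(W), seed=0, n_restarts=5)
        assert part.K == 1

    def test_deterministic_given_seed(self):
        net = two_cliques_net()
        a = spinglass_partition(net, seed=11, n_restarts=3)
        b = spinglass_partition(net, seed=11, n_restarts=3)
        assert a.assignment == b.assignment
        assert a.hamiltonian == b.hamiltonian

    def test_energy_beats_trivial_partitions(self, rng):
        W = random_signed_graph(rng, 10, edge_prob=0.6, connected=True)
        net = make_net(W)
        part = spinglass_partition(net, seed=0, n_restarts=5)
        ids = [n.node_id for n in net.nodes]
        singletons = {nid: k + 1 for k, nid in enumerate(ids)}
        lumped = {nid: 1 for nid in ids}
        e = part.hamiltonian
        assert e <= spinglass_hamiltonian(net, singletons) + 1e-9
        assert e <= spinglass_hamiltonian(net, lumped) + 1e-9

    def test_module_labels_canonical_by_size(self):
        part = spinglass_partition(two_cliques_net(), seed=0, n_restarts=3)
        # equal sizes: module 1 must contain the smaller node index
        assert part.assignment["n0"] == 1

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="no edges"):
            spinglass_partition(make_net(np.zeros((4, 4))), seed=0)


class TestSignedModularity:
    def test_single_community_positive_graph_is_zero(self):
        W = np.full((5, 5), 0.3)
        np.fill_diagonal(W, 0)
        net = make_net(W)
        assignment = {f"n{i}": 1 for i in range(5)}
        assert signed_modularity(net, assignment) == pytest.approx(0.0)

    def test_two_disconnected_cliques_textbook_half(self):
        W = np.zeros((8, 8))
        for block in (range(4), range(4, 8)):
            for a, b in itertools.combinations(block, 2):
                W[a, b] = W[b, a] = 0.7
        net = make_net(W)
        assignment = {f"n{i}": 1 if i < 4 else 2 for i in range(8)}
        assert signed_modularity(net, assignment) == pytest.approx(0.5)

    def test_no_negative_edges_matches_igraph_newman(self, rng):
        import igraph

        W = np.abs(random_signed_graph(rng, 9, connected=True))
        net = make_net(W)
        labels = rng.integers(0, 3, size=9)
        assignment = {f"n{i}": int(l) + 1 for i, l in enumerate(labels)}
        ii, jj = np.nonzero(np.triu(W, k=1))
        g = igraph.Graph(9, list(zip(ii.tolist(), jj.tolist())))
        q_ref = g.modularity(labels.tolist(), weights=W[ii, jj].tolist())
        assert signed_modularity(net, assignment) == pytest.approx(q_ref, abs=1e-12)

    def test_random_assignment_near_zero(self, rng):
        qs = []
        for seed in range(20):
            local = np.random.default_rng(seed)
            W = random_signed_graph(local, 12, edge_prob=0.4)
            if np.abs(W).sum() == 0:
                continue
            net = make_net(W)
            labels = local.integers(1, 4, size=12)
            qs.append(signed_modularity(net, {f"n{i}": int(l) for i, l in enumerate(labels)}))
        assert np.median(np.abs(qs)) < 0.1

    def test_missing_node_rejected(self, triangle_net):
        with pytest.raises(ValueError, match="missing"):
            signed_modularity(triangle_net, {"n0": 1})


class TestTransitivity:
    def test_triangle_is_one(self, triangle_net):
        assert transitivity(triangle_net) == pytest.approx(1.0)

    def test_path_is_zero(self, path3_net):
        assert transitivity(path3_net) == pytest.approx(0.0)

    def test_four_cycle_with_diagonal(self):
        # triangles {0,1,2} and {0,2,3} -> 6 closed triads over 8 connected
        # triples (sum of deg*(deg-1)/2 = 6+1+6+1 halves... = 8): T = 0.75
        W = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)]:
            W[i, j] = W[j, i] = 0.3
        assert transitivity(make_net(W)) == pytest.approx(0.75)
        assert transitivity(make_net(W)) == pytest.approx(brute_transitivity(W))

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(10):
            W = random_signed_graph(rng, 8, edge_prob=0.5)
            if (np.abs(W) > 0).sum() == 0:
                continue
            assert transitivity(make_net(W)) == pytest.approx(brute_transitivity(W))

    def test_no_triples_warns_and_returns_zero(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.5
        with pytest.warns(UserWarning, match="no connected triples"):
            assert transitivity(make_net(W)) == 0.0


class TestStructuralEquivalence:
    def test_duplicated_profile_reported(self):
        W = np.zeros((4, 4))
        # n0 and n1 have identical edge profiles to n2, n3
        W[0, 2] = W[2, 0] = 0.5
        W[0, 3] = W[3, 0] = -0.2
        W[1, 2] = W[2, 1] = 0.5
        W[1, 3] = W[3, 1] = -0.2
        pairs = structural_equivalence(make_net(W), threshold=0.95)
        assert ("n0", "n1", pytest.approx(1.0)) in pairs

    def test_random_sparse_network_typically_empty(self, rng):
        counts = [
            len(structural_equivalence(make_net(random_signed_graph(rng, 10, 0.3)), 0.95))
            for _ in range(5)
        ]
        assert np.median(counts) == 0

    def test_zero_threshold_reports_all_pairs(self, triangle_net):
        pairs = structural_equivalence(triangle_net, threshold=-1.0)
        assert len(pairs) == 3


class TestModuleAnova:
    def test_separated_groups_significant(self, rng):
        values = np.concatenate([rng.normal(0, 1, 10), rng.normal(3, 1, 10)])
        groups = np.array(["a"] * 10 + ["b"] * 10)
        F, p, means = module_attribute_anova(values, groups)
        assert p < 0.001
        assert means["b"] - means["a"] == pytest.approx(3.0, abs=1.5)

    def test_null_groups_not_significant(self, rng):
        pvals = []
        for seed in range(20):
            local = np.random.default_rng(seed)
            values = local.normal(size=30)
            groups = np.repeat(["a", "b", "c"], 10)
            pvals.append(module_attribute_anova(values, groups)[1])
        assert np.mean(np.array(pvals) < 0.05) < 0.2

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            module_attribute_anova(np.arange(4.0), np.array(["a"] * 4))

    def test_small_group_dropped_with_warning(self, rng):
        values = np.concatenate([rng.normal(size=5), rng.normal(size=5), [9.0]])
        groups = np.array(["a"] * 5 + ["b"] * 5 + ["tiny"])
        with pytest.warns(UserWarning, match="tiny"):
            F, p, means = module_attribute_anova(values, groups)
        assert "tiny" not in means


def test_module_composition_crosstab(triangle_net):
    for i, n in enumerate(triangle_net.nodes):
        n.module_id = 1 if i < 2 else 2
        n.function_tag = "secretion" if i == 0 else "trafficking"
    tab = module_composition(triangle_net, "function_tag")
    assert tab.loc[1, "secretion"] == 1
    assert tab.loc[1, "trafficking"] == 1
    assert tab.loc[2, "trafficking"] == 1
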
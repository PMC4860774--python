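import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from radscreen import (
    GeneSet,
    bh_adjust,
    cluster_subnetwork,
    enrich,
    enrich_clusters,
    hypergeometric_upper_tail,
    induced_subnetwork,
)

from _oracles import hypergeom_upper_tail_exact


def edge_frame(edges):
    return pd.DataFrame(edges, columns=["gene_a", "gene_b", "confidence"])


class TestInducedSubnetwork:
    def test_hand_enumeration(self):
        edges = edge_frame([("A", "B", 0.9), ("B", "C", 0.4)])
        sub = induced_subnetwork(edges, {"A", "B", "C"}, min_confidence=0.5)
        assert sub.nodes == {"A", "B"}
        assert sub.graph.number_of_edges() == 1
        assert sub.isolated == {"C"}

    def test_no_shared_edges_all_isolated(self):
        edges = edge_frame([("A", "X", 0.9), ("B", "Y", 0.9)])
        sub = induced_subnetwork(edges, {"A", "B"}, min_confidence=0.5)
        assert sub.nodes == set()
        assert sub.isolated == {"A", "B"}

    def test_full_network_identity_at_zero_cutoff(self):
        edges = edge_frame(
            [("A", "B", 0.2), ("B", "C", 0.7), ("A", "C", 0.05)]
        )
        sub = induced_subnetwork(edges, {"A", "B", "C"}, min_confidence=0.0)
        assert sub.graph.number_of_edges() == 3

    def test_unknown_candidates_reported_not_raised(self):
        edges = edge_frame([("A", "B", 0.9)])
        sub = induced_subnetwork(edges, {"A", "B", "ZZZ"}, 0.5)
        assert sub.missing_from_network == {"ZZZ"}


def two_cliques_with_bridge():
    g = nx.Graph()
    for block in (list("ABCD"), list("EFGH")):
        for u, v in itertools.combinations(block, 2):
            g.add_edge(u, v, confidence=0.9)
    g.add_edge("D", "E", confidence=0.9)
    return g


class TestClustering:
    def test_two_cliques_split_at_bridge(self):
        cs = cluster_subnetwork(two_cliques_with_bridge())
        assert sorted(sorted(c) for c in cs.clusters) == [
            list("ABCD"), list("EFGH")
        ]

    def test_single_clique_is_one_cluster(self):
        g = nx.Graph()
        for u, v in itertools.combinations("ABCDE", 2):
            g.add_edge(u, v, confidence=0.8)
        cs = cluster_subnetwork(g)
        assert cs.clusters == [frozenset("ABCDE")]

    def test_star_graph_single_cluster(self):
        g = nx.Graph()
        for leaf in "BCDEF":
            g.add_edge("A", leaf, confidence=1.0)
        cs = cluster_subnetwork(g)
        assert cs.clusters == [frozenset("ABCDEF")]

    def test_empty_graph(self):
        cs = cluster_subnetwork(nx.Graph())
        assert cs.clusters == [] and cs.unclustered == set()

    def test_small_groups_reported_unclustered(self):
        g = nx.Graph()
        g.add_edge("X", "Y", confidence=0.9)  # pair below min size 3
        for u, v in itertools.combinations("ABCD", 2):
            g.add_edge(u, v, confidence=0.9)
        cs = cluster_subnetwork(g, min_cluster_size=3)
        assert cs.clusters == [frozenset("ABCD")]
        assert cs.unclustered == {"X", "Y"}

    def test_invariant_under_node_relabeling(self):
        g = two_cliques_with_bridge()
        mapping = {n: f"Z{ord(n)}" for n in g.nodes}
        h = nx.relabel_nodes(g, mapping)
        cs_g = cluster_subnetwork(g)
        cs_h = cluster_subnetwork(h)
        relabeled = sorted(
            sorted(mapping[n] for n in c) for c in cs_g.clusters
        )
        assert relabeled == sorted(sorted(c) for c in cs_h.clusters)


class TestHypergeometric:
    def test_hand_computed_example(self):
        # N=10, K=5, n=4, k=4: choose(5,4)*choose(5,0)/choose(10,4) = 5/210
        assert hypergeometric_upper_tail(10, 5, 4, 4) == pytest.approx(
            5 / 210, rel=1e-12
        )

    def test_k_zero_is_one(self):
        assert hypergeometric_upper_tail(1000, 50, 100, 0) == 1.0

    def test_matches_exact_summation_oracle(self, rng):
        for _ in range(50):
            N = int(rng.integers(10, 1000))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            k = int(rng.integers(0, min(K, n) + 1))
            p = hypergeometric_upper_tail(N, K, n, k)
            exact = hypergeom_upper_tail_exact(N, K, n, k)
            assert p == pytest.approx(exact, rel=1e-10)

    def test_upper_plus_lower_tail_is_one(self, rng):
        from scipy import stats

        for _ in range(20):
            N = int(rng.integers(5, 400))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            k = int(rng.integers(1, min(K, n) + 1))
            upper = hypergeometric_upper_tail(N, K, n, k)
            lower = float(stats.hypergeom.cdf(k - 1, N, K, n))
            assert upper + lower == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_in_K_and_n(self, rng):
        for _ in range(20):
            N = int(rng.integers(5, 400))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            k = int(rng.integers(0, min(K, n) + 1))
            assert hypergeometric_upper_tail(N, K, n, k) == pytest.approx(
                hypergeometric_upper_tail(N, n, K, k), rel=1e-12
            )

    @pytest.mark.parametrize("args", [(10, 11, 4, 0), (10, 5, 4, 5), (10, 5, 11, 0)])
    def test_inconsistent_arguments_rejected(self, args):
        with pytest.raises(ValueError):
            hypergeometric_upper_tail(*args)


class TestBHAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_stepup_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(1e-6, 1, 25)
        perm = rng.permutation(25)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(1e-6, 1, 40)
        assert (bh_adjust(p) >= p - 1e-15).all()

    @pytest.mark.parametrize("bad", [[0.0], [-0.1], [1.1], [np.nan]])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            bh_adjust(bad)


class TestEnrich:
    def test_candidates_equal_to_set_attain_minimal_p(self):
        universe = [f"g{i}" for i in range(20)]
        sets = {
            "TARGET": GeneSet("the set", frozenset(universe[:5])),
            "OTHER": GeneSet("another", frozenset(universe[10:18])),
        }
        res = enrich(universe[:5], sets, universe)
        top = res.iloc[0]
        assert top["set_name"] == "TARGET"
        assert top["p_value"] == pytest.approx(
            hypergeom_upper_tail_exact(20, 5, 5, 5), rel=1e-10
        )

    def test_sets_without_overlap_not_tested(self):
        universe = [f"g{i}" for i in range(20)]
        sets = {"NOHIT": GeneSet("d", frozenset(universe[10:]))}
        res = enrich(universe[:5], sets, universe)
        assert len(res) == 0

    def test_candidates_outside_universe_dropped(self):
        universe = [f"g{i}" for i in range(10)]
        sets = {"S": GeneSet("d", frozenset(universe[:4]))}
        res = enrich(universe[:4] + ["alien"], sets, universe)
        assert res.iloc[0]["n_candidates"] == 4

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError):
            enrich({"a"}, {}, set())

    def test_invariants_on_counts(self):
        universe = [f"g{i}" for i in range(30)]
        rng = np.random.default_rng(0)
        sets = {
            f"S{j}": GeneSet("d", frozenset(rng.choice(universe, 8, replace=False)))
            for j in range(6)
        }
        res = enrich(rng.choice(universe, 10, replace=False), sets, universe)
        assert (res["overlap"] <= np.minimum(res["set_size"], res["n_candidates"])).all()
        assert ((res["p_value"] > 0) & (res["p_value"] <= 1)).all()
        assert (res["p_adjusted"] >= res["p_value"] - 1e-15).all()

    def test_per_cluster_enrichment_labels_clusters(self):
        from radscreen import ClusterSet

        universe = [f"g{i}" for i in range(12)]
        cs = ClusterSet([frozenset(universe[:4]), frozenset(universe[4:8])])
        sets = {"S": GeneSet("d", frozenset(universe[:4]))}
        res = enrich_clusters(cs, sets, universe)
        assert set(res["cluster"]) == {0}  # only cluster 0 overlaps S
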
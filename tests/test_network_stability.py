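import itertools

import networkx as nx
import numpy as np
import pytest

from amf_assembly.network_stability import (
    CooccurrenceNetwork,
    build_network,
    cohesion,
    filter_abundant_otus,
    robustness,
    topological_properties,
    vulnerability,
)

from conftest import make_table


def net_from_graph(g) -> CooccurrenceNetwork:
    return CooccurrenceNetwork(graph=g, rho_threshold=0.6, alpha=0.05,
                               p_adjust_method="fdr_bh", abundance_filter=0.001)


class TestAbundanceFilter:
    def test_strict_threshold(self):
        means = np.array([0.3, 0.2, 0.0009, 0.0011, 0.0005])
        row = np.append(means, 1 - means.sum())  # 6th OTU absorbs the rest
        t = make_table(np.tile(row, (4, 1)), is_relative=True)
        kept = filter_abundant_otus(t)
        assert kept.otu_ids == ("O1", "O2", "O4", "O6")

    def test_exact_boundary_dropped(self):
        row = np.array([0.001, 0.999])
        t = make_table(np.tile(row, (3, 1)), is_relative=True)
        assert filter_abundant_otus(t).otu_ids == ("O2",)

    def test_no_survivor_raises(self):
        t = make_table(np.full((3, 4), 0.25), is_relative=True)
        with pytest.raises(ValueError):
            filter_abundant_otus(t, min_mean_relative_abundance=0.5)


class TestBuildNetwork:
    def test_perfect_concordant_and_reversed_ranks(self, rng):
        base = np.arange(1, 11, dtype=float)
        noise = rng.random((10, 3)) * 0.01 + 0.5
        counts = np.column_stack([base, base * 2 + 3, base[::-1], noise])
        t = make_table(counts)
        net = build_network(t, rho_threshold=0.6, alpha=0.05)
        edges = {tuple(sorted(e)): d for *e, d in net.graph.edges(data=True)}
        assert edges[("O1", "O2")]["rho"] == pytest.approx(1.0)
        assert edges[("O1", "O2")]["sign"] == "+"
        assert edges[("O1", "O3")]["rho"] == pytest.approx(-1.0)
        assert edges[("O1", "O3")]["sign"] == "-"

    def test_independent_noise_rarely_yields_edges(self):
        # at n=10 samples a chance |rho| ~ 0.93 pair clears BH occasionally;
        # the enumerated false-edge rate for 20 noise OTUs is ~0.2 per table
        zero_edges = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            t = make_table(rng.random((10, 20)) + 0.01)
            net = build_network(t)
            zero_edges += net.n_edges == 0
            assert net.n_edges <= 2
        assert zero_edges >= 35

    def test_constant_otus_skipped_not_fatal(self, rng):
        counts = rng.random((8, 5)) + 0.1
        counts[:, 0] = 2.0
        net = build_network(make_table(counts))
        assert "O1" not in net.graph

    def test_deterministic(self, rng):
        counts = rng.random((12, 8)) + 0.1
        t = make_table(counts)
        e1 = build_network(t).edge_table()
        e2 = build_network(t).edge_table()
        assert e1.equals(e2)

    def test_too_few_samples(self, rng):
        with pytest.raises(ValueError, match="samples"):
            build_network(make_table(rng.random((3, 8))), min_samples=5)


class TestRobustness:
    def test_complete_graph_half_removal(self):
        net = net_from_graph(nx.complete_graph(10))
        rep = robustness(net, removal_fraction=0.5, n_repetitions=30, seed=1)
        assert rep.robustness_mean == pytest.approx(0.5)
        assert rep.robustness_sd == 0.0

    def test_star_graph_matches_exhaustive_enumeration(self):
        g = nx.star_graph(10)  # hub 0 + 10 leaves
        expected = _expected_robustness_by_enumeration(g, k=5)
        rep = robustness(net_from_graph(g), removal_fraction=0.5, n_repetitions=4000, seed=2)
        assert rep.robustness_mean == pytest.approx(expected, abs=0.02)

    def test_two_disjoint_edges_match_enumeration(self):
        g = nx.Graph([(0, 1), (2, 3)])
        expected = _expected_robustness_by_enumeration(g, k=2)
        rep = robustness(net_from_graph(g), removal_fraction=0.5, n_repetitions=4000, seed=3)
        assert rep.robustness_mean == pytest.approx(expected, abs=0.02)

    def test_targeted_mode_deterministic_single_repetition(self):
        g = nx.star_graph(6)
        rep = robustness(net_from_graph(g), mode="targeted_by_degree", seed=0)
        assert rep.n_repetitions == 1
        # removing the hub (plus leaves) disconnects every survivor
        assert rep.robustness_mean == 0.0

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            robustness(net_from_graph(nx.complete_graph(5)), removal_fraction=1.5)

    def test_mean_bounded_by_removal_fraction(self, rng):
        g = nx.gnp_random_graph(14, 0.3, seed=5)
        g.add_edge(0, 1)
        rep = robustness(net_from_graph(g), removal_fraction=0.5, n_repetitions=50, seed=4)
        assert 0.0 <= rep.robustness_mean <= 0.5 + 1e-12


def _expected_robustness_by_enumeration(g, k):
    nodes = sorted(g.nodes())
    total = 0.0
    sets = list(itertools.combinations(nodes, k))
    for removed in sets:
        h = g.copy()
        h.remove_nodes_from(removed)
        total += sum(1 for v in h if h.degree(v) > 0) / len(nodes)
    return total / len(sets)


class TestVulnerability:
    def test_complete_graph_zero(self):
        assert vulnerability(net_from_graph(nx.complete_graph(6))) == pytest.approx(0.0)

    def test_three_node_path_is_one(self):
        # E = (1 + 1 + 1/2)/3 = 5/6; deleting the middle node leaves no edges
        assert vulnerability(net_from_graph(nx.path_graph(3))) == pytest.approx(1.0)

    def test_cycle_symmetric_and_bounded(self):
        for n in (4, 5, 6):
            v = vulnerability(net_from_graph(nx.cycle_graph(n)))
            assert v <= 1.0 + 1e-12

    def test_bounded_on_random_graphs(self):
        for seed in range(5):
            g = nx.gnp_random_graph(12, 0.35, seed=seed)
            g.add_edges_from([(0, 1), (2, 3)])
            assert vulnerability(net_from_graph(g)) <= 1.0 + 1e-12


class TestCohesion:
    def test_complexity_identity(self, rng):
        t = make_table(rng.random((12, 9)) + 0.05)
        res = cohesion(t, n_null=50, seed=1)
        np.testing.assert_allclose(
            res.complexity, res.positive_cohesion + np.abs(res.negative_cohesion)
        )

    def test_all_positive_correlations_give_no_negative_cohesion(self):
        base = np.linspace(1, 5, 12)
        counts = np.column_stack([base * c for c in (1.0, 2.0, 0.5, 3.0)])
        res = cohesion(make_table(counts), n_null=100, seed=2)
        assert np.abs(res.negative_cohesion).max() < 0.12

    def test_independent_noise_cohesion_small(self):
        small = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            t = make_table(rng.random((150, 40)) + 0.02)
            res = cohesion(t, n_null=60, seed=seed)
            small += (
                abs(res.positive_cohesion.mean()) < 0.1
                and abs(res.negative_cohesion.mean()) < 0.1
            )
        assert small >= 9

    def test_invariant_to_sample_and_otu_reordering(self, rng):
        counts = rng.random((9, 6)) + 0.05
        t = make_table(counts)
        res = cohesion(t, n_null=40, seed=3)
        sperm = rng.permutation(9)
        operm = rng.permutation(6)
        t2 = make_table(
            counts[np.ix_(sperm, operm)],
            sample_ids=[t.sample_ids[i] for i in sperm],
            otu_ids=[t.otu_ids[j] for j in operm],
        )
        res2 = cohesion(t2, n_null=40, seed=3)
        for j, otu in enumerate(t.otu_ids):
            assert res.positive_connectedness[otu] == pytest.approx(
                res2.positive_connectedness[otu], abs=1e-12
            )
        lookup = dict(zip(res2.sample_ids, res2.positive_cohesion))
        for i, s in enumerate(t.sample_ids):
            assert res.positive_cohesion[i] == pytest.approx(lookup[s], abs=1e-12)

    def test_single_sample_rejected(self, rng):
        with pytest.raises(ValueError):
            cohesion(make_table(rng.random((1, 5)) + 0.1), n_null=20, seed=0)


class TestTopology:
    def test_triangle(self):
        props = topological_properties(net_from_graph(nx.complete_graph(3)))
        assert props["density"] == pytest.approx(1.0)
        assert props["clustering_coefficient"] == pytest.approx(1.0)
        assert props["mean_degree"] == pytest.approx(2.0)

    def test_two_disjoint_edges(self):
        props = topological_properties(net_from_graph(nx.Graph([(0, 1), (2, 3)])))
        assert props["density"] == pytest.approx(1 / 3)
        assert props["clustering_coefficient"] == 0.0
        assert props["average_path_length"] == pytest.approx(1.0)

    def test_two_planted_blocks_are_modular(self):
        g = nx.Graph()
        g.add_edges_from(itertools.combinations(range(6), 2))
        g.add_edges_from(itertools.combinations(range(6, 12), 2))
        g.add_edge(0, 6)
        props = topological_properties(net_from_graph(g))
        assert props["modularity"] > 0.3
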
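import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amf_assembly import assembly
from amf_assembly.assembly import (
    bmntd,
    bmntd_matrix,
    bnti,
    partition_processes,
    pairwise_assembly,
    phylo_mantel_correlogram,
    rc_bray,
    summarize_assembly,
    PairwiseAssembly,
)
from amf_assembly.data_io import PhylogeneticDistances
from amf_assembly.synthetic_data import simulate_tree

from conftest import make_table, star_distances


def brute_force_bmntd(d, row_a, row_b):
    """Doubly nested loop over present OTUs (independent oracle)."""
    pa = [i for i in range(len(row_a)) if row_a[i] > 0]
    pb = [j for j in range(len(row_b)) if row_b[j] > 0]
    wa = {i: row_a[i] / sum(row_a[i] for i in pa) for i in pa}
    wb = {j: row_b[j] / sum(row_b[j] for j in pb) for j in pb}
    term_a = sum(wa[i] * min(d[i][j] for j in pb) for i in pa)
    term_b = sum(wb[j] * min(d[j][i] for i in pa) for j in pb)
    return 0.5 * (term_a + term_b)


class TestBmntd:
    def test_identical_communities_zero(self, balanced_4otu):
        t = make_table([[1, 2, 0, 3], [1, 2, 0, 3]], otu_ids=list("ABCD"))
        assert bmntd(t, balanced_4otu, ("S1", "S2")) == pytest.approx(0.0)

    def test_star_phylogeny_disjoint_gives_tip_distance(self):
        d = star_distances(list("ABCD"), tip_distance=1.5)
        t = make_table([[2, 1, 0, 0], [0, 0, 3, 3]], otu_ids=list("ABCD"))
        assert bmntd(t, d, ("S1", "S2")) == pytest.approx(3.0)

    def test_worked_4otu_instance(self, balanced_4otu):
        t = make_table([[1, 1, 0, 0], [0, 0, 1, 1]], otu_ids=list("ABCD"))
        # every present OTU's nearest cross-community distance is 4
        assert bmntd(t, balanced_4otu, ("S1", "S2")) == pytest.approx(4.0)
        assert brute_force_bmntd(balanced_4otu.matrix, [1, 1, 0, 0], [0, 0, 1, 1]) == pytest.approx(4.0)

    def test_symmetry_and_nonnegativity(self, rng):
        _, dist, _ = simulate_tree(8, seed=3)
        t = make_table(rng.integers(0, 9, size=(4, 8)) + (rng.random((4, 8)) < 0.4),
                       otu_ids=list(dist.otu_ids))
        m = bmntd_matrix(t, dist)
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        assert (np.diag(m) == 0).all()
        assert (m >= 0).all()

    def test_matrix_equals_bruteforce_on_random_instances(self, rng):
        _, dist, _ = simulate_tree(6, seed=9)
        for _ in range(25):
            counts = rng.integers(0, 6, size=(2, 6))
            counts[:, rng.integers(6)] += 1  # keep both samples non-empty
            t = make_table(counts, otu_ids=list(dist.otu_ids))
            m = bmntd_matrix(t, dist)
            expected = brute_force_bmntd(dist.matrix, counts[0], counts[1])
            assert m[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_consistent_relabeling(self, rng, balanced_4otu):
        counts = np.array([[3, 1, 0, 2], [0, 2, 5, 1]], dtype=float)
        t = make_table(counts, otu_ids=list("ABCD"))
        perm = [2, 0, 3, 1]
        ids2 = [list("ABCD")[i] for i in perm]
        t2 = make_table(counts[:, perm], otu_ids=ids2)
        assert bmntd(t, balanced_4otu, ("S1", "S2")) == pytest.approx(
            bmntd(t2, balanced_4otu, ("S1", "S2"))
        )


class TestBnti:
    def test_exhaustive_null_matches_independent_enumeration(self, balanced_4otu):
        counts = np.array([[4, 1, 0, 0], [0, 0, 3, 2]], dtype=float)
        t = make_table(counts, otu_ids=list("ABCD"))
        z = bnti(t, balanced_4otu, ("S1", "S2"), exhaustive=True)

        d = balanced_4otu.matrix
        nulls = []
        for p in itertools.permutations(range(4)):
            dp = d[np.ix_(p, p)]
            nulls.append(brute_force_bmntd(dp, counts[0], counts[1]))
        obs = brute_force_bmntd(d, counts[0], counts[1])
        expected = (obs - np.mean(nulls)) / np.std(nulls)
        assert z == pytest.approx(expected, abs=1e-12)

    def test_star_phylogeny_degenerate_null_flagged(self):
        d = star_distances(list("ABCD"))
        t = make_table([[1, 1, 0, 0], [0, 0, 1, 1]], otu_ids=list("ABCD"))
        assert np.isnan(bnti(t, d, ("S1", "S2"), n_null=99, seed=0))

    def test_deterministic_given_seed(self):
        _, dist, _ = simulate_tree(6, seed=31)
        t = make_table([[4, 1, 0, 1, 2, 0], [0, 1, 3, 2, 0, 5]], otu_ids=list(dist.otu_ids))
        z1 = bnti(t, dist, ("S1", "S2"), n_null=199, seed=7)
        z2 = bnti(t, dist, ("S1", "S2"), n_null=199, seed=7)
        assert np.isfinite(z1) and z1 == z2


class TestRcBray:
    def test_identical_abundant_communities_near_minus_one(self):
        # two identical samples dominated by common OTUs, in a pool of many
        # samples with varying composition
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 30, size=(10, 20))
        counts[0] = counts[1] = np.concatenate([[500, 400], np.zeros(18, dtype=int)])
        t = make_table(counts + (counts.sum(axis=1, keepdims=True) == 0))
        rc = rc_bray(t, ("S1", "S2"), n_null=199, seed=7)
        assert rc <= -0.9

    def test_disjoint_rare_communities_near_plus_one(self):
        # rich enough samples that null assemblies (drawn by occupancy and
        # mean abundance) almost always share common taxa, while the observed
        # pair shares nothing and is built from the pool's rarest taxa
        rng = np.random.default_rng(3)
        counts = rng.integers(5, 30, size=(14, 40))
        counts[:, 24:] = 0
        counts[0] = 0
        counts[1] = 0
        counts[0, 24:32] = 40
        counts[1, 32:40] = 40
        t = make_table(counts)
        assert rc_bray(t, ("S1", "S2"), n_null=199, seed=5) >= 0.9

    def test_tie_rule_gives_zero_for_degenerate_pool(self):
        # single-OTU samples in a single-OTU pool: every null equals observed
        t = make_table([[10], [10], [10]])
        assert rc_bray(t, ("S1", "S2"), n_null=99, seed=1) == pytest.approx(0.0)

    def test_bounds_and_symmetry(self, rng):
        counts = rng.integers(0, 12, size=(6, 15)) + 1
        t = make_table(counts)
        m = assembly.rc_bray_matrix(t, n_null=99, seed=2)
        assert (m >= -1).all() and (m <= 1).all()
        np.testing.assert_allclose(m, m.T, atol=1e-12)


class TestPartition:
    @pytest.mark.parametrize(
        "z,rc,expected",
        [
            (2.5, 0.1, "variable_selection"),
            (-2.5, 0.1, "homogeneous_selection"),
            (-1.0, 0.97, "dispersal_limitation"),
            (1.0, -0.97, "homogenizing_dispersal"),
            (1.0, 0.5, "undominated"),
            (2.0, 0.0, "undominated"),  # boundary betaNTI falls to stochastic side
            (-2.0, -0.95, "undominated"),  # boundary RC falls to undominated
            (0.0, 0.95, "undominated"),
            (2.0, 0.96, "dispersal_limitation"),
        ],
    )
    def test_threshold_semantics(self, z, rc, expected):
        assert partition_processes(z, rc) == expected

    def test_nan_raises(self):
        with pytest.raises(ValueError):
            partition_processes(float("nan"), 0.0)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        st.floats(-10, 10, allow_nan=False),
        st.floats(-1, 1, allow_nan=False),
    )
    def test_total_function_over_finite_inputs(self, z, rc):
        assert partition_processes(z, rc) in assembly.PROCESSES

    def test_summary_counts(self):
        pairs = (
            [_pair("undominated")] * 7
            + [_pair("dispersal_limitation")] * 2
            + [_pair("variable_selection")]
        )
        s = summarize_assembly(pairs)
        assert s.stochastic_fraction == pytest.approx(0.9)
        assert sum(s.fractions.values()) == pytest.approx(1.0)
        assert s.n_pairs == 10

    def test_flagged_pairs_excluded_from_denominator(self):
        pairs = [_pair("variable_selection")] * 3 + [
            PairwiseAssembly("a", "b", 1.0, float("nan"), 0.1, None, flag="degenerate")
        ]
        s = summarize_assembly(pairs)
        assert s.n_pairs == 3
        assert s.stochastic_fraction == 0.0


def _pair(process):
    return PairwiseAssembly("a", "b", 1.0, 0.0, 0.0, process)


class TestPairwiseAssembly:
    def test_end_to_end_on_small_table(self, rng):
        _, dist, _ = simulate_tree(12, seed=4)
        counts = rng.integers(0, 20, size=(5, 12)) + 1
        t = make_table(counts, otu_ids=list(dist.otu_ids))
        pairs = pairwise_assembly(t, dist, n_null=99, seed=3)
        assert len(pairs) == 10
        for p in pairs:
            if p.process is not None:
                assert p.process == partition_processes(p.bnti, p.rc_bray)


class TestPhyloMantelCorrelogram:
    def test_brownian_traits_show_short_distance_signal(self):
        from amf_assembly.synthetic_data import ScenarioConfig, simulate

        ds = simulate(ScenarioConfig(seed=13, scenario="selection", n_samples=20, n_otus=60))
        res = phylo_mantel_correlogram(
            ds.distances, ds.truth["optima"], n_classes=4, n_permutations=199, seed=2
        )
        assert res[0]["r"] > 0
        assert res[0]["p_corrected"] < 0.05

    def test_permuted_traits_mostly_nonsignificant(self, rng):
        _, dist, _ = simulate_tree(40, seed=6)
        vals = dict(zip(dist.otu_ids, rng.normal(0, 1, 40)))
        res = phylo_mantel_correlogram(dist, vals, n_classes=4, n_permutations=199, seed=3)
        assert sum(c["p_corrected"] < 0.05 for c in res) <= 1

    def test_sparse_classes_dropped(self, rng):
        _, dist, _ = simulate_tree(4, seed=2)
        vals = dict(zip(dist.otu_ids, [0.0, 1.0, 2.0, 5.0]))
        res = phylo_mantel_correlogram(dist, vals, n_classes=5, n_permutations=99, seed=0)
        assert len(res) < 5
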
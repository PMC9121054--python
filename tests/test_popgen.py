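import math

import numpy as np
import pytest

import oracles
from conftest import make_dataset, random_sequences

from gradientpop.datatypes import SimulationParams
from gradientpop.popgen import (
    collapse_haplotypes,
    haplotype_distances,
    haplotype_diversity,
    minimum_spanning_network,
    nucleotide_diversity,
    pairwise_differences,
    segregating_sites,
    tajima_constants,
    tajimas_d,
)
from gradientpop.simulate import simulate_dataset


class TestCollapse:
    def test_identical_sequences_one_haplotype(self):
        ds = make_dataset(["ACGT"] * 4, ["north"] * 4)
        spec = collapse_haplotypes(ds)
        assert len(spec.haplotypes) == 1
        assert list(spec.total_counts) == [4]
        assert np.allclose(spec.p, [1.0])

    def test_two_haplotypes(self):
        ds = make_dataset(["ACGT", "ACGT", "ACCT"], ["north"] * 3)
        spec = collapse_haplotypes(ds)
        assert list(spec.total_counts) == [2, 1]

    def test_counts_match_brute_force_grouping(self, rng):
        seqs = [random_sequences(rng, 1, 30, n_variable=4)[0] for _ in range(20)]
        # force collisions by sampling from 6 distinct strings
        pool = list(dict.fromkeys(seqs))[:6]
        seqs = [pool[int(i)] for i in rng.integers(0, len(pool), size=20)]
        ds = make_dataset(seqs, ["north"] * 20)
        spec = collapse_haplotypes(ds)
        assert sorted(spec.total_counts) == sorted(oracles.haplotype_counts(seqs))
        assert spec.n == 20
        assert np.isclose(spec.p.sum(), 1.0)

    def test_n_kept_distinct_for_collapsing(self):
        # an N-carrying sequence is its own haplotype, conservatively
        ds = make_dataset(["ACGT", "ACGN"], ["north"] * 2)
        assert len(collapse_haplotypes(ds).haplotypes) == 2

    def test_empty_input_raises(self):
        from gradientpop.datatypes import SpeciesDataset
        with pytest.raises(ValueError):
            collapse_haplotypes(SpeciesDataset("x", []))


class TestPairwiseDifferences:
    def test_identical_pair(self):
        dm = pairwise_differences(make_dataset(["ACGT"] * 2, ["north"] * 2))
        assert dm.d[0, 1] == 0
        assert dm.comparable[0, 1] == 4

    def test_two_differences(self):
        dm = pairwise_differences(
            make_dataset(["ACGTACGTAC", "ACCTACGTAT"], ["north"] * 2)
        )
        assert dm.d[0, 1] == 2

    def test_pairwise_deletion_of_n(self):
        dm = pairwise_differences(make_dataset(["ACGN", "ACGT"], ["north"] * 2))
        assert dm.d[0, 1] == 0
        assert dm.comparable[0, 1] == 3

    def test_matrix_invariants_on_random_data(self, rng):
        seqs = random_sequences(rng, 8, 40)
        dm = pairwise_differences(make_dataset(seqs, ["north"] * 8))
        assert np.array_equal(dm.d, dm.d.T)
        assert np.all(np.diag(dm.d) == 0)
        assert np.all(dm.d <= dm.comparable)
        assert np.all(dm.comparable <= 40)
        for i in range(8):
            for j in range(i + 1, 8):
                d, c = oracles.pair_diff(seqs[i], seqs[j])
                assert dm.d[i, j] == d and dm.comparable[i, j] == c


class TestDiversity:
    def test_single_haplotype_gives_zero(self):
        ds = make_dataset(["ACGT"] * 7, ["north"] * 7)
        assert haplotype_diversity(collapse_haplotypes(ds)) == 0.0

    def test_two_distinct_of_two(self):
        ds = make_dataset(["ACGT", "TGCA"], ["north"] * 2)
        assert haplotype_diversity(collapse_haplotypes(ds)) == pytest.approx(1.0)

    def test_even_counts_of_four(self):
        ds = make_dataset(["ACGT", "ACGT", "TGCA", "TGCA"], ["north"] * 4)
        assert haplotype_diversity(collapse_haplotypes(ds)) == pytest.approx(2 / 3)

    def test_pi_zero_when_identical(self):
        pi, k = nucleotide_diversity(make_dataset(["ACGT"] * 5, ["north"] * 5))
        assert pi == 0.0 and k == 0.0

    def test_two_sequences_hand_value(self):
        pi, k = nucleotide_diversity(
            make_dataset(["ACGTACGTAC", "ACCTACGTAT"], ["north"] * 2)
        )
        assert k == pytest.approx(2.0)
        assert pi == pytest.approx(0.2)

    def test_matches_brute_force_on_random_sets(self, rng):
        for _ in range(10):
            seqs = random_sequences(rng, 5, 25, n_variable=8)
            pi, k = nucleotide_diversity(make_dataset(seqs, ["north"] * 5))
            opi, ok = oracles.pi_and_khat(seqs)
            assert pi == pytest.approx(opi)
            assert k == pytest.approx(ok)


class TestTajimasD:
    def test_monomorphic_is_undefined_not_zero(self):
        D, p_beta, p_norm = tajimas_d(make_dataset(["ACGT" * 100] * 6, ["north"] * 6))
        assert math.isnan(D) and math.isnan(p_beta)

    def test_constants_and_statistic_match_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 12))
            seqs = random_sequences(rng, n, 30, n_variable=int(rng.integers(2, 10)))
            if oracles.seg_sites(seqs) == 0:
                continue
            D, _, _ = tajimas_d(make_dataset(seqs, ["north"] * n))
            assert D == pytest.approx(oracles.tajimas_d(seqs), abs=1e-12)

    def test_constants_re_derivation(self):
        c = tajima_constants(10)
        i = np.arange(1, 10)
        assert c["a1"] == pytest.approx(np.sum(1 / i))
        assert c["e2"] == pytest.approx(
            (c["b2"] - 12 / (c["a1"] * 10) + c["a2"] / c["a1"] ** 2)
            / (c["a1"] ** 2 + c["a2"])
        )

    def test_negative_under_post_bottleneck_expansion(self):
        # star-like genealogies: large present-day deme, tiny ancestor,
        # recent split -> excess of rare variants -> negative mean D
        vals = []
        for s in range(60):
            params = SimulationParams(
                q1=20, q2=20, qA=0.05, t=0.5, m12=0, m21=0,
                L=545, n1=20, n2=2, seed=1000 + s,
            )
            ds, _ = simulate_dataset(params)
            north = ds.subset("north")
            D, _, _ = tajimas_d(north)
            if np.isfinite(D):
                vals.append(D)
        assert len(vals) > 30
        assert np.mean(vals) < 0


class TestMinimumSpanningNetwork:
    def test_two_haplotypes_single_edge(self):
        ds = make_dataset(["AAAT", "AGGC"], ["north"] * 2)
        G = minimum_spanning_network(collapse_haplotypes(ds))
        assert G.number_of_edges() == 1
        assert G.edges[0, 1]["weight"] == 3

    def test_tied_edges_retained_heavier_excluded(self):
        # d(0,1) = 1, d(1,2) = 1, d(0,2) = 2
        ds = make_dataset(["AAAA", "AAAT", "AATT"], ["north"] * 3)
        G = minimum_spanning_network(collapse_haplotypes(ds))
        assert set(map(frozenset, G.edges())) == {frozenset({0, 1}), frozenset({1, 2})}

    def test_single_haplotype_single_node(self):
        ds = make_dataset(["ACGT"] * 3, ["north"] * 3)
        G = minimum_spanning_network(collapse_haplotypes(ds))
        assert G.number_of_nodes() == 1 and G.number_of_edges() == 0
        assert G.nodes[0]["count"] == 3

    def test_matches_spanning_tree_enumeration(self, rng):
        import networkx as nx

        for _ in range(10):
            k = int(rng.integers(3, 6))
            seqs = []
            seen = set()
            while len(seqs) < k:
                s = "".join(rng.choice(list("ACGT"), size=8))
                if s not in seen:
                    seen.add(s)
                    seqs.append(s)
            ds = make_dataset(seqs, ["north"] * k)
            spec = collapse_haplotypes(ds)
            G = minimum_spanning_network(spec)
            dmat = haplotype_distances(spec)
            weights = {
                (i, j): int(dmat[i, j]) for i in range(k) for j in range(i + 1, k)
            }
            expected = oracles.msn_edges(weights, k)
            got = {tuple(sorted(e)) for e in G.edges()}
            assert got == expected
            assert nx.is_connected(G)

    def test_contains_a_minimum_spanning_tree(self, rng):
        import networkx as nx

        seqs = list({s for s in random_sequences(rng, 12, 20, n_variable=6)})
        ds = make_dataset(seqs, ["north"] * len(seqs))
        spec = collapse_haplotypes(ds)
        G = minimum_spanning_network(spec)
        full = nx.Graph()
        dmat = haplotype_distances(spec)
        k = len(spec.haplotypes)
        for i in range(k):
            for j in range(i + 1, k):
                full.add_edge(i, j, weight=int(dmat[i, j]))
        mst_weight = sum(d["weight"] for _, _, d in nx.minimum_spanning_tree(full).edges(data=True))
        sub_mst = nx.minimum_spanning_tree(G)
        assert sum(d["weight"] for _, _, d in sub_mst.edges(data=True)) == mst_weight


def test_segregating_sites_ignores_ambiguous_only_columns():
    ds = make_dataset(["ANGT", "ACGT", "ATGT"], ["north"] * 3)
    # column 1: {C, T} after dropping N -> segregating; others fixed
    assert segregating_sites(ds) == 1
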
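"""IBS matrix, PCA, Weir-Cockerham F_ST, Q matrices and k-NN networks."""

import io

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from rohscape.genotypes import HET, HOM_A, HOM_B, MISSING
from rohscape.popstruct import (
    RelationshipMatrix,
    build_network,
    ibs_matrix,
    knn_neighbor_lists,
    modularity_permutation_test,
    pairwise_fst,
    pca,
    read_q_matrix,
    write_q_matrix,
)
from rohscape.simulate import SimConfig, simulate_population
from helpers import make_matrix


class TestIbs:
    def test_identical_and_opposite_rows(self):
        codes = np.array([[HOM_A] * 10, [HOM_A] * 10, [HOM_B] * 10], dtype=np.int8)
        rel = ibs_matrix(make_matrix(codes))
        assert rel.values[0, 1] == 1.0
        assert rel.values[0, 2] == 0.0
        assert np.allclose(np.diag(rel.values), 1.0)

    def test_het_shares_half(self):
        codes = np.array([[HOM_A] * 4, [HET] * 4], dtype=np.int8)
        rel = ibs_matrix(make_matrix(codes))
        assert rel.values[0, 1] == 0.5

    def test_naive_pairwise_recount(self, rng):
        codes = rng.integers(0, 4, size=(6, 50)).astype(np.int8)
        codes[:, 0] = HOM_A  # guarantee overlap for every pair
        rel = ibs_matrix(make_matrix(codes))
        dose = {HOM_A: 0, HET: 1, HOM_B: 2}
        for i in range(6):
            for j in range(6):
                num = den = 0
                for a, b in zip(codes[i], codes[j]):
                    if a == MISSING or b == MISSING:
                        continue
                    num += 1 - abs(dose[a] - dose[b]) / 2
                    den += 1
                assert rel.values[i, j] == pytest.approx(num / den)

    def test_zero_overlap_pair_named(self):
        codes = np.array([[HOM_A, MISSING], [MISSING, HOM_A]], dtype=np.int8)
        with pytest.raises(ValueError, match="s0.*s1"):
            ibs_matrix(make_matrix(codes))

    def test_permutation_equivariance(self, rng):
        codes = rng.integers(0, 3, size=(8, 60)).astype(np.int8)
        g = make_matrix(codes)
        rel = ibs_matrix(g)
        perm = rng.permutation(8)
        rel_p = ibs_matrix(g.take_samples(perm))
        assert np.allclose(rel_p.values, rel.values[np.ix_(perm, perm)])


class TestPca:
    def test_separated_subpopulations_split_on_pc1(self):
        cfg = SimConfig(samples_per_subpop=(25, 25), chromosomes=(("1", 10_000_000),),
                        snp_spacing=4000, target_fst=0.15,
                        per_individual_froh_target=0.0, island_spec=None,
                        het_error_rate=0.0, missing_rate=0.0, seed=5)
        g, _ = simulate_population(cfg)
        res = pca(ibs_matrix(g))
        pc1 = res.coordinates["PC1"].to_numpy()
        labels = g.samples["subpopulation"].to_numpy()
        m0 = pc1[labels == labels[0]].mean()
        m1 = pc1[labels != labels[0]].mean()
        # group means separated by more than both within-group spreads
        gap = abs(m0 - m1)
        assert gap > pc1[labels == labels[0]].std() + pc1[labels != labels[0]].std()

    def test_identical_individuals_flagged_degenerate(self):
        rel = RelationshipMatrix(np.ones((4, 4)), [f"s{i}" for i in range(4)])
        res = pca(rel)
        assert res.degenerate
        assert np.all(res.explained_variance_ratio == 0)

    def test_variance_fractions_non_increasing_and_bounded(self, rng):
        codes = rng.integers(0, 3, size=(12, 80)).astype(np.int8)
        res = pca(ibs_matrix(make_matrix(codes)))
        r = res.explained_variance_ratio
        assert np.all(np.diff(r) <= 1e-12)
        assert r.sum() <= 1.0 + 1e-9

    def test_asymmetric_matrix_rejected(self):
        values = np.eye(3)
        values[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            pca(RelationshipMatrix(values, ["a", "b", "c"]))


def _wc_hand_two_demes(n1, p1, h1, n2, p2, h2):
    """Scalar Weir-Cockerham components for one locus, written longhand."""
    r = 2
    nbar = (n1 + n2) / 2
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


class TestFst:
    def _two_pop_matrix(self):
        # deme 1: 3 individuals -- AA, Aa, aa ; deme 2: 2 individuals -- AA, AA
        codes = np.array(
            [[HOM_A, HOM_A], [HET, HOM_A], [HOM_B, HET], [HOM_A, HOM_B], [HOM_A, HOM_B]],
            dtype=np.int8,
        )
        subpops = ["d1", "d1", "d1", "d2", "d2"]
        return make_matrix(codes, subpops=subpops)

    def test_hand_computed_two_deme_case(self):
        g = self._two_pop_matrix()
        got = pairwise_fst(g).loc["d1", "d2"]
        # locus 1: p(B) = 0.5 vs 0.0, het 1/3 vs 0 ; locus 2: 1/6 vs 1.0
        num = den = 0.0
        for (p1, h1), (p2, h2) in [((0.5, 1 / 3), (0.0, 0.0)),
                                   ((1 / 6, 1 / 3), (1.0, 0.0))]:
            a, b, c = _wc_hand_two_demes(3, p1, h1, 2, p2, h2)
            num += a
            den += a + b + c
        assert got == pytest.approx(num / den, abs=1e-10)

    def test_null_limit(self):
        cfg = SimConfig(samples_per_subpop=(100, 100), chromosomes=(("1", 25_000_000),),
                        snp_spacing=5000, target_fst=0.0,
                        per_individual_froh_target=0.0, island_spec=None,
                        het_error_rate=0.0, missing_rate=0.0, seed=42)
        g, _ = simulate_population(cfg)
        est = pairwise_fst(g).iloc[0, 1]
        assert abs(est) < 0.01

    def test_balding_nichols_recovery(self):
        cfg = SimConfig(samples_per_subpop=(100, 100), chromosomes=(("1", 25_000_000),),
                        snp_spacing=5000, target_fst=0.05,
                        per_individual_froh_target=0.0, island_spec=None,
                        het_error_rate=0.0, missing_rate=0.0, seed=43)
        g, _ = simulate_population(cfg)
        est = pairwise_fst(g).iloc[0, 1]
        assert est == pytest.approx(0.05, abs=0.01)

    def test_allele_label_swap_invariance(self, rng):
        codes = rng.integers(0, 3, size=(30, 40)).astype(np.int8)
        subpops = ["x"] * 15 + ["y"] * 15
        g = make_matrix(codes, subpops=subpops)
        swapped = codes.copy()
        cols = rng.choice(40, size=10, replace=False)
        swapped[:, cols] = np.where(swapped[:, cols] == HOM_A, HOM_B,
                                    np.where(swapped[:, cols] == HOM_B, HOM_A,
                                             swapped[:, cols]))
        g2 = make_matrix(swapped, subpops=subpops)
        assert pairwise_fst(g).iloc[0, 1] == pytest.approx(
            pairwise_fst(g2).iloc[0, 1], abs=1e-12)

    def test_small_group_rejected(self):
        codes = np.zeros((3, 5), dtype=np.int8)
        g = make_matrix(codes, subpops=["a", "a", "b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            pairwise_fst(g)


class TestQMatrix:
    def test_k1_file_of_ones(self):
        q = read_q_matrix(io.StringIO("1.0\n1.0\n"), n_samples=2)
        assert np.allclose(q, 1.0)

    def test_bad_row_sum_rejected(self):
        with pytest.raises(ValueError, match="sums to"):
            read_q_matrix(io.StringIO("0.5 0.3\n0.5 0.5\n"), n_samples=2)

    def test_row_count_mismatch(self):
        with pytest.raises(ValueError, match="rows"):
            read_q_matrix(io.StringIO("1.0\n"), n_samples=2)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            read_q_matrix(io.StringIO("1.2 -0.2\n0.5 0.5\n"), n_samples=2)

    def test_roundtrip(self, rng, tmp_path):
        q = rng.dirichlet(np.ones(4), size=6)
        write_q_matrix(q, tmp_path / "q.Q")
        back = read_q_matrix(tmp_path / "q.Q", n_samples=6)
        assert np.allclose(q, back, atol=1e-6)


class TestNetwork:
    def _rel(self, n, rng=None):
        if rng is None:
            values = np.eye(n)
        else:
            x = rng.random((n, n)) * 0.5 + 0.25
            values = (x + x.T) / 2
            np.fill_diagonal(values, 1.0)
        ids = [f"s{i}" for i in range(n)]
        return RelationshipMatrix(values if rng else np.eye(n), ids)

    def test_three_nodes_k2_complete(self, rng):
        rel = self._rel(3, rng)
        net = build_network(rel, k=2)
        assert net.number_of_edges() == 3

    def test_directed_degree_is_min_k_nm1(self, rng):
        rel = self._rel(7, rng)
        nbrs = knn_neighbor_lists(rel, k=4)
        assert all(len(v) == 4 for v in nbrs.values())
        with pytest.raises(ValueError):
            knn_neighbor_lists(rel, k=7)
        with pytest.raises(ValueError):
            knn_neighbor_lists(rel, k=0)

    def test_edge_attributes_and_no_self_edges(self, rng):
        rel = self._rel(6, rng)
        net = build_network(rel, k=2)
        assert all(u != v for u, v in net.edges)
        for u, v, d in net.edges(data=True):
            i, j = rel.sample_ids.index(u), rel.sample_ids.index(v)
            assert d["distance"] == pytest.approx(1 - rel.values[i, j])
        assert net.number_of_edges() <= 6 * 2

    def test_node_size_affine_in_sroh(self, rng):
        rel = self._rel(5, rng)
        s_roh = {f"s{i}": 100.0 + 50 * i for i in range(5)}
        net = build_network(rel, k=2, s_roh=s_roh, size_range=(4, 20))
        sizes = [net.nodes[f"s{i}"]["size"] for i in range(5)]
        assert sizes[0] == 4.0 and sizes[-1] == 20.0
        assert np.allclose(np.diff(sizes), 4.0)

    def test_mutual_mode_is_subgraph_of_union(self, rng):
        rel = self._rel(10, rng)
        union = build_network(rel, k=3)
        mutual = build_network(rel, k=3, mutual=True)
        assert set(map(frozenset, mutual.edges)) <= set(map(frozenset, union.edges))

    def test_q_fractions_copied_to_nodes(self, rng):
        rel = self._rel(4, rng)
        q = rng.dirichlet(np.ones(3), size=4)
        net = build_network(rel, k=2, q=q)
        for i in range(4):
            got = [net.nodes[f"s{i}"][f"q{k + 1}"] for k in range(3)]
            assert np.allclose(got, q[i])

    def test_modularity_beats_permutation_null(self):
        cfg = SimConfig(samples_per_subpop=(30, 30, 30, 30),
                        chromosomes=(("1", 12_000_000),), snp_spacing=4000,
                        target_fst=0.05, per_individual_froh_target=0.0,
                        island_spec=None, het_error_rate=0.0, missing_rate=0.0,
                        seed=8)
        g, _ = simulate_population(cfg)
        net = build_network(ibs_matrix(g), k=10)
        obs, p, null = modularity_permutation_test(
            net, g.subpopulations, n_permutations=200,
            rng=np.random.default_rng(0))
        assert obs > null.max()
        assert p == pytest.approx(1 / 201)

    def test_connected_on_panmictic_panel(self):
        cfg = SimConfig(samples_per_subpop=(80,), chromosomes=(("1", 8_000_000),),
                        snp_spacing=4000, target_fst=0.0,
                        per_individual_froh_target=0.0, island_spec=None,
                        het_error_rate=0.0, missing_rate=0.0, seed=12)
        g, _ = simulate_population(cfg)
        net = build_network(ibs_matrix(g), k=10)
        assert nx.is_connected(net)
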
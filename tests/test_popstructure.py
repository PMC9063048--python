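"""Genotype filtering, PCA and neighbor-joining structure analyses."""

import io
import itertools

import numpy as np
import pytest

from orgpan.popstructure import (
    GenotypeMatrix,
    filter_sites,
    hamming_distance_matrix,
    nj_tree,
    pca,
    tree_groups_monophyletic,
)


def matrix(G, accessions=None):
    G = np.asarray(G, dtype=np.int8)
    accessions = accessions or [f"a{i}" for i in range(G.shape[0])]
    sites = [("bb", j + 1) for j in range(G.shape[1])]
    return GenotypeMatrix(accessions, sites, G)


class TestFilterSites:
    def test_low_maf_removed(self):
        # MAF 0.01 (1 alt in 100) below a 0.02 threshold
        G = np.zeros((100, 2), dtype=np.int8)
        G[0, 0] = 1
        G[:50, 1] = 1
        m = filter_sites(matrix(G), min_maf=0.02)
        assert m.n_sites == 1

    def test_high_missingness_removed(self):
        G = np.zeros((20, 2), dtype=np.int8)
        G[:10, 0] = 1
        G[:10, 1] = 1
        G[:5, 1] = -1  # 25% missing > 20%
        m = filter_sites(matrix(G), min_maf=0.02, max_missing=0.20)
        assert m.n_sites == 1 and m.sites[0] == ("bb", 1)

    def test_kept_site(self):
        G = np.zeros((100, 1), dtype=np.int8)
        G[:3, 0] = 1  # MAF 0.03
        G[-10:, 0] = -1  # 10% missing
        m = filter_sites(matrix(G), min_maf=0.02, max_missing=0.20)
        assert m.n_sites == 1

    def test_all_removed_is_error(self):
        G = np.zeros((10, 3), dtype=np.int8)
        with pytest.raises(ValueError, match="removed"):
            filter_sites(matrix(G), min_maf=0.02)

    def test_maf_bounded_by_half(self):
        G = np.zeros((9, 1), dtype=np.int8)
        G[:3, 0] = 1
        G[3:6, 0] = 2  # three alleles at 1/3 each
        assert matrix(G).maf()[0] <= 0.5


class TestPca:
    def test_two_groups_fixed_sites_dominate_pc1(self):
        rng = np.random.default_rng(0)
        n, fixed, noisy = 20, 100, 8
        G = np.zeros((n, fixed + noisy), dtype=np.int8)
        G[: n // 2, :fixed] = 1  # group A carries the alt at 100 fixed sites
        G[:, fixed:] = rng.integers(0, 2, size=(n, noisy))
        coords, explained = pca(matrix(G), 2)
        assert explained[0] > 0.9
        a = coords.iloc[: n // 2, 0]
        b = coords.iloc[n // 2 :, 0]
        assert (a.max() < b.min()) or (b.max() < a.min())

    def test_zero_variance_error(self):
        G = np.ones((5, 4), dtype=np.int8)
        with pytest.raises(ValueError):
            pca(matrix(G), 2)

    def test_explained_fractions_non_increasing(self, small_cp):
        m = GenotypeMatrix.from_records(small_cp.records, small_cp.accessions)
        _, explained = pca(m, 4)
        assert all(a >= b for a, b in zip(explained, explained[1:]))
        assert explained.sum() <= 1 + 1e-9

    def test_order_permutation_invariance(self):
        rng = np.random.default_rng(1)
        G = rng.integers(0, 2, size=(12, 40)).astype(np.int8)
        m = matrix(G)
        coords, _ = pca(m, 2)
        perm = rng.permutation(12)
        m2 = GenotypeMatrix([m.accessions[i] for i in perm], m.sites, G[perm])
        coords2, _ = pca(m2, 2)
        for acc in m.accessions:
            assert np.allclose(
                np.abs(coords.loc[acc]), np.abs(coords2.loc[acc]), atol=1e-8
            )


def additive_matrix(topology, bl):
    """Pairwise distances for an unrooted 4-taxon tree ((x,y),(z,w))."""
    x, y, z, w = topology
    t = {x: bl[0], y: bl[1], z: bl[2], w: bl[3]}
    internal = bl[4]
    taxa = sorted(topology)
    D = np.zeros((4, 4))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i == j:
                continue
            same_side = {a, b} in ({x, y}, {z, w})
            D[i, j] = t[a] + t[b] + (0 if same_side else internal)
    return taxa, D


class TestNjTree:
    def _split_of(self, newick, taxa):
        from skbio import TreeNode

        tree = TreeNode.read(io.StringIO(newick))
        splits = set()
        for node in tree.non_tips():
            tips = frozenset(t.name for t in node.tips())
            if 1 < len(tips) < 4:
                splits.add(frozenset([tips, frozenset(taxa) - tips]))
        return splits

    @pytest.mark.parametrize(
        "topology", [("a", "b", "c", "d"), ("a", "c", "b", "d"), ("a", "d", "b", "c")]
    )
    def test_recovers_additive_topology(self, topology):
        """Against the brute-force oracle: of the 3 unrooted topologies,
        NJ returns the one whose additive distances generated the data."""
        taxa, D = additive_matrix(topology, [2, 3, 4, 5, 6])
        sites = [("bb", 1)]
        m = GenotypeMatrix(taxa, sites, np.zeros((4, 1), dtype=np.int8))
        from skbio import DistanceMatrix
        from skbio.tree import nj

        newick = str(nj(DistanceMatrix(D, taxa))).strip()
        want = frozenset([
            frozenset({topology[0], topology[1]}),
            frozenset({topology[2], topology[3]}),
        ])
        assert want in self._split_of(newick, taxa)

    def test_identical_accessions_zero_distance_sisters(self):
        G = np.array([[0, 0, 0, 0], [0, 0, 0, 0], [1, 1, 1, 0], [1, 1, 0, 1]],
                     dtype=np.int8)
        m = matrix(G)
        D = hamming_distance_matrix(m)
        assert D[0, 1] == 0
        newick = nj_tree(m)
        from skbio import TreeNode

        tree = TreeNode.read(io.StringIO(newick))
        lca = tree.lca([tree.find("a0"), tree.find("a1")])
        assert {t.name for t in lca.tips()} == {"a0", "a1"}
        assert tree.find("a0").length == 0 and tree.find("a1").length == 0

    def test_requires_three(self):
        with pytest.raises(ValueError):
            nj_tree(matrix(np.zeros((2, 3), dtype=np.int8)))

    def test_distance_matrix_properties(self, small_cp):
        m = GenotypeMatrix.from_records(small_cp.records, small_cp.accessions)
        D = hamming_distance_matrix(m)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)

    def test_population_groups_monophyletic(self, small_cp):
        m = GenotypeMatrix.from_records(small_cp.records, small_cp.accessions)
        newick = nj_tree(m)
        mono = tree_groups_monophyletic(newick, small_cp.groups)
        assert all(mono.values())
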
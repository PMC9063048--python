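"""Population structure: SNP filtering, PCA and a neighbor-joining tree.

The genotype matrix holds haploid allele indices (0 = reference, 1.. =
alternate, -1 = missing).  Sites are filtered on minor allele frequency
(computed over non-missing calls) and missing fraction; PCA runs on the
mean-imputed, column-centered matrix; the NJ tree uses normalized Hamming
distances over shared non-missing sites and is emitted as newick with
negative branch lengths clamped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MAF_WITHIN_SPECIES = 0.02
MAF_CROSS_SPECIES = 0.005
MAX_MISSING = 0.20


@dataclass
class GenotypeMatrix:
    """accessions x sites haploid genotype matrix."""

    accessions: list[str]
    sites: list[tuple[str, int]]  # (chrom, pos1)
    G: np.ndarray  # shape (n_accessions, n_sites), int8, -1 = missing

    @classmethod
    def from_records(cls, records, accessions: list[str]) -> "GenotypeMatrix":
        sites = [(r.chrom, r.pos1) for r in records]
        if records:
            G = np.stack([r.genotypes for r in records], axis=1).astype(np.int8)
        else:
            G = np.zeros((len(accessions), 0), dtype=np.int8)
        return cls(list(accessions), sites, G)

    @property
    def n_sites(self) -> int:
        return self.G.shape[1]

    def missing_fraction(self) -> np.ndarray:
        return (self.G < 0).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Per-site minor allele frequency over non-missing haploid calls
        (second-largest allele frequency, hence always in [0, 0.5])."""
        out = np.zeros(self.n_sites)
        for j in range(self.n_sites):
            g = self.G[:, j]
            g = g[g >= 0]
            if len(g) == 0:
                out[j] = 0.0
                continue
            freqs = np.sort(np.bincount(g) / len(g))[::-1]
            out[j] = freqs[1] if len(freqs) > 1 else 0.0
        return out


def filter_sites(
    m: GenotypeMatrix,
    min_maf: float = MAF_CROSS_SPECIES,
    max_missing: float = MAX_MISSING,
) -> GenotypeMatrix:
    """Keep sites with MAF >= min_maf and missing fraction <= max_missing."""
    keep = (m.maf() >= min_maf) & (m.missing_fraction() <= max_missing)
    if not keep.any():
        raise ValueError(
            f"all {m.n_sites} sites removed (maf >= {min_maf}, "
            f"missing <= {max_missing})"
        )
    return GenotypeMatrix(
        m.accessions,
        [s for s, k in zip(m.sites, keep) if k],
        m.G[:, keep],
    )


def _imputed_centered(m: GenotypeMatrix) -> np.ndarray:
    X = m.G.astype(float)
    X[X < 0] = np.nan
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    return X - X.mean(axis=0)


def pca(m: GenotypeMatrix, n_components: int = 2):
    """PCA of the genotype matrix.

    Returns (coordinates DataFrame indexed by accession, explained-variance
    fractions).  Components are ordered by decreasing eigenvalue; the sign
    convention makes the largest-magnitude loading of each component
    positive.  Raises on a zero-variance matrix.
    """
    if len(m.accessions) < 2 or m.n_sites < 1:
        raise ValueError("need >= 2 accessions and >= 1 site")
    X = _imputed_centered(m)
    if not X.any():
        raise ValueError("zero-variance genotype matrix")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    n_components = min(n_components, len(S))
    eig = S**2
    explained = eig / eig.sum()
    coords = U[:, :n_components] * S[:n_components]
    for j in range(n_components):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            coords[:, j] *= -1
    return (
        pd.DataFrame(
            coords,
            index=m.accessions,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        ),
        explained[:n_components],
    )


def hamming_distance_matrix(m: GenotypeMatrix) -> np.ndarray:
    """Pairwise Hamming distance over shared non-missing sites, normalized
    by the number of comparable sites."""
    G = m.G
    n = len(m.accessions)
    D = np.zeros((n, n))
    valid = G >= 0
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            nb = int(both.sum())
            d = float((G[i, both] != G[j, both]).mean()) if nb else 0.0
            D[i, j] = D[j, i] = d
    return D


def nj_tree(m: GenotypeMatrix) -> str:
    """Neighbor-joining tree (newick) from normalized Hamming distances.

    Negative branch lengths are clamped to zero.  Requires >= 3 accessions.
    """
    if len(m.accessions) < 3:
        raise ValueError("need >= 3 accessions for a tree")
    from skbio import DistanceMatrix
    from skbio.tree import nj

    D = hamming_distance_matrix(m)
    tree = nj(DistanceMatrix(D, m.accessions))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return str(tree).strip()


def tree_groups_monophyletic(newick: str, groups: dict[str, str]) -> dict[str, bool]:
    """For each group: does the smallest clade containing all its members
    contain no other accessions?  (Checked on the unrooted tree by also
    accepting complements.)"""
    import io

    from skbio import TreeNode

    tree = TreeNode.read(io.StringIO(newick))
    tips = {t.name for t in tree.tips()}
    out = {}
    for g in sorted(set(groups.values())):
        members = {a for a, gg in groups.items() if gg == g} & tips
        if len(members) < 2:
            out[g] = True
            continue
        lca = tree.lca([tree.find(m) for m in members])
        clade = {t.name for t in lca.tips()}
        out[g] = clade == members or (tips - clade) <= members or clade == tips and (
            # root clade: check the complement side too
            any(
                {t.name for t in c.tips()} == members
                or tips - {t.name for t in c.tips()} == members
                for c in tree.children
            )
        )
    return out
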
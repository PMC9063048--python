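"""Gene presence/absence and copy-number calling by homology search.

Reference genes (protein-coding genes, rRNAs, tRNAs, ORFs) are located in
each assembly by seed-and-extend homology search on both strands, circular
junction included.  A gene is called *present* when a hit covers at least
60% of the gene at >= 85% identity (thresholds configurable); the copy
number is the count of qualifying non-overlapping loci, which recovers the
double copies of rRNA genes inside chloroplast inverted repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import pandas as pd

from .circseq import CircularGenome, revcomp

PAV_MIN_COVERAGE = 0.60
PAV_MIN_IDENTITY = 0.85


@dataclass
class Gene:
    """A reference gene: sequence plus feature type.

    ``intron`` optionally holds ``(cds_offset, intron_seq)`` -- the genomic
    copy of the gene carries the intron inserted at that CDS offset.
    """

    id: str
    seq: str
    kind: str = "protein"  # protein | rRNA | tRNA | ORF
    intron: tuple[int, str] | None = None

    @property
    def genomic_seq(self) -> str:
        if self.intron is None:
            return self.seq
        off, iseq = self.intron
        return self.seq[:off] + iseq + self.seq[off:]


@dataclass
class GeneSet:
    genes: list[Gene]

    def __iter__(self):
        return iter(self.genes)

    def __len__(self):
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def ids(self) -> list[str]:
        return [g.id for g in self.genes]

    def write(self, fasta_path, features_path) -> None:
        from .circseq import write_fasta

        write_fasta([(g.id, g.genomic_seq) for g in self.genes], fasta_path)
        with open(features_path, "w") as fh:
            fh.write("gene\tkind\tlength\n")
            for g in self.genes:
                fh.write(f"{g.id}\t{g.kind}\t{len(g.genomic_seq)}\n")


@dataclass
class Hit:
    """One homology hit of a gene on a genome (coordinates folded to the
    single circle, 0-based half-open; end may exceed the genome length for
    junction-spanning hits)."""

    start0: int
    end0: int
    strand: str
    identity: float
    coverage: float
    matches: int


@dataclass
class GenePAVRecord:
    gene_id: str
    accession_id: str
    present: bool
    copy_number: int
    coverage: float
    identity: float
    hits: list[Hit] = field(default_factory=list)


def _cigar_stats(cigar: str, query_len: int):
    import re

    matches = cols = aligned_q = 0
    for num, op in re.findall(r"(\d+)([=XID])", cigar):
        n = int(num)
        cols += n
        if op == "=":
            matches += n
            aligned_q += n
        elif op == "X":
            aligned_q += n
    identity = matches / cols if cols else 0.0
    coverage = aligned_q / query_len if query_len else 0.0
    return identity, coverage, matches


def _genome_seed_hits(genome: CircularGenome, queries: dict[str, str], k: int = 21, stride: int = 4):
    """Seed phase: scan the doubled genome once against all query k-mers.

    Returns {(gene_id, strand): [(diagonal, genome_pos), ...]}.
    """
    kmap: dict[str, list[tuple[str, int, str]]] = {}
    for gid, seq in queries.items():
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for off in range(0, max(len(s) - k + 1, 1), stride):
                km = s[off : off + k]
                if len(km) == k:
                    kmap.setdefault(km, []).append((gid, off, strand))
    doubled = genome.sequence + genome.sequence
    hits: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for p in range(0, len(doubled) - k + 1):
        entry = kmap.get(doubled[p : p + k])
        if entry:
            for gid, off, strand in entry:
                hits.setdefault((gid, strand), []).append((p - off, p))
    return hits


def _cluster_diagonals(anchors, gene_len: int, slack: int = 40):
    """Group seed anchors into candidate loci by diagonal proximity."""
    clusters = []
    for diag, p in sorted(anchors):
        if clusters and diag - clusters[-1][-1][0] <= slack:
            clusters[-1].append((diag, p))
        else:
            clusters.append([(diag, p)])
    out = []
    for cl in clusters:
        diags = [d for d, _ in cl]
        start = min(diags)
        out.append((max(start - 30, 0), start + gene_len + 30))
    return out


def locate_gene(
    genome: CircularGenome,
    gene_seq: str,
    k: int = 21,
    stride: int = 4,
    min_seed: int = 2,
) -> list[Hit]:
    """Find homology hits of ``gene_seq`` on either strand of a circular
    genome.  Hits whose folded intervals overlap by more than 50% of their
    span are merged per locus, keeping the higher-scoring hit."""
    return _locate_from_seeds(
        genome, {"q": gene_seq}, k=k, stride=stride, min_seed=min_seed
    ).get("q", [])


def _locate_from_seeds(genome, queries, k=21, stride=4, min_seed=2):
    seeds = _genome_seed_hits(genome, queries, k=k, stride=stride)
    doubled = genome.sequence + genome.sequence
    L = len(genome)
    results: dict[str, list[Hit]] = {gid: [] for gid in queries}
    for (gid, strand), anchors in seeds.items():
        gene_seq = queries[gid]
        q = gene_seq if strand == "+" else revcomp(gene_seq)
        for wstart, wend in _cluster_diagonals(anchors, len(q)):
            window = doubled[wstart : min(wend, len(doubled))]
            if not window:
                continue
            res = edlib.align(q, window, task="path", mode="HW")
            if res["editDistance"] < 0:
                continue
            loc = res["locations"][0]
            identity, coverage, matches = _cigar_stats(res["cigar"], len(q))
            start0 = wstart + loc[0]
            end0 = wstart + loc[1] + 1
            if start0 >= L:
                start0 -= L
                end0 -= L
            results[gid].append(Hit(start0, end0, strand, identity, coverage, matches))
    for gid, hits in results.items():
        results[gid] = _merge_hits(hits, L)
    return results


def _circular_overlap(a: Hit, b: Hit, L: int) -> int:
    """Overlap length of two hit intervals on a circle of length L (hit
    ends may exceed L for junction-spanning hits)."""
    best = 0
    for shift in (-L, 0, L):
        s2, e2 = b.start0 + shift, b.end0 + shift
        best = max(best, min(a.end0, e2) - max(a.start0, s2))
    return best


def _merge_hits(hits: list[Hit], L: int) -> list[Hit]:
    """Deduplicate hits (doubled-genome copies, junction echoes, dense seed
    clusters): hits overlapping more than 50% of either span on the circle
    collapse to the best one."""
    hits = sorted(hits, key=lambda h: -h.matches)
    kept: list[Hit] = []
    for h in hits:
        dup = False
        for kp in kept:
            ov = _circular_overlap(h, kp, L)
            if ov > 0.5 * min(h.end0 - h.start0, kp.end0 - kp.start0):
                dup = True
                break
        if not dup:
            kept.append(h)
    kept.sort(key=lambda h: h.start0)
    return kept


def call_pav(
    hits: list[Hit],
    gene_length: int,
    accession_id: str = "",
    gene_id: str = "",
    min_cov: float = PAV_MIN_COVERAGE,
    min_ident: float = PAV_MIN_IDENTITY,
) -> GenePAVRecord:
    """Apply the coverage/identity thresholds and count qualifying loci."""
    qualifying = [h for h in hits if h.coverage >= min_cov and h.identity >= min_ident]
    copy_number = len(qualifying)
    best = max(hits, key=lambda h: h.matches) if hits else None
    return GenePAVRecord(
        gene_id=gene_id,
        accession_id=accession_id,
        present=copy_number >= 1,
        copy_number=copy_number,
        coverage=best.coverage if best else 0.0,
        identity=best.identity if best else 0.0,
        hits=qualifying,
    )


def pav_records(
    genome: CircularGenome,
    gene_set: GeneSet,
    min_cov: float = PAV_MIN_COVERAGE,
    min_ident: float = PAV_MIN_IDENTITY,
) -> list[GenePAVRecord]:
    """PAV calls for every gene of a set against one genome (shared scan)."""
    queries = {g.id: g.genomic_seq for g in gene_set}
    located = _locate_from_seeds(genome, queries)
    return [
        call_pav(
            located.get(g.id, []),
            len(g.genomic_seq),
            accession_id=genome.id,
            gene_id=g.id,
            min_cov=min_cov,
            min_ident=min_ident,
        )
        for g in gene_set
    ]


def hits_to_gff3(records: list[GenePAVRecord], seqid: str, path) -> None:
    """Write qualifying gene hits as GFF3 (1-based, inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            for h in rec.hits:
                fh.write(
                    f"{seqid}\torgpan\tgene\t{h.start0 + 1}\t{h.end0}\t"
                    f"{h.identity:.4f}\t{h.strand}\t.\t"
                    f"ID={rec.gene_id};coverage={h.coverage:.4f}\n"
                )


def pav_matrix(
    genomes: list[CircularGenome],
    gene_set: GeneSet,
    min_cov: float = PAV_MIN_COVERAGE,
    min_ident: float = PAV_MIN_IDENTITY,
):
    """Gene x accession copy-number matrix plus the core/dispensable summary.

    A gene is *core* when present in 100% of accessions; genes with more
    than one distinct copy number across accessions are listed as
    variable-copy.
    """
    if not genomes or not len(gene_set):
        raise ValueError("need at least one genome and one gene")
    data = {}
    for g in genomes:
        recs = pav_records(g, gene_set, min_cov=min_cov, min_ident=min_ident)
        data[g.id] = {r.gene_id: r.copy_number for r in recs}
    mat = pd.DataFrame(data).reindex(gene_set.ids)
    core = (mat >= 1).all(axis=1)
    variable = mat.nunique(axis=1) > 1
    summary = pd.DataFrame(
        {
            "kind": [gene_set[i].kind for i in mat.index],
            "core": core,
            "variable_copy": variable,
        },
        index=mat.index,
    )
    return mat, summary
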
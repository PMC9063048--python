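"""Pan-genome construction: reference selection, insertion editing and
dispensable scaffolds.

The accession with the most high-quality pairwise alignments (identity
>= 0.9, mutual coverage >= 0.975) becomes the draft reference.  Every
insertion fragment > 10 bp observed in any accession is placed into the
backbone at its anchored position (alleles of one event are deduplicated
at >= 95% identity within 20 bp); unanchored fragments > 100 bp are
clustered at >= 95% identity and clusters supported by at least two
accessions are appended as dispensable scaffolds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .circseq import (
    AlignmentDiff,
    CircularGenome,
    align_pair,
    diff_from_chains,
    evict_index,
    normalize_rotation,
    revcomp,
)

MIN_INSERT = 10
MIN_UNANCHORED = 100
MIN_SUPPORT = 2
DEDUP_IDENTITY = 0.95
DEDUP_POS_SLACK = 20


@dataclass
class AppliedEdit:
    """One insertion applied to the draft backbone (draft coordinates)."""

    draft_pos: int
    seq: str
    support: int
    accessions: list[str]

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class Scaffold:
    id: str
    seq: str
    support: int
    accessions: list[str]


@dataclass
class PanGenome:
    backbone: CircularGenome
    scaffolds: list[Scaffold]
    provenance: list[AppliedEdit]
    conflicts: list[str] = field(default_factory=list)
    coordinate_map: dict[str, list[tuple[int, int, str, int, int, str]]] = field(
        default_factory=dict
    )
    reference_id: str = ""

    @property
    def total_length(self) -> int:
        return len(self.backbone) + sum(len(s.seq) for s in self.scaffolds)

    def applied_offsets(self) -> list[tuple[int, int]]:
        """(draft_pos, length) of applied insertions, sorted."""
        return sorted((e.draft_pos, e.length) for e in self.provenance)

    def write_fasta(self, path) -> None:
        from .circseq import write_fasta

        recs = [(
            f"{self.backbone.id} circular=true length={len(self.backbone)}",
            self.backbone.sequence,
        )]
        recs += [
            (f"{s.id} circular=false length={len(s.seq)} support={s.support}", s.seq)
            for s in self.scaffolds
        ]
        write_fasta(recs, path)


def _seq_identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def pairwise_alignment_stats(
    genomes: list[CircularGenome], k: int = 31, stride: int = 8
) -> dict[tuple[str, str], tuple[float, float, float]]:
    """All-vs-all (identity, query_coverage, subject_coverage) per unordered
    pair, computed once per pair after rotation normalization."""
    stats = {}
    for j, subject in enumerate(genomes):
        for i in range(j):
            query = genomes[i]
            try:
                q = normalize_rotation(query, subject, k=k, stride=stride)
                chains = align_pair(q, subject, k=k, stride=stride)
            except ValueError:
                stats[(query.id, subject.id)] = (0.0, 0.0, 0.0)
                continue
            cols = sum(c.columns for c in chains)
            matches = sum(c.matches for c in chains)
            stats[(query.id, subject.id)] = (
                matches / cols if cols else 0.0,
                chains[0].query_coverage,
                chains[0].subject_coverage,
            )
        evict_index(subject)
    return stats


def choose_reference(
    genomes: list[CircularGenome],
    min_identity: float = 0.9,
    min_coverage: float = 0.975,
    k: int = 31,
    stride: int = 8,
    stats: dict | None = None,
) -> str:
    """The accession with the largest number of high-quality alignments
    to the others; ties broken by higher mean identity, then id."""
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")
    if stats is None:
        stats = pairwise_alignment_stats(genomes, k=k, stride=stride)
    counts = {g.id: 0 for g in genomes}
    idsum = {g.id: 0.0 for g in genomes}
    for (qid, sid), (ident, qc, sc) in stats.items():
        ok = ident >= min_identity and qc >= min_coverage and sc >= min_coverage
        for gid in (qid, sid):
            if ok:
                counts[gid] += 1
            idsum[gid] += ident
    if all(c == 0 for c in counts.values()):
        raise ValueError("no genome aligns to any other at the required quality")
    n = len(genomes)
    return min(counts, key=lambda g: (-counts[g], -idsum[g] / (n - 1), g))


def orient_reference(reference: CircularGenome, anchor_seq: str) -> CircularGenome:
    """Rotate/flip the draft reference so that ``anchor_seq`` (typically the
    first reference gene) starts at position 0 on the forward strand --
    the conventional fixed origin for organelle assemblies.  Returns the
    reference unchanged when the anchor is not found."""
    doubled = reference.sequence + reference.sequence
    best = None
    for strand, q in (("+", anchor_seq), ("-", revcomp(anchor_seq))):
        res = edlib.align(q, doubled, mode="HW", task="locations")
        if res["editDistance"] >= 0 and (best is None or res["editDistance"] < best[0]):
            best = (res["editDistance"], strand, res["locations"][0][0])
    if best is None or best[0] > 0.2 * len(anchor_seq):
        return reference
    _, strand, start = best
    L = len(reference)
    if strand == "+":
        seq = reference.sequence[start % L :] + reference.sequence[: start % L]
    else:
        rc = revcomp(reference.sequence)
        # anchor found at `start` on forward == ends at L-start on rc frame
        res = edlib.align(anchor_seq, rc + rc, mode="HW", task="locations")
        start = res["locations"][0][0] % L
        seq = rc[start:] + rc[:start]
    return CircularGenome(reference.id, seq, circular=True, mitotype=reference.mitotype)


def _infix_identity(a: str, b: str) -> float:
    """Identity of the shorter sequence aligned inside the longer one --
    robust to events whose boundaries absorbed a few flanking differences."""
    if not a or not b:
        return 0.0
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    d = edlib.align(short, long_, mode="HW")["editDistance"]
    return 1.0 - d / len(short)


def _same_insertion(pos_a, seq_a, pos_b, seq_b) -> bool:
    len_diff = abs(len(seq_a) - len(seq_b))
    if len_diff > 50:
        return False
    return (
        abs(pos_a - pos_b) <= DEDUP_POS_SLACK + len_diff
        and _infix_identity(seq_a, seq_b) >= DEDUP_IDENTITY
    )


def _cluster_insertions(entries, conflicts):
    """entries: (pos, seq, accession).  One cluster per insertion locus;
    within a cluster the majority allele is applied (accessions whose event
    boundaries swallowed adjacent substitutions rejoin the majority; their
    extra differences re-emerge as ordinary variants downstream)."""
    clusters: list[dict] = []
    for pos, seq, acc in sorted(entries, key=lambda t: (t[0], t[2])):
        placed = False
        for cl in clusters:
            if _same_insertion(pos, seq, cl["alleles"][0][0], cl["alleles"][0][1]):
                cl["alleles"].append((pos, seq))
                cl["accs"].append(acc)
                placed = True
                break
        if not placed:
            clusters.append({"alleles": [(pos, seq)], "accs": [acc]})
    # majority allele per cluster (ties: first seen)
    for cl in clusters:
        counts: dict[tuple[int, str], int] = {}
        for al in cl["alleles"]:
            counts[al] = counts.get(al, 0) + 1
        (pos, seq), _ = max(counts.items(), key=lambda kv: (kv[1], -kv[0][0]))
        cl["pos"], cl["seq"] = pos, seq
    # conflicting dissimilar alleles at one locus: keep the best-supported
    clusters.sort(key=lambda c: c["pos"])
    kept: list[dict] = []
    for cl in clusters:
        if kept and abs(cl["pos"] - kept[-1]["pos"]) <= DEDUP_POS_SLACK:
            prev = kept[-1]
            loser = min(prev, cl, key=lambda c: (len(c["accs"]), -c["pos"]))
            winner = cl if loser is prev else prev
            conflicts.append(
                f"conflicting insertion alleles at draft position {winner['pos']}: "
                f"kept support {len(winner['accs'])}, dropped support {len(loser['accs'])}"
            )
            kept[-1] = winner
        else:
            kept.append(cl)
    return [
        AppliedEdit(c["pos"], c["seq"], len(set(c["accs"])), sorted(set(c["accs"])))
        for c in kept
    ]


def _cluster_unanchored(entries, min_support):
    """entries: (seq, accession).  Cluster at >=95% identity (either strand);
    clusters with enough distinct accessions become scaffolds."""
    clusters: list[dict] = []
    for seq, acc in entries:
        placed = False
        for cl in clusters:
            if (
                _seq_identity(seq, cl["seq"]) >= DEDUP_IDENTITY
                or _seq_identity(revcomp(seq), cl["seq"]) >= DEDUP_IDENTITY
            ):
                cl["accs"].append(acc)
                placed = True
                break
        if not placed:
            clusters.append({"seq": seq, "accs": [acc]})
    out = []
    i = 0
    for cl in clusters:
        accs = sorted(set(cl["accs"]))
        if len(accs) >= min_support:
            i += 1
            out.append(Scaffold(f"scaffold_{i}", cl["seq"], len(accs), accs))
    return out


def compute_diffs(
    genomes: list[CircularGenome],
    reference: CircularGenome,
    k: int = 31,
    stride: int = 8,
) -> dict[str, AlignmentDiff]:
    """Normalize every accession to the reference frame and diff it."""
    diffs = {}
    for g in genomes:
        if g.id == reference.id:
            continue
        gn = normalize_rotation(g, reference, k=k, stride=stride)
        chains = align_pair(gn, reference, k=k, stride=stride)
        diff = diff_from_chains(chains, gn, reference)
        diff.chains = chains  # retained for the coordinate map
        diffs[g.id] = diff
    return diffs


def build_pangenome(
    genomes: list[CircularGenome],
    reference: CircularGenome | str,
    min_insert: int = MIN_INSERT,
    min_unanchored: int = MIN_UNANCHORED,
    min_support: int = MIN_SUPPORT,
    diffs: dict[str, AlignmentDiff] | None = None,
    k: int = 31,
    stride: int = 8,
) -> PanGenome:
    """Edit the draft with every insertion fragment > ``min_insert`` and
    append unanchored fragment clusters with >= ``min_support`` accessions
    as dispensable scaffolds.

    ``reference`` is the draft genome (pass the oriented CircularGenome
    when diffs were computed against it, or an accession id).
    """
    if isinstance(reference, str):
        reference = {g.id: g for g in genomes}[reference]
    reference_id = reference.id
    if diffs is None:
        diffs = compute_diffs(genomes, reference, k=k, stride=stride)

    ins_entries = []
    un_entries = []
    for acc, diff in diffs.items():
        for pos, seq in diff.insertions:
            if len(seq) > min_insert:
                ins_entries.append((pos, seq, acc))
        for qs, qe, seq in diff.unanchored:
            if qe - qs > min_unanchored:
                un_entries.append((seq, acc))

    conflicts: list[str] = []
    edits = _cluster_insertions(ins_entries, conflicts)
    scaffolds = _cluster_unanchored(un_entries, min_support)

    backbone_seq = reference.sequence
    for e in sorted(edits, key=lambda e: -e.draft_pos):  # right-to-left
        backbone_seq = backbone_seq[: e.draft_pos] + e.seq + backbone_seq[e.draft_pos :]
    backbone = CircularGenome(f"{reference_id}_pan", backbone_seq, circular=True)

    # coordinate map: accession intervals -> backbone intervals
    offsets = sorted((e.draft_pos, e.length) for e in edits)

    def shift(p: int) -> int:
        return p + sum(ln for pos, ln in offsets if pos <= p)

    cmap: dict[str, list[tuple[int, int, str, int, int, str]]] = {}
    for acc, diff in diffs.items():
        rows = []
        for gap in diff.gaps:
            qs, qe, seq = gap
            if qe - qs > min_unanchored:
                for s in scaffolds:
                    if _seq_identity(seq, s.seq) >= DEDUP_IDENTITY or \
                            _seq_identity(revcomp(seq), s.seq) >= DEDUP_IDENTITY:
                        rows.append((qs, qe, s.id, 0, len(s.seq), "+"))
                        break
        cmap[acc] = rows
    pan = PanGenome(
        backbone=backbone,
        scaffolds=scaffolds,
        provenance=edits,
        conflicts=conflicts,
        coordinate_map=cmap,
        reference_id=reference_id,
    )
    _fill_chain_map(pan, diffs, shift)
    return pan


def _fill_chain_map(pan, diffs, shift):
    """Map each accession's chain spans onto the edited backbone."""
    for acc, diff in diffs.items():
        rows = pan.coordinate_map.setdefault(acc, [])
        for ch in getattr(diff, "chains", []):
            rows.append(
                (ch.q_start, ch.q_end, pan.backbone.id,
                 shift(ch.s_start), shift(ch.s_end), ch.strand)
            )
        rows.sort()


def pangenome_stats(pan: PanGenome) -> dict:
    """Backbone/scaffold size summary (Results-style totals)."""
    sc_lens = [len(s.seq) for s in pan.scaffolds]
    return {
        "backbone_length": len(pan.backbone),
        "n_scaffolds": len(pan.scaffolds),
        "mean_scaffold_length": round(sum(sc_lens) / len(sc_lens)) if sc_lens else 0,
        "total_length": pan.total_length,
        "gc_content": round(pan.backbone.gc_content(), 4),
    }


def combined_total(backbone_length: int, n_scaffolds: int, mean_scaffold_length: float) -> int:
    """Total pan-genome size from its printed components."""
    return int(round(backbone_length + n_scaffolds * mean_scaffold_length))
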
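"""Population variant catalog on the pan-genome.

Per-accession alignment differences (SNPs and small indels, <=10 bp) are
normalized to canonical VCF form (anchored, left-aligned), merged across
accessions into multi-allelic records, passed through the single-sample
filter (an alternate allele carried by exactly one accession is removed),
annotated against gene models, and summarized per cytoplasm group
(variant counts, Ts/Tv, density per kb, genomic-region distribution).

Genotypes are haploid allele indices (0 = reference, 1.. = alternates,
-1 = N for missing/low-confidence calls, written as '.' in VCF).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circseq import AlignmentDiff, CircularGenome, Event

REGIONS = (
    "exonic",
    "splicing",
    "ncRNA_exonic",
    "intronic",
    "upstream/downstream",
    "intergenic",
)
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


# ---------------------------------------------------------------------------
# site normalization (shared with the truth bookkeeping)
# ---------------------------------------------------------------------------

def normalize_site(pos0: int, ref: str, alts: list[str], seq) -> tuple[int, str, list[str]]:
    """Canonical (pos1, REF, ALTs) for a replacement site.

    ``pos0``/``ref``/``alts`` describe raw alleles replacing
    ``seq[pos0 : pos0+len(ref)]`` (either side may be empty).  Indels are
    anchored on the preceding base and left-aligned across all alleles
    (parsimony + left shift), so equivalent descriptions of one edit
    collapse to the same record.
    """
    alleles = [ref] + list(alts)
    if all(len(a) == 1 for a in alleles):
        return pos0 + 1, ref, list(alts)
    start = pos0  # 0-based position of alleles[0] on seq
    while True:
        if all(alleles) and len({a[-1] for a in alleles}) == 1:
            # shared trailing base: truncate right; extend left first when
            # truncation would empty an allele
            if any(len(a) == 1 for a in alleles):
                if start == 0:
                    break
                prev = seq[start - 1]
                alleles = [prev + a[:-1] for a in alleles]
                start -= 1
            else:
                alleles = [a[:-1] for a in alleles]
        elif any(not a for a in alleles):
            if start == 0:
                break
            prev = seq[start - 1]
            alleles = [prev + a for a in alleles]
            start -= 1
        else:
            break
    while all(len(a) >= 2 for a in alleles) and len({a[0] for a in alleles}) == 1:
        alleles = [a[1:] for a in alleles]
        start += 1
    return start + 1, alleles[0], alleles[1:]


@dataclass
class VariantRecord:
    """One site of the catalog."""

    chrom: str
    pos1: int
    ref: str
    alts: list[str]
    genotypes: np.ndarray  # int8 per accession; -1 = N
    region: str | None = None
    effect: str | None = None
    genes: list[str] = field(default_factory=list)

    @property
    def type(self) -> str:
        return "SNP" if len(self.ref) == 1 and all(len(a) == 1 for a in self.alts) else "InDel"

    def allele(self, idx: int) -> str | None:
        if idx < 0:
            return None
        return self.ref if idx == 0 else self.alts[idx - 1]

    def key(self):
        return (self.chrom, self.pos1, self.ref)


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def merge_calls(
    per_accession_diffs: dict[str, AlignmentDiff],
    backbone: CircularGenome,
    low_confidence: dict[str, set[int]] | None = None,
) -> list[VariantRecord]:
    """Merge per-accession alignment events into one record per site.

    Only SNPs and small indels (length difference <= 10) become records;
    accessions without an alternate at a site receive the reference
    genotype, except where their alignment deletes the region (large
    deletion / unanchored locus) or the site is flagged low-confidence --
    those genotypes are N.
    """
    accessions = list(per_accession_diffs)
    n = len(accessions)
    seq = backbone.sequence
    sites: dict[tuple[int, str], dict[str, list[str]]] = {}
    deleted: dict[str, list[tuple[int, int]]] = {}
    for acc, diff in per_accession_diffs.items():
        deleted[acc] = [
            (ev.s_start, ev.s_end)
            for ev in diff.events
            if ev.ref_len - len(ev.alt) > 10
        ]
        for ev in diff.events:
            delta = len(ev.alt) - ev.ref_len
            if abs(delta) > 10 or (ev.ref_len == 0 and len(ev.alt) == 0):
                continue
            ref_raw = seq[ev.s_start : ev.s_end]
            pos1, ref_f, alts_f = normalize_site(ev.s_start, ref_raw, [ev.alt], seq)
            sites.setdefault((pos1, ref_f), {}).setdefault(alts_f[0], []).append(acc)

    low_confidence = low_confidence or {}
    records: list[VariantRecord] = []
    acc_index = {a: i for i, a in enumerate(accessions)}
    for (pos1, ref_f), alt_map in sorted(sites.items()):
        alts = sorted(alt_map)
        gt = np.zeros(n, dtype=np.int8)
        for alt, carriers in alt_map.items():
            ai = 1 + alts.index(alt)
            for acc in carriers:
                gt[acc_index[acc]] = ai
        pos0 = pos1 - 1
        for acc, intervals in deleted.items():
            for s, e in intervals:
                if s <= pos0 < e:
                    gt[acc_index[acc]] = -1
                    break
        for acc, poss in low_confidence.items():
            if pos1 in poss or pos0 in poss:
                gt[acc_index[acc]] = -1
        records.append(VariantRecord(backbone.id, pos1, ref_f, alts, gt))
    return records


def filter_singletons(records: list[VariantRecord]) -> list[VariantRecord]:
    """Drop alternate alleles carried by exactly one accession; records
    left without alternates are removed (the "single sample-specific
    variant" filter, applied per allele in multi-allelic records)."""
    out = []
    for rec in records:
        keep = [a for i, a in enumerate(rec.alts, start=1)
                if int((rec.genotypes == i).sum()) >= 2]
        if not keep:
            continue
        if keep == rec.alts:
            out.append(rec)
            continue
        gt = rec.genotypes.copy()
        new = np.zeros_like(gt)
        new[gt == -1] = -1
        for j, a in enumerate(keep, start=1):
            old = 1 + rec.alts.index(a)
            new[gt == old] = j
        out.append(VariantRecord(rec.chrom, rec.pos1, rec.ref, keep, new,
                                 rec.region, rec.effect, rec.genes))
    return out


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A gene on pan-genome coordinates (0-based half-open features)."""

    gene_id: str
    strand: str
    kind: str  # protein | tRNA | rRNA | ORF
    cds: list[tuple[int, int]] = field(default_factory=list)  # genomic order
    introns: list[tuple[int, int]] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(s for s, _ in self.cds)

    @property
    def end(self) -> int:
        return max(e for _, e in self.cds)

    @property
    def coding(self) -> bool:
        return self.kind in ("protein", "ORF")


def _cds_sequence(model: GeneModel, seq: str) -> str:
    from .circseq import revcomp

    parts = [seq[s:e] for s, e in sorted(model.cds)]
    cds = "".join(parts)
    return revcomp(cds) if model.strand == "-" else cds


def _cds_offset(model: GeneModel, pos0: int) -> int | None:
    """Offset of a genomic position within the spliced CDS (strand-aware)."""
    off = 0
    total = sum(e - s for s, e in model.cds)
    for s, e in sorted(model.cds):
        if s <= pos0 < e:
            fwd = off + (pos0 - s)
            return (total - 1 - fwd) if model.strand == "-" else fwd
        off += e - s
    return None


def _snp_effect(model: GeneModel, pos0: int, alt: str, seq: str, code_table: int) -> str:
    from Bio.Seq import Seq
    from .circseq import revcomp

    cds = _cds_sequence(model, seq)
    if len(cds) % 3 != 0:
        return "unknown"
    off = _cds_offset(model, pos0)
    if off is None:
        return "unknown"
    base = alt if model.strand == "+" else revcomp(alt)
    ci = off // 3
    codon = cds[3 * ci : 3 * ci + 3]
    new_codon = codon[: off % 3] + base + codon[off % 3 + 1 :]
    aa_old = str(Seq(codon).translate(table=code_table))
    aa_new = str(Seq(new_codon).translate(table=code_table))
    if aa_old == aa_new:
        return "synonymous"
    if aa_new == "*":
        return "stopgain"
    if aa_old == "*":
        return "stoploss"
    return "nonsynonymous"


def annotate(
    records: list[VariantRecord],
    gene_models: list[GeneModel],
    backbone: CircularGenome,
    flank: int = 1000,
    splice_window: int = 2,
    code_table: int = 1,
) -> list[VariantRecord]:
    """Assign region and functional effect to each record in place.

    Region priority: exonic(coding) > splicing > ncRNA_exonic > intronic >
    upstream/downstream (within ``flank`` bp of a gene) > intergenic.
    Effects: codon translation for CDS SNPs; CDS indels are frameshift iff
    the length difference is not a multiple of 3; 'unknown' when the codon
    cannot be resolved (CDS length not divisible by 3, boundary-spanning
    alleles); 'na' outside coding sequence.
    """
    seq = backbone.sequence
    warnings: list[str] = []
    for rec in records:
        pos0 = rec.pos1 - 1 if rec.type == "SNP" else rec.pos1  # first varying base
        region, effect, genes = "intergenic", "na", []
        best = len(REGIONS)
        for model in gene_models:
            cand = None
            if any(s <= pos0 < e for s, e in model.cds):
                cand = "exonic" if model.coding else "ncRNA_exonic"
            elif any(s <= pos0 < e for s, e in model.introns):
                near = any(
                    pos0 < s + splice_window or pos0 >= e - splice_window
                    for s, e in model.introns
                    if s <= pos0 < e
                )
                cand = "splicing" if near else "intronic"
            elif model.start - flank <= pos0 < model.end + flank:
                cand = "upstream/downstream"
            if cand is None:
                continue
            rank = REGIONS.index(cand)
            if rank < best:
                best = rank
                region = cand
                genes = [model.gene_id]
                if cand == "exonic":
                    if rec.type == "SNP":
                        effs = {
                            _snp_effect(model, pos0, alt, seq, code_table)
                            for alt in rec.alts
                        }
                        order = ["stopgain", "stoploss", "nonsynonymous",
                                 "synonymous", "unknown"]
                        effect = next(e for e in order if e in effs)
                        if len(_cds_sequence(model, seq)) % 3 != 0:
                            warnings.append(f"{model.gene_id}: CDS length not divisible by 3")
                    else:
                        deltas = {abs(len(alt) - len(rec.ref)) for alt in rec.alts}
                        effect = "frameshift" if any(d % 3 for d in deltas) else "nonframeshift"
                else:
                    effect = "na"
            elif rank == best and genes and model.gene_id not in genes:
                genes.append(model.gene_id)
        rec.region = region
        rec.effect = effect
        rec.genes = genes
    annotate.warnings = warnings  # simple log hook for callers/tests
    return records


def write_gene_models_gff3(models: list[GeneModel], seqid: str, path) -> None:
    """Gene models as GFF3 (gene + CDS/exon and intron features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write(f"{seqid}\torgpan\tgene\t{m.start + 1}\t{m.end}\t.\t"
                     f"{m.strand}\t.\tID={m.gene_id};kind={m.kind}\n")
            feat = "CDS" if m.coding else "exon"
            for s, e in sorted(m.cds):
                fh.write(f"{seqid}\torgpan\t{feat}\t{s + 1}\t{e}\t.\t{m.strand}\t"
                         f".\tParent={m.gene_id}\n")
            for s, e in sorted(m.introns):
                fh.write(f"{seqid}\torgpan\tintron\t{s + 1}\t{e}\t.\t{m.strand}\t"
                         f".\tParent={m.gene_id}\n")


def read_gene_models_gff3(path) -> list[GeneModel]:
    """Read gene models from GFF3 written by this package (or compatible:
    gene lines with ID=/kind= plus CDS/exon/intron children via Parent=)."""
    models: dict[str, GeneModel] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            ftype, start1, end, strand, attrs = (
                parts[2], int(parts[3]), int(parts[4]), parts[6], parts[8]
            )
            kv = dict(p.split("=", 1) for p in attrs.split(";") if "=" in p)
            if ftype == "gene":
                models[kv["ID"]] = GeneModel(kv["ID"], strand,
                                             kv.get("kind", "protein"))
            elif ftype in ("CDS", "exon"):
                models[kv["Parent"]].cds.append((start1 - 1, end))
            elif ftype == "intron":
                models[kv["Parent"]].introns.append((start1 - 1, end))
    return list(models.values())


def build_gene_models(
    genome: CircularGenome,
    gene_set,
    min_cov: float = 0.60,
    min_ident: float = 0.85,
) -> list[GeneModel]:
    """Locate reference genes on a (pan-)genome by homology and lift their
    exon/intron structure onto its coordinates.

    Hits wrapping the circular origin are skipped (the backbone is oriented
    so that genes do not cross it).
    """
    from . import gene_pav

    L = len(genome)
    models: list[GeneModel] = []
    located = gene_pav._locate_from_seeds(genome, {g.id: g.genomic_seq for g in gene_set})
    for gene in gene_set:
        for i, hit in enumerate(located.get(gene.id, [])):
            if hit.coverage < min_cov or hit.identity < min_ident or hit.end0 > L:
                continue
            gid = gene.id if i == 0 else f"{gene.id}_{i + 1}"
            s, e = hit.start0, hit.end0
            if gene.intron is None:
                cds = [(s, e)]
                introns = []
            else:
                off, iseq = gene.intron
                li = len(iseq)
                if hit.strand == "+":
                    cds = [(s, s + off), (s + off + li, e)]
                    introns = [(s + off, s + off + li)]
                else:
                    cds = [(s, e - off - li), (e - off, e)]
                    introns = [(e - off - li, e - off)]
            models.append(
                GeneModel(gid, hit.strand, gene.kind, cds=cds, introns=introns)
            )
    return models


# ---------------------------------------------------------------------------
# per-group and per-region summary tables
# ---------------------------------------------------------------------------

@dataclass
class CatalogSummary:
    per_group: pd.DataFrame  # SNPs / InDels / Ts/Tv rows per group + All
    region_counts: pd.DataFrame
    density_per_kb: float
    n_snps: int
    n_indels: int

    @property
    def snp_share(self) -> float:
        total = self.n_snps + self.n_indels
        return round(100 * self.n_snps / total, 2) if total else float("nan")


def _polymorphic_in(rec: VariantRecord, idx: np.ndarray) -> list[str]:
    """Alternate alleles segregating within the accession subset."""
    gt = rec.genotypes[idx]
    gt = gt[gt >= 0]
    present = set(int(g) for g in gt)
    if len(present) <= 1:
        return []
    return [rec.alts[g - 1] for g in present if g >= 1]


def ts_tv(pairs: list[tuple[str, str]]) -> float | None:
    ts = sum(1 for p in pairs if p in TRANSITIONS)
    tv = len(pairs) - ts
    if tv == 0:
        return None
    return ts / tv


def summarize(
    records: list[VariantRecord],
    groups: dict[str, str],
    accession_order: list[str],
    backbone_length: int,
) -> CatalogSummary:
    """Per-group and overall variant counts, Ts/Tv and density.

    Group counts include only sites polymorphic within that group
    (N genotypes excluded); density uses the backbone length.
    """
    order = {a: i for i, a in enumerate(accession_order)}
    group_names = sorted(set(groups.values()), key=lambda g: list(groups.values()).index(g))
    rows = []
    for g in group_names + ["All"]:
        if g == "All":
            idx = np.arange(len(accession_order))
        else:
            idx = np.array([order[a] for a in accession_order if groups[a] == g])
        n_snp = n_indel = 0
        pairs = []
        for rec in records:
            alts = _polymorphic_in(rec, idx)
            if not alts:
                continue
            if rec.type == "SNP":
                n_snp += 1
                pairs.extend((rec.ref, a) for a in alts if len(a) == 1 and len(rec.ref) == 1)
            else:
                n_indel += 1
        r = ts_tv(pairs)
        rows.append({
            "group": g,
            "SNPs": n_snp,
            "InDels": n_indel,
            "Ts/Tv": round(r, 2) if r is not None else "undefined",
        })
    per_group = pd.DataFrame(rows).set_index("group")
    region_counts = pd.Series(
        [r.region or "unannotated" for r in records]
    ).value_counts().rename_axis("region").to_frame("count")
    n_snps = sum(1 for r in records if r.type == "SNP")
    n_indels = len(records) - n_snps
    return CatalogSummary(
        per_group=per_group,
        region_counts=region_counts,
        density_per_kb=round(len(records) / (backbone_length / 1000), 1),
        n_snps=n_snps,
        n_indels=n_indels,
    )


def variant_density_per_kb(n_variants: int, backbone_length: int) -> float:
    """Variants per kb of backbone, reported at one decimal."""
    return round(n_variants / (backbone_length / 1000), 1)


# ---------------------------------------------------------------------------
# VCF v4.2 I/O (haploid GT, '.' for N)
# ---------------------------------------------------------------------------

def write_vcf(records: list[VariantRecord], accessions: list[str], path,
              contig: str | None = None, contig_length: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=orgpan\n")
        if contig is not None:
            ln = f",length={contig_length}" if contig_length else ""
            fh.write(f"##contig=<ID={contig}{ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Haploid genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(accessions) + "\n")
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos1)):
            gts = "\t".join("." if g < 0 else str(int(g)) for g in rec.genotypes)
            info = "." if rec.region is None else f"REGION={rec.region};EFFECT={rec.effect}"
            fh.write(
                f"{rec.chrom}\t{rec.pos1}\t.\t{rec.ref}\t{','.join(rec.alts)}\t.\tPASS\t"
                f"{info}\tGT\t{gts}\n"
            )


def read_vcf(path) -> tuple[list[VariantRecord], list[str]]:
    records: list[VariantRecord] = []
    accessions: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                accessions = parts[9:]
                continue
            chrom, pos1, _, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
            info = parts[7]
            region = effect = None
            if info != ".":
                kv = dict(p.split("=", 1) for p in info.split(";") if "=" in p)
                region, effect = kv.get("REGION"), kv.get("EFFECT")
            gt = np.array([-1 if g == "." else int(g) for g in parts[9:]], dtype=np.int8)
            records.append(
                VariantRecord(chrom, pos1, ref, alt.split(","), gt, region, effect)
            )
    return records, accessions
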
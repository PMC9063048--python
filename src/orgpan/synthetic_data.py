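"""Synthetic organelle genome populations with known ground truth.

The generator emulates a population of assembled circular organelle
genomes of a crop like *Brassica napus*:

* chloroplast-like genomes (~153 kb, ~36.3% G+C) with an LSC/IRa/SSC/IRb
  layout -- two inverted repeats carrying the duplicated rRNA genes -- and
  fully collinear structure across cytoplasm groups;
* mitochondrion-like genomes (~222 kb, ~45.2% G+C) in several mitotype
  groups whose founders differ by segmental inversions (one designated
  pair, by default *cam*/*pol*, stays collinear) and by presence/absence
  of mitotype-specific markers and variant ORFs.

Every accession is a founder plus sampled mutations: private SNPs, small
indels (1-10 bp), occasional large novel insertions (11-1,000 bp), rare
gene deletions/duplications, and -- for mitochondria -- shared novel
fragments inserted at rearrangement breakpoints, which downstream become
dispensable scaffolds.  Between-group fixed differences and within-group
shared SNPs are laid out on an interleaved site lattice; a designed
low-diversity block for one focal group provides a known
reduction-of-diversity region.  All events are recorded in a
:class:`TruthSet` with enough bookkeeping to predict the downstream
pan-genome edits and the non-singleton variant catalog exactly.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circseq import CircularGenome, revcomp, rotate
from .gene_pav import Gene, GeneSet
from .mitotyper import MitotypeProfile

# margins (bp) around placed elements; chosen so that distinct events are
# always separated by a clean unique-anchor run of the aligner
MARGIN_POINT = 20
MARGIN_INDEL = 40
MARGIN_STRUCT = 60
ORIGIN_MARGIN = 150

CP_LENGTH, MT_LENGTH = 153_000, 222_000
CP_GC, MT_GC = 0.363, 0.452


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study conditions for one simulated population."""

    seed: int = 0
    n_accessions: int = 60
    mitotype_proportions: dict[str, float] = field(
        default_factory=lambda: {"nap": 0.50, "cam": 0.30, "pol": 0.15, "ole": 0.05}
    )
    genome_kind: str = "cp"  # "cp" | "mt"
    genome_length: int | None = None
    gc_content: float | None = None
    snp_rate: float = 2e-5  # private substitutions per bp per accession
    small_indel_rate: float = 2e-6  # private 1-10 bp indels per bp
    large_insertion_rate: float = 0.2  # events per genome, 11-1000 bp
    unanchored_rate: float = 0.6  # per (group, breakpoint): shared novel fragment
    read_length: int = 150
    read_depth: int = 150
    # population variation layout
    site_spacing: int | None = 200  # period of the polymorphic-site lattice
    shared_carriers: int = 2  # carriers per within-group shared SNP
    founder_indel_rate: float = 2e-5  # fixed small indels per bp per founder
    rod_block: tuple[str, int, int] | None = None  # (group, start, end); auto
    gene_deletion_rate: float = 0.02  # per accession
    gene_duplication_rate: float = 0.02  # per accession
    collinear_pair: tuple[str, str] = ("cam", "pol")
    randomize_rotation: bool = True

    def __post_init__(self) -> None:
        if self.genome_length is None:
            self.genome_length = CP_LENGTH if self.genome_kind == "cp" else MT_LENGTH
        if self.gc_content is None:
            self.gc_content = CP_GC if self.genome_kind == "cp" else MT_GC
        self.validate()

    def validate(self) -> None:
        if self.genome_kind not in ("cp", "mt"):
            raise ValueError("genome_kind must be 'cp' or 'mt'")
        tot = sum(self.mitotype_proportions.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"mitotype proportions sum to {tot}, not 1")
        for name, value in (
            ("snp_rate", self.snp_rate),
            ("small_indel_rate", self.small_indel_rate),
            ("large_insertion_rate", self.large_insertion_rate),
            ("unanchored_rate", self.unanchored_rate),
            ("founder_indel_rate", self.founder_indel_rate),
        ):
            if value < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.genome_length <= 10 * self.read_length:
            raise ValueError("genome_length must exceed 10 x read_length")

    @property
    def groups(self) -> list[str]:
        return list(self.mitotype_proportions)

    @property
    def base_group(self) -> str:
        """The group whose founder is the coordinate base (largest share)."""
        return max(self.mitotype_proportions, key=lambda g: (self.mitotype_proportions[g], g))

    def to_yaml(self, path) -> None:
        import yaml

        d = {k: v for k, v in self.__dict__.items()}
        d["collinear_pair"] = list(self.collinear_pair)
        if d.get("rod_block"):
            d["rod_block"] = list(d["rod_block"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "collinear_pair" in d and d["collinear_pair"] is not None:
            d["collinear_pair"] = tuple(d["collinear_pair"])
        if d.get("rod_block"):
            d["rod_block"] = tuple(d["rod_block"])
        return cls(**d)


# ---------------------------------------------------------------------------
# interval registry
# ---------------------------------------------------------------------------

class IntervalRegistry:
    """Disjoint reserved intervals on the base coordinate system."""

    def __init__(self, length: int):
        self.length = length
        self.starts: list[int] = []
        self.ends: list[int] = []

    def is_free(self, start: int, end: int, margin: int = 0) -> bool:
        if start < 0 or end > self.length:
            return False
        i = bisect.bisect_left(self.starts, start)
        if i > 0 and self.ends[i - 1] + margin > start:
            return False
        if i < len(self.starts) and end + margin > self.starts[i]:
            return False
        return True

    def reserve(self, start: int, end: int, margin: int = 0) -> None:
        if not self.is_free(start, end, margin):
            raise ValueError(f"interval [{start},{end}) not free")
        i = bisect.bisect_left(self.starts, start)
        self.starts.insert(i, start)
        self.ends.insert(i, end)

    def sample(self, rng, length: int, margin: int, lo: int = 0, hi: int | None = None,
               tries: int = 300) -> int:
        hi = self.length if hi is None else hi
        for _ in range(tries):
            p = int(rng.integers(lo, hi - length))
            if self.is_free(p, p + length, margin):
                self.reserve(p, p + length, margin)
                return p
        raise RuntimeError("could not place element: genome too crowded")

    def copy(self) -> "IntervalRegistry":
        new = IntervalRegistry(self.length)
        new.starts = list(self.starts)
        new.ends = list(self.ends)
        return new

    def free_intervals(self, lo: int, hi: int) -> list[tuple[int, int]]:
        out = []
        cursor = lo
        for s, e in zip(self.starts, self.ends):
            if e <= lo or s >= hi:
                continue
            if s > cursor:
                out.append((cursor, min(s, hi)))
            cursor = max(cursor, e)
        if cursor < hi:
            out.append((cursor, hi))
        return out


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def _random_seq(rng, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=probs)])


def _random_cds(rng, n_codons: int, gc: float) -> str:
    """ATG ... stop, no internal stop codons."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_seq(rng, 3, gc)
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _apply_base_events(seq: str, events: list[tuple[int, str, str]]) -> str:
    """Apply non-overlapping (pos, ref, alt) replacements, any order given."""
    out = []
    cursor = 0
    for pos, ref_seq, alt in sorted(events):
        if pos < cursor:
            raise ValueError("overlapping events")
        out.append(seq[cursor:pos])
        out.append(alt)
        cursor = pos + len(ref_seq)
    out.append(seq[cursor:])
    return "".join(out)


class _Shift:
    """Cumulative coordinate shift induced by a set of indel events."""

    def __init__(self, events: list[tuple[int, str, str]]):
        pts = sorted((pos, len(alt) - len(ref_seq)) for pos, ref_seq, alt in events)
        self.pos = np.array([p for p, _ in pts], dtype=np.int64)
        self.cum = np.cumsum([d for _, d in pts]).astype(np.int64) if pts else np.zeros(0, np.int64)

    def __call__(self, p: int) -> int:
        i = np.searchsorted(self.pos, p, side="left")
        return int(p + (self.cum[i - 1] if i > 0 else 0))


# ---------------------------------------------------------------------------
# default mitotype profile (synthetic marker/ORF sequences)
# ---------------------------------------------------------------------------

_EXPECTED_ROWS = {
    #            nap  cam  pol  ole
    "MSS1":     (1, 0, 0, 0),
    "MSS2":     (1, 0, 1, 0),
    "MSS3":     (0, 1, 0, 0),
    "MSS4":     (0, 1, 1, 0),
    "MSS5":     (0, 0, 1, 0),
    "MSS6":     (0, 0, 0, 1),
    "MSS7":     (1, 1, 0, 0),
    "MSS8":     (0, 0, 1, 1),
    "MSS9":     (1, 0, 0, 1),
    "MSS10":    (0, 1, 1, 1),
    "MSS11":    (1, 1, 1, 0),
    "MSS12":    (0, 1, 0, 1),
    "orf224":   (1, 0, 0, 0),
    "orf139":   (0, 1, 0, 0),
    "orf263":   (0, 0, 1, 0),
    "orf188":   (0, 0, 0, 1),
    "orf108a":  (1, 1, 0, 0),
    "orf115c":  (0, 0, 1, 1),
    "orf131":   (1, 0, 1, 0),
    "orf222":   (0, 1, 0, 1),
}


def default_profile(seed: int = 0, mitotypes=("nap", "cam", "pol", "ole"),
                    gc: float = MT_GC) -> MitotypeProfile:
    """A synthetic mitotype profile: 12 MSS markers and 8 variant ORFs with
    a fixed expectation matrix over four mitotypes (sequences are random,
    mutually non-homologous)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    markers = {}
    orfs = {}
    for mid in _EXPECTED_ROWS:
        if mid.startswith("MSS"):
            markers[mid] = _random_seq(rng, int(rng.integers(150, 601)), gc)
        else:
            orfs[mid] = _random_cds(rng, int(rng.integers(100, 201)), gc)
    expected = pd.DataFrame(
        {mt: [bool(v[j]) for v in _EXPECTED_ROWS.values()]
         for j, mt in enumerate(("nap", "cam", "pol", "ole"))},
        index=list(_EXPECTED_ROWS),
    )[list(mitotypes)]
    return MitotypeProfile(markers=markers, orfs=orfs, expected=expected)


# ---------------------------------------------------------------------------
# truth bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class TruthEvent:
    """A replacement of base[pos:pos+len(ref)] by ``alt`` carried by a set
    of accessions (tag: lattice_shared / lattice_fixed / founder_indel /
    private_snp / private_indel / insertion / gene_del / gene_dup /
    fragment)."""

    pos: int
    ref: str
    alt: str
    carriers: frozenset[str]
    tag: str
    group: str | None = None

    @property
    def delta(self) -> int:
        return len(self.alt) - len(self.ref)

    @property
    def is_small(self) -> bool:
        return abs(self.delta) <= 10


@dataclass
class FounderSet:
    """Founders plus the construction context needed by the simulator."""

    config: SimulationConfig
    profile: MitotypeProfile
    base: str
    founders: dict[str, CircularGenome]
    founder_events: dict[str, list[tuple[int, str, str]]]
    inversions: dict[str, list[tuple[int, int]]]
    marker_intervals: dict[str, tuple[int, int]]  # ids embedded in base
    marker_loci: dict[str, int]  # insertion points for non-base ids
    gene_set: GeneSet
    gene_locations: dict[str, list[tuple[int, int, str]]]  # base coords
    registry: IntervalRegistry
    designed_genes: list[str]
    rod_block: tuple[str, int, int]

    def __getitem__(self, group: str) -> CircularGenome:
        return self.founders[group]

    def keys(self):
        return self.founders.keys()

    def items(self):
        return self.founders.items()

    def __iter__(self):
        return iter(self.founders)

    def shift(self, group: str) -> _Shift:
        return _Shift(self.founder_events.get(group, []))


class _Frame:
    """Orientation of an emitted/normalized draft relative to the founder
    frame, detected from the sequences themselves (rotation + strand)."""

    def __init__(self, ff_seq: str, draft_seq: str, probe_len: int = 300):
        if len(ff_seq) != len(draft_seq):
            raise ValueError("frame detection requires equal-length sequences")
        self.L = len(ff_seq)
        doubled = draft_seq + draft_seq
        probe = ff_seq[:probe_len]
        i = doubled.find(probe)
        if i >= 0:
            self.flip = False
            self.i0 = i % self.L  # draft index of ff position 0
        else:
            i = doubled.find(revcomp(probe))
            if i < 0:
                raise ValueError("draft does not match the founder frame")
            self.flip = True
            # revcomp(probe) occupies draft [i, i+probe_len) = ff positions
            # probe_len-1 .. 0 mirrored
            self.i0 = (i + probe_len) % self.L  # mirror pivot: ff pos p -> i0 - 1 - p
        # verify on a second probe away from the origin
        q = self.L // 2
        s, e = self.interval(q, q + 50)
        seg = doubled[s : s + 50]
        want = ff_seq[q : q + 50] if not self.flip else revcomp(ff_seq[q : q + 50])
        if seg != want:
            raise ValueError("ambiguous frame detection")

    def point(self, p: int) -> int:
        """Draft index of the base at founder-frame position ``p``."""
        if not self.flip:
            return (p + self.i0) % self.L
        return (self.i0 - 1 - p) % self.L

    def anchor(self, p: int) -> int:
        """Draft position of the junction before founder-frame ``p``."""
        return self.interval(p, p)[0]

    def interval(self, s: int, e: int) -> tuple[int, int]:
        if not self.flip:
            return (s + self.i0) % self.L, ((e - 1 + self.i0) % self.L) + 1
        ds = (self.i0 - e) % self.L
        return ds, ds + (e - s)

    def seq(self, s: str) -> str:
        return revcomp(s) if self.flip else s


@dataclass
class TruthSet:
    """Everything the generator knows: labels, events, matrices, designs."""

    config: SimulationConfig
    founder_set: FounderSet
    labels: dict[str, str]
    events: list[TruthEvent]
    marker_matrix: pd.DataFrame  # id x accession, bool
    copy_numbers: pd.DataFrame  # gene x accession, int
    fragments: list[dict]  # shared unanchored fragments
    rotations: dict[str, tuple[int, bool]]  # accession -> (offset, flipped)
    rod_block: tuple[str, int, int]

    @property
    def accessions(self) -> list[str]:
        return list(self.labels)

    def group_members(self, group: str) -> list[str]:
        return [a for a, g in self.labels.items() if g == group]

    # -- downstream expectations ------------------------------------------

    def point_events(self) -> list[TruthEvent]:
        """SNP/small-indel events that enter the variant catalog."""
        return [e for e in self.events if e.is_small and e.tag != "fragment"]

    def deleted_intervals(self, acc: str) -> list[tuple[int, int]]:
        """Base-coordinate intervals this accession lacks (large deletions,
        including group-absent markers baked into its founder)."""
        return [
            (e.pos, e.pos + len(e.ref))
            for e in self.events
            if acc in e.carriers and e.delta < -10
        ]

    def _id_present(self, mid: str, group: str) -> bool:
        exp = self.founder_set.profile.expected
        return bool(exp.loc[mid, group]) if mid in exp.index else True

    def refacc_shift(self, ref_id: str) -> _Shift:
        """Base -> draft-reference coordinate shift: the cumulative length
        effect of every indel event the reference accession carries
        (founder-level differences included; segmental inversions preserve
        length and carry no events, so they do not shift coordinates)."""
        evs = [
            (e.pos, e.ref, e.alt)
            for e in self.events
            if ref_id in e.carriers and e.delta != 0
        ]
        return _Shift(evs)

    def founder_frame_seq(self, acc: str) -> str:
        """The accession's sequence before the emitted rotation/flip."""
        fs = self.founder_set
        g = self.labels[acc]
        fshift = fs.shift(g)
        evs = [
            (fshift(e.pos), e.ref, e.alt)
            for e in self.events
            if acc in e.carriers and not e.tag.startswith("founder")
        ]
        return _apply_base_events(fs.founders[g].sequence, evs)

    def draft_frame(self, ref_id: str, draft_seq: str) -> _Frame:
        """Orientation of the pipeline's draft relative to the founder frame."""
        return _Frame(self.founder_frame_seq(ref_id), draft_seq)

    def expected_backbone_insertions(
        self, ref_id: str, draft_seq: str
    ) -> list[tuple[int, str]]:
        """(draft position, sequence) of every >10 bp insertion the
        pan-genome builder should apply, in the draft's own orientation."""
        shift = self.refacc_shift(ref_id)
        frame = self.draft_frame(ref_id, draft_seq)
        ref_group = self.labels[ref_id]
        counts = {g: len(self.group_members(g)) for g in self.config.groups}
        fset = self.founder_set
        seqs = {**fset.profile.markers, **fset.profile.orfs}
        out = []
        seen_loci = set()
        for mid in fset.profile.expected.index:
            if self._id_present(mid, ref_group):
                continue
            donors = [g for g in self.config.groups
                      if counts.get(g, 0) > 0 and self._id_present(mid, g)]
            if not donors:
                continue
            if mid in fset.marker_intervals:
                s, e = fset.marker_intervals[mid]
                pos, seq = s, fset.base[s:e]
            else:
                pos, seq = fset.marker_loci[mid], seqs[mid]
            if pos not in seen_loci:
                out.append((frame.anchor(shift(pos)), frame.seq(seq)))
                seen_loci.add(pos)
        for e in self.events:
            if (e.delta > 10 and e.tag not in ("fragment",)
                    and not e.tag.startswith("founder")
                    and ref_id not in e.carriers):
                out.append((frame.anchor(shift(e.pos)), frame.seq(e.alt)))
        # breakpoint fragments anchor (and get applied) when the reference
        # group shares the rearrangement; otherwise they stay unanchored
        for f in self.fragments:
            if self._fragment_anchorable(f, ref_group) and ref_id not in f["carriers"]:
                out.append((frame.anchor(shift(f["pos"])), frame.seq(f["seq"])))
        return sorted(out)

    def _fragment_anchorable(self, frag: dict, ref_group: str) -> bool:
        inv = self.founder_set.inversions
        seg = next(s for s in inv[frag["group"]] if frag["pos"] in s)
        return seg in inv.get(ref_group, [])

    def expected_scaffolds(self, ref_group: str | None = None) -> list[dict]:
        """Fragments that should surface as dispensable scaffolds: shared by
        >= 2 accessions and not anchorable on the chosen reference."""
        out = [f for f in self.fragments if len(f["carriers"]) >= 2]
        if ref_group is not None:
            out = [f for f in out if not self._fragment_anchorable(f, ref_group)]
        return out

    def expected_catalog(self, ref_id: str, accession_order: list[str],
                         draft_seq: str, backbone_seq: str,
                         applied_edits: list[tuple[int, int]]):
        """Predict the post-singleton-filter variant catalog on backbone
        coordinates.  ``applied_edits`` are (draft_pos, inserted_length)
        pairs from the pan-genome builder's provenance; ``draft_seq`` is
        the oriented draft the builder edited."""
        from .variant_catalog import normalize_site

        shift = self.refacc_shift(ref_id)
        frame = self.draft_frame(ref_id, draft_seq)
        ins = _Shift([(p, "", "x" * ln) for p, ln in applied_edits])
        deleted = {a: self.deleted_intervals(a) for a in accession_order}
        records = []
        for ev_group in self._events_by_pos():
            pos = ev_group[0].pos
            alleles: dict[str, str | None] = {}
            for acc in accession_order:
                al = next((ev.alt for ev in ev_group if acc in ev.carriers),
                          ev_group[0].ref)
                for s, e in deleted[acc]:
                    if s <= pos < e:
                        al = None  # missing region -> N
                        break
                alleles[acc] = al
            ref_allele = alleles[ref_id]
            if ref_allele is None:
                continue
            # per-allele singleton filter (base-frame alleles)
            alt_counts: dict[str, int] = {}
            for acc, al in alleles.items():
                if al is not None and al != ref_allele:
                    alt_counts[al] = alt_counts.get(al, 0) + 1
            kept = [a for a, c in alt_counts.items() if c >= 2]
            if not kept:
                continue
            # draft frame: the site occupies the reference accession's
            # allele footprint; alleles are strand-transformed with it
            ffs = shift(pos)
            ds, _ = frame.interval(ffs, ffs + len(ref_allele))
            dref = frame.seq(ref_allele)
            dalts = sorted(frame.seq(a) for a in kept)
            bb_pos = ins(ds)
            pos1, ref_f, alts_f = normalize_site(bb_pos, dref, dalts, backbone_seq)
            genotypes = []
            for acc in accession_order:
                al = alleles[acc]
                dal = None if al is None else frame.seq(al)
                if al is None:
                    genotypes.append(-1)
                elif al == ref_allele or dal not in dalts:
                    genotypes.append(0)
                else:
                    genotypes.append(1 + dalts.index(dal))
            records.append((pos1, ref_f, tuple(alts_f), tuple(genotypes)))
        records.sort()
        return records

    def _events_by_pos(self):
        small = [e for e in self.point_events()]
        by_pos: dict[int, list[TruthEvent]] = {}
        for e in small:
            by_pos.setdefault(e.pos, []).append(e)
        return [by_pos[p] for p in sorted(by_pos)]

    # -- tabular outputs ---------------------------------------------------

    def labels_to_tsv(self, path) -> None:
        pd.Series(self.labels, name="mitotype").rename_axis("accession").to_csv(
            path, sep="\t"
        )

    def events_to_tsv(self, path) -> None:
        rows = [
            {
                "pos0": e.pos,
                "ref": e.ref or "-",
                "alt": e.alt or "-",
                "tag": e.tag,
                "group": e.group or "",
                "carriers": ",".join(sorted(e.carriers)),
            }
            for e in self.events
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# founder construction
# ---------------------------------------------------------------------------

def _make_gene_set(rng, kind: str, gc: float, profile: MitotypeProfile) -> GeneSet:
    genes: list[Gene] = []
    if kind == "cp":
        protein = ["rbcL", "matK", "psbA", "psbB", "ndhA", "atpA", "rpoB", "rpoC1",
                   "clpP", "accD", "cemA", "ccsA", "petA", "psaA", "psaB", "ndhB",
                   "ycf1", "ycf2"]
        intron_hosts = ["rpl2", "petB"]
        trnas = ["trnH", "trnK", "trnD", "trnS"]
        rrnas = ["rrn16", "rrn23"]
        orf_core: list[str] = []
    else:
        protein = ["atp1", "atp4", "atp6", "atp8", "atp9", "cob", "cox1", "cox2",
                   "cox3", "ccmB", "ccmC", "matR", "nad1", "nad2", "nad3"]
        intron_hosts = ["nad4", "nad7"]
        trnas = ["trnM", "trnC", "trnF", "trnW"]
        rrnas = ["rrn18", "rrn26"]
        orf_core = ["orf25", "orf240"]
    for name in protein:
        genes.append(Gene(name, _random_cds(rng, int(rng.integers(100, 401)), gc), "protein"))
    for name in intron_hosts:
        cds = _random_cds(rng, int(rng.integers(120, 301)), gc)
        ioff = 3 * int(rng.integers(20, len(cds) // 3 - 20))
        intron = "GT" + _random_seq(rng, 116, gc) + "AG"
        genes.append(Gene(name, cds, "protein", intron=(ioff, intron)))
    for name in trnas:
        genes.append(Gene(name, _random_seq(rng, 75, gc), "tRNA"))
    for name in rrnas:
        genes.append(Gene(name, _random_seq(rng, 800, gc), "rRNA"))
    for name in orf_core:
        genes.append(Gene(name, _random_cds(rng, int(rng.integers(80, 151)), gc), "ORF"))
    for name, seq in profile.orfs.items():
        genes.append(Gene(name, seq, "ORF"))
    return GeneSet(genes)


def build_founders(config: SimulationConfig, profile: MitotypeProfile) -> FounderSet:
    """Construct one founder genome per mitotype.

    The base group's founder *is* the base coordinate system; other
    founders carry fixed small indels, marker/ORF insertions or deletions
    and (for mitochondria) segmental inversions, all recorded in base
    coordinates.  Fixed SNP differences between groups are added later by
    the population simulator's site lattice.
    """
    profile.validate()
    L = config.genome_length
    for mid, seq in {**profile.markers, **profile.orfs}.items():
        if len(seq) >= L:
            raise ValueError(f"marker {mid} longer than genome")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    base = list(_random_seq(rng, L, config.gc_content))
    registry = IntervalRegistry(L)
    registry.reserve(0, ORIGIN_MARGIN)
    registry.reserve(L - ORIGIN_MARGIN, L)

    groups = config.groups
    base_group = config.base_group

    # --- segmental inversions (mt only) ---------------------------------
    inversions: dict[str, list[tuple[int, int]]] = {g: [] for g in groups}
    if config.genome_kind == "mt":
        others = [g for g in groups if g != base_group]
        pair = [g for g in config.collinear_pair if g in others]
        segments: list[tuple[int, int]] = []
        frac = 0.28
        n_segments = max(1, len(others) - (1 if len(pair) == 2 else 0))
        for i in range(n_segments):
            a = int(L * (frac + 0.14 * i))
            b = a + int(L * 0.06)
            segments.append((a, b))
            registry.reserve(a - MARGIN_STRUCT, b + MARGIN_STRUCT)
        si = 0
        for g in others:
            if len(pair) == 2 and g in pair:
                inversions[g] = [segments[0]]
            else:
                inversions[g] = [segments[min(si + (1 if len(pair) == 2 else 0),
                                              len(segments) - 1)]]
                si += 1
        # guarantee every non-collinear pair differs by >= 1 rearrangement:
        # groups either share segment[0] (the designated pair) or own a
        # distinct later segment, so symmetric differences are non-empty.

    # --- ROD block --------------------------------------------------------
    if config.rod_block is None:
        bs = int(round(0.10 * L, -2))
        # long enough that the block's windows exceed the top-1% window
        # count, so quantile selection resolves to the block alone
        bl = max(2000, L // 50 + 1000)
        # the focal group carries the shared-site load of the lattice, so
        # it is the *second*-largest group: the base group stays the most
        # homogeneous one and is naturally chosen as the reference
        by_share = sorted(config.mitotype_proportions,
                          key=lambda g: (-config.mitotype_proportions[g], g))
        focal_group = by_share[1] if len(by_share) > 1 else base_group
        block = (focal_group, bs, bs + bl)
    else:
        block = config.rod_block
    registry.reserve(block[1] - MARGIN_STRUCT, block[2] + MARGIN_STRUCT)

    # --- inverted repeats with rRNA genes (cp) ---------------------------
    gene_set = _make_gene_set(rng, config.genome_kind, config.gc_content, profile)
    gene_locations: dict[str, list[tuple[int, int, str]]] = {g.id: [] for g in gene_set}
    if config.genome_kind == "cp":
        rrnas = [g for g in gene_set if g.kind == "rRNA"]
        ir = list(_random_seq(rng, 2400, config.gc_content))
        off = 100
        rr_offsets = []
        for g in rrnas:
            ir[off : off + len(g.seq)] = g.seq
            rr_offsets.append((g.id, off, len(g.seq)))
            off += len(g.seq) + 150
        ir_seq = "".join(ir)
        pa = registry.sample(rng, len(ir_seq), MARGIN_STRUCT,
                             lo=int(0.52 * L), hi=int(0.60 * L))
        pb = registry.sample(rng, len(ir_seq), MARGIN_STRUCT,
                             lo=int(0.72 * L), hi=int(0.80 * L))
        base[pa : pa + len(ir_seq)] = ir_seq
        base[pb : pb + len(ir_seq)] = revcomp(ir_seq)
        for gid, o, ln in rr_offsets:
            gene_locations[gid].append((pa + o, pa + o + ln, "+"))
            gene_locations[gid].append((pb + len(ir_seq) - o - ln, pb + len(ir_seq) - o, "-"))

    # --- genes embedded in the base --------------------------------------
    variant_ids = set(profile.orfs)
    for g in gene_set:
        if g.kind == "rRNA" and config.genome_kind == "cp":
            continue  # already inside the IRs
        seq = g.genomic_seq
        strand = "+" if rng.random() < 0.5 else "-"
        p = registry.sample(rng, len(seq), MARGIN_STRUCT)
        base[p : p + len(seq)] = seq if strand == "+" else revcomp(seq)
        gene_locations[g.id].append((p, p + len(seq), strand))

    # --- markers: embed base-group's, reserve loci for the rest ----------
    marker_intervals: dict[str, tuple[int, int]] = {}
    marker_loci: dict[str, int] = {}
    for mid in profile.ids:
        seqs = {**profile.markers, **profile.orfs}
        seq = seqs[mid]
        present_in_base = bool(profile.expected.loc[mid, base_group]) \
            if base_group in profile.expected.columns else False
        if mid in variant_ids:
            # variant ORFs were placed with the gene set only if present in
            # the base group; relocate bookkeeping accordingly
            if present_in_base:
                loc = gene_locations[mid][0]
                marker_intervals[mid] = (loc[0], loc[1])
            else:
                s, e, _ = gene_locations[mid][0]
                # carve the ORF back out of the base: it must be absent
                base[s:e] = _random_seq(rng, e - s, config.gc_content)
                gene_locations[mid] = []
                marker_loci[mid] = s
        elif present_in_base:
            p = registry.sample(rng, len(seq), MARGIN_STRUCT)
            base[p : p + len(seq)] = seq
            marker_intervals[mid] = (p, p + len(seq))
        else:
            p = registry.sample(rng, 2, MARGIN_STRUCT)
            marker_loci[mid] = p
    base_seq = "".join(base)
    assert len(base_seq) == L

    # --- per-group founder events ----------------------------------------
    founder_events: dict[str, list[tuple[int, str, str]]] = {g: [] for g in groups}
    seqs = {**profile.markers, **profile.orfs}
    for g in groups:
        if g == base_group:
            continue
        evs = founder_events[g]
        for mid, (s, e) in marker_intervals.items():
            present = bool(profile.expected.loc[mid, g])
            if not present:
                evs.append((s, base_seq[s:e], ""))
        for mid, p in marker_loci.items():
            if bool(profile.expected.loc[mid, g]):
                evs.append((p, "", seqs[mid]))
        n_ind = rng.poisson(config.founder_indel_rate * L)
        for _ in range(n_ind):
            ln = int(rng.integers(1, 11))
            if rng.random() < 0.5:
                p = registry.sample(rng, ln, MARGIN_INDEL)
                evs.append((p, base_seq[p : p + ln], ""))
            else:
                p = registry.sample(rng, 1, MARGIN_INDEL)
                evs.append((p, "", _random_seq(rng, ln, config.gc_content)))

    founders: dict[str, CircularGenome] = {}
    for g in groups:
        seq = _apply_base_events(base_seq, founder_events[g])
        shift = _Shift(founder_events[g])
        for a, b in inversions[g]:
            a2, b2 = shift(a), shift(b)
            seq = seq[:a2] + revcomp(seq[a2:b2]) + seq[b2:]
        founders[g] = CircularGenome(f"founder_{g}", seq, mitotype=g)

    # post-condition: each founder contains exactly its profile's markers
    return FounderSet(
        config=config,
        profile=profile,
        base=base_seq,
        founders=founders,
        founder_events=founder_events,
        inversions=inversions,
        marker_intervals=marker_intervals,
        marker_loci=marker_loci,
        gene_set=gene_set,
        gene_locations=gene_locations,
        registry=registry,
        designed_genes=_pick_designed_genes(gene_set, gene_locations, inversions, config),
        rod_block=block,
    )


def _pick_designed_genes(gene_set, gene_locations, inversions, config):
    """Genes that receive exonic lattice sites: a few single-copy genes
    outside every inversion segment."""
    inv = [seg for segs in inversions.values() for seg in segs]
    out = []
    wanted = {"protein": 2, "tRNA": 1}
    taken = {"protein": 0, "tRNA": 0}
    for g in gene_set:
        locs = gene_locations.get(g.id, [])
        if len(locs) != 1 or g.kind not in wanted or g.intron is not None:
            continue
        s, e, _ = locs[0]
        if any(a <= s < b or a < e <= b for a, b in inv):
            continue
        if taken[g.kind] < wanted[g.kind]:
            out.append(g.id)
            taken[g.kind] += 1
    # one intron host for intronic annotations
    for g in gene_set:
        if g.intron is not None and gene_locations.get(g.id):
            s, e, _ = gene_locations[g.id][0]
            if not any(a <= s < b or a < e <= b for a, b in inv):
                out.append(g.id)
                break
    return out


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------

def largest_remainder_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """round(n x p) with largest-remainder correction summing exactly to n."""
    raw = {g: n * p for g, p in proportions.items()}
    counts = {g: int(v) for g, v in raw.items()}
    short = n - sum(counts.values())
    order = sorted(proportions, key=lambda g: -(raw[g] - counts[g]))
    for g in order[:short]:
        counts[g] += 1
    return counts


def _rand_base(rng, exclude: str) -> str:
    choices = [b for b in "ACGT" if b != exclude]
    return choices[int(rng.integers(0, len(choices)))]


def _pick_carriers(rng, members: list[str], k: int) -> frozenset[str]:
    idx = rng.choice(len(members), size=min(k, len(members)), replace=False)
    return frozenset(members[int(i)] for i in idx)


def _lattice_sites(config, fs, reg, rng, members_of):
    """Lay polymorphic SNP sites as focal-partner-focal triplets.

    Each triplet holds a partner site (another group's shared pair or a
    group-fixed difference) flanked ~70 bp on both sides by focal-group
    shared sites; the triplet span is reserved as one interval, so no
    later structural event can separate a partner from its focal flanks.
    Any analysis window that contains population polymorphism therefore
    also contains focal-group polymorphism -- except inside the designed
    low-diversity block, which receives partner sites only and is the one
    place where the focal group's diversity is exactly zero.  A few
    designated genes get the same pattern for coding-region annotations.
    """
    events: list[TruthEvent] = []
    base_seq = fs.base
    focal, bs, be = fs.rod_block
    cycle = []
    for g in config.groups:
        if not members_of[g]:
            continue
        if g != config.base_group:
            # fixed differences are relative to the base founder, so the
            # base group itself has none; the focal group's fixed sites are
            # within-group monomorphic and cannot disturb its window pi
            cycle.append(("fixed", g))
        if g != focal and len(members_of[g]) >= 2:
            cycle.append(("shared", g))
    if not cycle:
        cycle = [("fixed", focal)]  # degenerate single-group population

    def add_site(p, kind, g, force=False) -> bool:
        # the designed block is pre-reserved (nothing else may enter it);
        # its own sites are laid with force=True on a fixed grid instead
        if not force and not reg.is_free(p, p + 1, MARGIN_POINT):
            return False
        members = members_of[g]
        if kind == "shared":
            if len(members) < 2:
                return False
            carriers = _pick_carriers(rng, members, config.shared_carriers)
        else:
            carriers = frozenset(members)
        ref = base_seq[p]
        if ref == "N":
            return False
        if not force:
            reg.reserve(p, p + 1)
        events.append(
            TruthEvent(p, ref, _rand_base(rng, ref), carriers,
                       f"lattice_{kind}", group=g)
        )
        return True

    gap = config.site_spacing  # free space between triplets
    ci = 0

    def lay_triplets(lo, hi, inner, period):
        nonlocal ci
        for x in range(lo, hi - 2 * inner - 10, period):
            if not reg.is_free(x - 5, x + 2 * inner + 16):
                continue
            reg.reserve(x - 5, x + 2 * inner + 16)
            ok = add_site(x + int(rng.integers(0, 11)), "shared", focal, force=True)
            kind, g = cycle[ci % len(cycle)]
            ci += 1
            if ok:
                add_site(x + inner + int(rng.integers(0, 11)), kind, g, force=True)
            add_site(x + 2 * inner + int(rng.integers(0, 11)), "shared", focal,
                     force=True)

    inner = 70
    for zs, ze in reg.copy().free_intervals(ORIGIN_MARGIN, config.genome_length - ORIGIN_MARGIN):
        if ze - zs < 2 * inner + gap:
            continue
        lay_triplets(zs + 40, ze - 40, inner, 2 * inner + gap)
    # designed block: partner sites only -> focal-group diversity is zero
    for x in range(bs + 30, be - 30, 100):
        p = x + int(rng.integers(-10, 11))
        kind, g = cycle[ci % len(cycle)]
        ci += 1
        if bs + 10 <= p < be - 10:
            add_site(p, kind, g, force=True)
    # designated genes: the triplet pattern inside coding regions
    for gid in fs.designed_genes:
        s, e, _ = fs.gene_locations[gid][0]
        if e - s >= 260:
            lay_triplets(s + 30, e - 30, 60, 250)
    return events


def simulate_population(
    config: SimulationConfig, founder_set: FounderSet
) -> tuple[list[CircularGenome], TruthSet]:
    """Sample a population of accessions from the founders.

    Per-accession mutations are independent (star phylogeny); group-level
    structure comes from the founders and the shared-site lattice.  All
    events are recorded in the returned TruthSet; replaying the same
    config and founders is byte-identical.
    """
    fs = founder_set
    L = config.genome_length
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))
    reg = fs.registry.copy()

    counts = largest_remainder_counts(config.n_accessions, config.mitotype_proportions)
    labels: dict[str, str] = {}
    for g in config.groups:
        for i in range(counts[g]):
            labels[f"{g}_{i:02d}"] = g
    members_of = {g: [a for a, gg in labels.items() if gg == g] for g in config.groups}

    events: list[TruthEvent] = []
    # founder-level differences, re-expressed as events carried by every
    # group member (already baked into the founder sequences: the assembly
    # loop below skips founder-tagged events)
    for g in config.groups:
        members = frozenset(members_of[g])
        if not members or g == config.base_group:
            continue
        for pos, ref_seq, alt in fs.founder_events[g]:
            tag = "founder_marker" if abs(len(alt) - len(ref_seq)) > 10 else "founder_indel"
            events.append(TruthEvent(pos, ref_seq, alt, members, tag, group=g))

    # shared novel fragments at rearrangement breakpoints (-> scaffolds);
    # both junctions of an inversion can accumulate novel sequence
    fragments: list[dict] = []
    for g in config.groups:
        for a, b in fs.inversions.get(g, []):
            for bp in (a, b):
                if rng.random() >= config.unanchored_rate:
                    continue
                members = members_of[g]
                if len(members) < 2:
                    continue
                nc = int(rng.integers(2, len(members) + 1))
                carriers = _pick_carriers(rng, members, nc)
                seq = _random_seq(rng, int(rng.integers(300, 2001)), config.gc_content)
                fid = f"frag_{g}_{bp}"
                events.append(TruthEvent(bp, "", seq, carriers, "fragment", group=g))
                fragments.append(
                    {"id": fid, "seq": seq, "carriers": sorted(carriers),
                     "group": g, "pos": bp}
                )

    # deletable / duplicable genes: single-locus, outside inversions, not
    # profile-relevant, not carrying designed sites
    inv = [seg for segs in fs.inversions.values() for seg in segs]
    variant_ids = set(fs.profile.orfs) | set(fs.profile.markers)
    targets = []
    for g in fs.gene_set:
        locs = fs.gene_locations.get(g.id, [])
        if (len(locs) == 1 and g.id not in variant_ids
                and g.id not in fs.designed_genes and g.kind != "rRNA"):
            s, e, _ = locs[0]
            if not any(a <= s < b or a < e <= b for a, b in inv):
                targets.append(g)

    # pass 1: the population site lattice (triplets reserve their spans, so
    # later structural events can only fall in the gaps between them)
    if config.site_spacing:
        events.extend(_lattice_sites(config, fs, reg, rng, members_of))

    # pass 2: per-accession structural events
    copy_adjust: dict[str, dict[str, int]] = {a: {} for a in labels}
    for acc in labels:
        for _ in range(rng.poisson(config.small_indel_rate * L)):
            ln = int(rng.integers(1, 11))
            try:
                if rng.random() < 0.5:
                    p = reg.sample(rng, ln, MARGIN_INDEL)
                    events.append(TruthEvent(p, fs.base[p : p + ln], "",
                                             frozenset([acc]), "private_indel"))
                else:
                    p = reg.sample(rng, 1, MARGIN_INDEL)
                    events.append(TruthEvent(p, "", _random_seq(rng, ln, config.gc_content),
                                             frozenset([acc]), "private_indel"))
            except RuntimeError:
                break
        for _ in range(rng.poisson(config.large_insertion_rate)):
            ln = int(rng.integers(11, 1001))
            try:
                p = reg.sample(rng, 1, MARGIN_STRUCT)
            except RuntimeError:
                break
            events.append(TruthEvent(p, "", _random_seq(rng, ln, config.gc_content),
                                     frozenset([acc]), "insertion"))
        if targets and rng.random() < config.gene_deletion_rate:
            gene = targets[int(rng.integers(0, len(targets)))]
            s, e, _ = fs.gene_locations[gene.id][0]
            if not any(ev.pos == s and acc in ev.carriers for ev in events):
                events.append(TruthEvent(s, fs.base[s:e], "", frozenset([acc]), "gene_del"))
                copy_adjust[acc][gene.id] = copy_adjust[acc].get(gene.id, 0) - 1
        if targets and rng.random() < config.gene_duplication_rate:
            gene = targets[int(rng.integers(0, len(targets)))]
            try:
                p = reg.sample(rng, 1, MARGIN_STRUCT)
                events.append(TruthEvent(p, "", gene.genomic_seq, frozenset([acc]),
                                         "gene_dup"))
                copy_adjust[acc][gene.id] = copy_adjust[acc].get(gene.id, 0) + 1
            except RuntimeError:
                pass

    # pass 3: per-accession private SNPs (single-base, narrow margin)
    for acc in labels:
        for _ in range(rng.poisson(config.snp_rate * L)):
            try:
                p = reg.sample(rng, 1, MARGIN_POINT)
            except RuntimeError:
                break
            ref = fs.base[p]
            if ref == "N":
                continue
            events.append(TruthEvent(p, ref, _rand_base(rng, ref), frozenset([acc]),
                                     "private_snp"))

    # truth matrices
    exp = fs.profile.expected
    marker_matrix = pd.DataFrame(
        {acc: [bool(exp.loc[mid, labels[acc]]) for mid in exp.index] for acc in labels},
        index=list(exp.index),
    )
    variant_orfs = set(fs.profile.orfs)
    rows = {}
    for g in fs.gene_set:
        per_acc = []
        for acc in labels:
            if g.id in variant_orfs:
                cn = 1 if bool(exp.loc[g.id, labels[acc]]) else 0
            else:
                cn = len(fs.gene_locations.get(g.id, []))
            cn += copy_adjust[acc].get(g.id, 0)
            per_acc.append(cn)
        rows[g.id] = per_acc
    copy_numbers = pd.DataFrame.from_dict(rows, orient="index", columns=list(labels))

    # assemble accession sequences
    genomes: list[CircularGenome] = []
    rotations: dict[str, tuple[int, bool]] = {}
    for acc, g in labels.items():
        fshift = fs.shift(g)
        founder_seq = fs.founders[g].sequence
        acc_events = []
        for ev in events:
            if acc in ev.carriers and not ev.tag.startswith("founder"):
                fp = fshift(ev.pos)
                if ev.ref:
                    got = founder_seq[fp : fp + len(ev.ref)]
                    if got != ev.ref:
                        raise AssertionError(
                            f"{acc}: truth bookkeeping mismatch at {ev.pos}"
                        )
                acc_events.append((fp, ev.ref, ev.alt))
        seq = _apply_base_events(founder_seq, acc_events)
        if config.randomize_rotation:
            off = int(rng.integers(0, len(seq)))
            flip = bool(rng.random() < 0.5)
            out = rotate(seq, off)
            if flip:
                out = revcomp(out)
        else:
            off, flip = 0, False
            out = seq
        rotations[acc] = (off, flip)
        genomes.append(CircularGenome(acc, out, mitotype=g))

    truth = TruthSet(
        config=config,
        founder_set=fs,
        labels=labels,
        events=sorted(events, key=lambda e: (e.pos, e.tag)),
        marker_matrix=marker_matrix,
        copy_numbers=copy_numbers,
        fragments=fragments,
        rotations=rotations,
        rod_block=fs.rod_block,
    )
    return genomes, truth


def simulate_read_placements(
    genome: CircularGenome,
    config: SimulationConfig,
    seed: int | None = None,
    mask: tuple[int, int] | None = None,
):
    """Error-free read placements tiling the circle evenly.

    Start sites are spread evenly around the circle (for the default 150 bp
    reads at 150x this is one start per position, giving exactly the target
    depth everywhere).  ``mask`` suppresses read *starts* inside an
    interval, creating a known structural-QC gap -- the signature a real
    assembly breakpoint leaves even when flanking reads still overlap it.
    """
    from .assembly_qc import Placements

    if config.read_depth < 1:
        raise ValueError("read depth must be >= 1")
    L = len(genome)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed if seed is None else seed), 3])
    )
    n = int(round(config.read_depth * L / config.read_length))
    starts = (np.arange(n, dtype=np.int64) * L) // n
    if mask is not None:
        s, e = mask
        starts = starts[~((starts >= s) & (starts < e))]
    strands = np.where(rng.random(len(starts)) < 0.5, "+", "-")
    return Placements.build(genome.id, starts, length=config.read_length,
                            strand=strands, exact=True)
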
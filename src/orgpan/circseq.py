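"""Circular-sequence model and a pairwise aligner for near-identical genomes.

Assembled organelle genomes are circular molecules with an arbitrary
sequencing start and strand.  This module provides

* :class:`CircularGenome` -- the basic container,
* :func:`normalize_rotation` -- put a genome into the rotation/strand frame
  of a reference by unique k-mer voting,
* :func:`align_pair` -- a sparse whole-genome aligner: unique k-mer anchors,
  collinear chaining and banded closing of inter-anchor intervals (edit
  distance via edlib), suitable for genomes that are >90% identical,
* :func:`diff_from_chains` -- turn an alignment into SNPs, small indels
  (<=10 bp), large insertions (>10 bp), large deletions and unanchored
  query intervals (>100 bp),
* a round-trip oracle: :func:`reconstruct_query` rebuilds the query from the
  subject plus the alignment, which is the module's correctness standard.

Coordinates are 0-based half-open throughout; conversion to 1-based happens
only in VCF/GFF/BED writers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: maximum inter-anchor interval (bp) closed by banded alignment
DEFAULT_BAND = 5000
#: gap runs up to this length are small indels; longer query-side gaps are
#: insertion fragments, longer subject-side gaps are deletions
SMALL_INDEL_MAX = 10
#: unanchored query intervals must exceed this length to be reported
UNANCHORED_MIN = 100


class UnalignableError(ValueError):
    """No anchor chain could be found between two sequences."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def rotate(seq: str, offset: int) -> str:
    """Rotate a circular sequence so that ``seq[offset]`` becomes position 0."""
    offset %= len(seq)
    return seq[offset:] + seq[:offset]


@dataclass
class CircularGenome:
    """One accession's assembled organelle sequence.

    Parameters
    ----------
    id : accession identifier
    sequence : DNA string over {A, C, G, T, N}
    circular : circular topology flag
    mitotype : cytoplasm haplotype label when known (truth or called)
    """

    id: str
    sequence: str
    circular: bool = True
    mitotype: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        if re.search("[^ACGTN]", self.sequence):
            raise ValueError(f"{self.id}: sequence contains non-ACGTN characters")
        n_frac = self.sequence.count("N") / len(self.sequence)
        if n_frac >= 0.05:
            raise ValueError(f"{self.id}: N fraction {n_frac:.2f} >= 5%")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def gc_content(self) -> float:
        s = self.sequence
        return (s.count("G") + s.count("C")) / len(s)


# ---------------------------------------------------------------------------
# FASTA I/O (wrapped 60 columns, upper case)
# ---------------------------------------------------------------------------

def write_fasta(records, path, wrap: int = 60) -> None:
    """Write ``(id, sequence)`` pairs or CircularGenome objects as FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, CircularGenome):
                name, seq = rec.id, rec.sequence
            else:
                name, seq = rec
            fh.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def read_fasta(path, circular: bool = True) -> list[CircularGenome]:
    """Read a multi-FASTA into CircularGenome records (description dropped)."""
    from Bio import SeqIO

    return [
        CircularGenome(rec.id, str(rec.seq).upper(), circular=circular)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


# ---------------------------------------------------------------------------
# k-mer anchoring
# ---------------------------------------------------------------------------

def _subject_index(seq: str, k: int) -> dict[str, int]:
    """Positions of k-mers that occur exactly once in ``seq`` counting both
    strands (a k-mer shared with the reverse complement, e.g. inside an
    inverted repeat, is excluded)."""
    counts: dict[str, int] = {}
    pos: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        c = counts.get(km)
        if c is None:
            counts[km] = 1
            pos[km] = i
        else:
            counts[km] = c + 1
    rc = revcomp(seq)
    for i in range(len(rc) - k + 1):
        km = rc[i : i + k]
        if km in counts:
            counts[km] += 1
    return {km: p for km, p in pos.items() if counts[km] == 1}


def _index_for(genome: CircularGenome, k: int) -> dict[str, int]:
    cache = genome.__dict__.setdefault("_kmer_index_cache", {})
    if k not in cache:
        cache[k] = _subject_index(genome.sequence, k)
    return cache[k]


def evict_index(genome: CircularGenome) -> None:
    """Drop a genome's cached k-mer index (memory control in all-vs-all)."""
    genome.__dict__.pop("_kmer_index_cache", None)


def _sample_positions(n_kmers: int, stride: int):
    pos = list(range(0, n_kmers, stride))
    if pos and pos[-1] != n_kmers - 1:
        pos.append(n_kmers - 1)
    return pos


def _collect_anchors(query: str, index: dict[str, int], k: int, stride: int):
    """Return (plus, minus) anchor lists.  Plus anchors are (q, s) with
    query[q:q+k] == subject[s:s+k]; minus anchors are expressed in the
    reverse-complemented query frame q' = Lq - k - q so that both lists
    chain with the same forward machinery."""
    lq = len(query)
    plus: list[tuple[int, int]] = []
    minus: list[tuple[int, int]] = []
    for q in _sample_positions(lq - k + 1, stride):
        km = query[q : q + k]
        s = index.get(km)
        if s is not None:
            plus.append((q, s))
            continue
        s = index.get(revcomp(km))
        if s is not None:
            minus.append((lq - k - q, s))
    # one-to-one: drop anchors whose subject position is hit more than once
    # (query-side repeats that survived subject uniqueness)
    for lst in (plus, minus):
        seen: dict[int, int] = {}
        for _, s in lst:
            seen[s] = seen.get(s, 0) + 1
        lst[:] = [(q, s) for q, s in lst if seen[s] == 1]
    minus.sort()
    return plus, minus


# ---------------------------------------------------------------------------
# chains, events, diffs
# ---------------------------------------------------------------------------

@dataclass
class Event:
    """A replacement of subject[s_start:s_end] by ``alt`` (subject strand)."""

    s_start: int
    s_end: int
    alt: str

    @property
    def ref_len(self) -> int:
        return self.s_end - self.s_start

    @property
    def kind(self) -> str:
        rl, al = self.ref_len, len(self.alt)
        if rl == 1 and al == 1:
            return "SNP"
        if al - rl > SMALL_INDEL_MAX:
            return "insertion"
        if rl - al > SMALL_INDEL_MAX:
            return "deletion"
        return "InDel"


@dataclass
class AlignmentChain:
    """A maximal collinear run of anchors with closed inter-anchor intervals.

    ``blocks`` are exact-match runs (q_start0, s_start0, length, strand);
    ``events`` are the differences found while closing the intervals between
    blocks.  For strand '-', query coordinates of the chain span refer to the
    original (forward) query sequence while events stay in subject frame.
    """

    query_id: str
    subject_id: str
    strand: str
    blocks: list[tuple[int, int, int, str]]
    events: list[Event]
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    matches: int
    columns: int
    identity: float = field(init=False)
    query_coverage: float = 0.0
    subject_coverage: float = 0.0

    def __post_init__(self) -> None:
        self.identity = self.matches / self.columns if self.columns else 0.0

    @property
    def q_span(self) -> tuple[int, int]:
        return self.q_start, self.q_end

    @property
    def s_span(self) -> tuple[int, int]:
        return self.s_start, self.s_end


def _parse_cigar(cigar: str, qseg: str, s_off: int):
    """Parse an edlib extended cigar for (qseg vs sseg) into raw events.

    Returns (raw, matches, columns) where raw items are
    (s_start, s_end, q_start, q_end) intervals of non-matching columns.
    ``s_off`` is the absolute subject coordinate of sseg[0]; 'I' consumes
    query only, 'D' subject only.
    """
    raw: list[list[int]] = []
    matches = cols = 0
    qi = 0
    si = s_off
    for num, op in re.findall(r"(\d+)([=XID])", cigar):
        n = int(num)
        cols += n
        if op == "=":
            matches += n
            qi += n
            si += n
            continue
        dq = n if op in "XI" else 0
        ds = n if op in "XD" else 0
        raw.append([si, si + ds, qi, qi + dq])
        qi += dq
        si += ds
    return raw, matches, cols


#: adjacent non-match intervals separated by at most this many matched
#: columns are merged before canonicalization -- edit-distance alignments
#: place co-optimal gaps arbitrarily and would otherwise fragment one
#: biological indel into several events
_EVENT_MERGE_GAP = 5


def _canonical_events(raw, qseg: str) -> list[Event]:
    """Merge clustered raw intervals and trim shared flanks.

    Produces minimal replacement events: a biological insertion whose
    alignment was fragmented collapses back to a single pure-gap event.
    """
    events: list[Event] = []
    i = 0
    while i < len(raw):
        s0, s1, q0, q1 = raw[i]
        j = i + 1
        while j < len(raw) and raw[j][0] - s1 <= _EVENT_MERGE_GAP:
            s1 = raw[j][1]
            q1 = raw[j][3]
            j += 1
        i = j
        # matched columns swallowed by merging reappear as shared flanks of
        # (ref, alt) and are trimmed away again by _trim_event
        events.append(Event(s0, s1, qseg[q0:q1]))
    return events


def _trim_event(ev: Event, sseq: str) -> Event:
    ref = sseq[ev.s_start : ev.s_end]
    alt = ev.alt
    s0, s1 = ev.s_start, ev.s_end
    while ref and alt and ref[0] == alt[0]:
        ref = ref[1:]
        alt = alt[1:]
        s0 += 1
    while ref and alt and ref[-1] == alt[-1]:
        ref = ref[:-1]
        alt = alt[:-1]
        s1 -= 1
    return Event(s0, s1, alt)


class _Shifted:
    """View of a segment addressed by absolute subject coordinates."""

    def __init__(self, seg: str, off: int):
        self._seg = seg
        self._off = off

    def __getitem__(self, item):
        if isinstance(item, slice):
            return self._seg[item.start - self._off : item.stop - self._off]
        return self._seg[item - self._off]


def _event_columns(ev: Event) -> int:
    """Aligned-column contribution of an event to chain identity.

    Small events (SNPs, indels <= 10 bp) count their full span; structural
    one-sided gaps (insertion fragments, large deletions) contribute only
    the aligned residue, so an accession simply lacking a fragment is not
    penalized as divergence -- identity stays a substitution-level measure.
    """
    rl, al = ev.ref_len, len(ev.alt)
    if abs(rl - al) <= SMALL_INDEL_MAX:
        return max(rl, al)
    return min(rl, al)


def _split_complex(ev: Event, view) -> list[Event]:
    """Decompose a structural event that carries a replaced residue.

    Edit-distance alignments of very asymmetric intervals scatter matches
    through the gap (threading single bases is cheaper than paying for a
    flank substitution), which merges a nearby SNP into the indel.  The
    short side is re-assigned to the long side's two ends at minimal
    Hamming cost, yielding flank substitutions plus one pure gap."""
    ref = view[ev.s_start : ev.s_end]
    alt = ev.alt
    short, long_ = (alt, ref) if len(alt) <= len(ref) else (ref, alt)
    m, n = len(short), len(long_)
    if m == 0 or n - m <= SMALL_INDEL_MAX:
        return [ev]
    pre = [0] * (m + 1)
    suf = [0] * (m + 1)
    for j in range(m):
        pre[j + 1] = pre[j] + (short[j] != long_[j])
        suf[j + 1] = suf[j] + (short[m - 1 - j] != long_[n - 1 - j])
    best_i, best_cost = 0, m + 1
    for i in range(m + 1):
        cost = pre[i] + suf[m - i]
        if cost < best_cost or (cost == best_cost and i > best_i):
            best_i, best_cost = i, cost
    if best_cost > 0.2 * m + 1:
        return [ev]
    i = best_i
    out: list[Event] = []
    deletion = len(ref) > len(alt)
    for j in range(i):  # prefix substitutions
        if short[j] != long_[j]:
            out.append(Event(ev.s_start + j, ev.s_start + j + 1, alt[j]))
    gap = long_[i : n - (m - i)]
    if deletion:
        out.append(Event(ev.s_start + i, ev.s_start + i + len(gap), ""))
        tail0 = ev.s_start + i + len(gap)
    else:
        out.append(Event(ev.s_start + i, ev.s_start + i, gap))
        tail0 = ev.s_start + i
    for j in range(m - i):  # suffix substitutions
        qc = short[i + j] if deletion else long_[n - (m - i) + j]
        sc = long_[n - (m - i) + j] if deletion else short[i + j]
        if qc != sc:
            alt_base = alt[i + j] if deletion else alt[len(alt) - (m - i) + j]
            out.append(Event(tail0 + j, tail0 + j + 1, alt_base))
    return out


def _close_interval(qseg: str, sseg: str, s_off: int):
    """Close one inter-anchor interval, returning (events, matches, columns).

    Columns are aligned columns (see :func:`_event_columns`)."""
    if not qseg and not sseg:
        return [], 0, 0
    if not sseg:
        ev = Event(s_off, s_off, qseg)
        return [ev], 0, _event_columns(ev)
    if not qseg:
        ev = Event(s_off, s_off + len(sseg), "")
        return [ev], 0, _event_columns(ev)
    res = edlib.align(qseg, sseg, task="path", mode="NW")
    raw, matches, _ = _parse_cigar(res["cigar"], qseg, s_off)
    view = _Shifted(sseg, s_off)
    events = []
    for ev in _canonical_events(raw, qseg):
        ev = _trim_event(ev, view)
        if ev.s_start == ev.s_end and not ev.alt:
            continue
        if ev.ref_len == len(ev.alt) and ev.ref_len > 1:
            # equal-length replacement from merged nearby substitutions:
            # report the mismatching columns as individual SNPs
            for j in range(ev.ref_len):
                if view[ev.s_start + j] != ev.alt[j]:
                    events.append(Event(ev.s_start + j, ev.s_start + j + 1, ev.alt[j]))
        elif abs(ev.ref_len - len(ev.alt)) > SMALL_INDEL_MAX and \
                min(ev.ref_len, len(ev.alt)) > 0:
            events.extend(_split_complex(ev, view))
        else:
            events.append(ev)
    cols = matches + sum(_event_columns(ev) for ev in events)
    return events, matches, cols


def _joinable(gq: int, gs: int, band: int) -> bool:
    """Any interval pair within the band is closed; closures that turn out
    to be dissimilar are split again afterwards (see MIN_CLOSURE_IDENTITY),
    so joining can be permissive."""
    if gq < 0 or gs < 0:
        return False
    return gq <= band and gs <= band


def _build_chains(anchors, qseq: str, k: int, band: int):
    """Group collinear anchors into chains; each chain is a list of exact
    blocks [(q, s, length)] plus the raw anchor boundaries for closing."""
    chains: list[list[list[int]]] = []  # each chain: list of [q, s, length]
    cur: list[list[int]] | None = None
    for q, s in sorted(anchors):
        if cur is not None:
            bq, bs, bl = cur[-1]
            dq, ds = q - bq, s - bs
            if dq <= 0:
                continue
            if dq == ds and dq <= bl:
                # same diagonal, overlapping/contiguous exact run
                cur[-1][2] = q + k - bq
                continue
            gq = q - (bq + bl)
            gs = s - (bs + bl)
            ln = k
            if (gq < 0 or gs < 0) and min(gq, gs) > -(k - 15):
                # anchors overlapping across a diagonal change (an indel
                # boundary shares a few bases): trim the incoming anchor
                ov = max(-gq, -gs)
                q, s, ln = q + ov, s + ov, k - ov
                gq += ov
                gs += ov
            if _joinable(gq, gs, band):
                cur.append([q, s, ln])
                continue
        cur = [[q, s, k]]
        chains.append(cur)
    return chains


#: a closed inter-anchor interval below this identity (over >= 30 columns)
#: splits the chain instead of polluting it -- the interval is then either
#: covered by a chain on the other strand or reported as unanchored
MIN_CLOSURE_IDENTITY = 0.66


def _finalize_chain(blocks, qseq, sseq, qid, sid, strand, band, lq):
    """Close gaps between blocks of one chain and compute its statistics.

    ``blocks``/coordinates are in the (possibly revcomp'd) query frame used
    for chaining; the returned chains report the original-query span.  A
    closure whose identity is below :data:`MIN_CLOSURE_IDENTITY` splits the
    chain at that interval (returning more than one chain).
    """
    pieces: list[tuple[list, list[Event], int, int]] = []
    cur_blocks = [blocks[0]]
    events: list[Event] = []
    matches = cols = blocks[0][2]
    for i in range(1, len(blocks)):
        pq, ps, pl = cur_blocks[-1]
        q, s, ln = blocks[i]
        qseg, sseg = qseq[pq + pl : q], sseq[ps + pl : s]
        ev, m, c = _close_interval(qseg, sseg, ps + pl)
        # a closure is untrustworthy when even the smaller side aligns
        # poorly -- one-sided gaps (insertions/deletions with short flank
        # residuals) have m ~= min side and are fine
        lo = min(len(qseg), len(sseg))
        bad = lo >= 30 and m / lo < MIN_CLOSURE_IDENTITY
        if bad:
            pieces.append((cur_blocks, events, matches, cols))
            cur_blocks = [blocks[i]]
            events = []
            matches = cols = ln
        else:
            events.extend(ev)
            matches += m
            cols += c + ln
            matches += ln
            cur_blocks.append(blocks[i])
    pieces.append((cur_blocks, events, matches, cols))

    chains = []
    for cur_blocks, events, matches, cols in pieces:
        q0, s0 = cur_blocks[0][0], cur_blocks[0][1]
        q1 = cur_blocks[-1][0] + cur_blocks[-1][2]
        s1 = cur_blocks[-1][1] + cur_blocks[-1][2]
        if strand == "+":
            oq0, oq1 = q0, q1
            blk = [(q, s, ln, "+") for q, s, ln in cur_blocks]
        else:
            oq0, oq1 = lq - q1, lq - q0
            blk = [(lq - (q + ln), s, ln, "-") for q, s, ln in cur_blocks]
        chains.append(
            AlignmentChain(
                query_id=qid,
                subject_id=sid,
                strand=strand,
                blocks=blk,
                events=sorted(events, key=lambda e: e.s_start),
                q_start=oq0,
                q_end=oq1,
                s_start=s0,
                s_end=s1,
                matches=matches,
                columns=cols,
            )
        )
    return chains


def _merge_adjacent_chains(chains: list[AlignmentChain], qseq: str, sseq: str,
                           band: int) -> list[AlignmentChain]:
    """Stitch consecutive same-strand chains whose gap is closable.

    A handful of stray anchors (e.g. a duplicated gene matching its source
    locus) can split one collinear run into two chains; once the stray
    mini-chain is dropped by overlap resolution, the flanking chains abut
    and are merged, closing the gap so its events are not lost."""
    if len(chains) < 2:
        return chains
    chains = sorted(chains, key=lambda c: c.q_start)
    out = [chains[0]]
    for c in chains[1:]:
        a = out[-1]
        gq = c.q_start - a.q_end
        gs = c.s_start - a.s_end
        if a.strand == c.strand == "+" and gq >= 0 and gs >= 0 and \
                _joinable(gq, gs, band):
            ev, m, cols = _close_interval(
                qseq[a.q_end : c.q_start], sseq[a.s_end : c.s_start], a.s_end
            )
            lo = min(gq, gs)
            if not (lo >= 30 and m / lo < MIN_CLOSURE_IDENTITY):
                a.events = sorted(a.events + ev + c.events, key=lambda e: e.s_start)
                a.blocks = a.blocks + c.blocks
                a.q_end, a.s_end = c.q_end, c.s_end
                a.matches += m + c.matches
                a.columns += cols + c.columns
                a.identity = a.matches / a.columns if a.columns else 0.0
                continue
        out.append(c)
    return out


def _close_circular_junction(chains, qseq: str, sseq: str, band: int) -> None:
    """Close the wrap gap between the chain reaching the subject's end and
    the chain starting near its origin (both sequences are circles; the
    linearized alignment leaves a sliver at the junction).  Events are
    split at the subject origin so coordinates stay linear."""
    lq, ls = len(qseq), len(sseq)
    plus = [c for c in chains if c.strand == "+"]
    if len(plus) < 2:
        return
    c_hi = max(plus, key=lambda c: c.s_end)
    c_lo = min(plus, key=lambda c: c.s_start)
    if c_hi is c_lo:
        return
    qg = c_lo.q_start - c_hi.q_end
    sg = (ls - c_hi.s_end) + c_lo.s_start
    if qg < 0 or (qg == 0 and sg == 0) or not _joinable(qg, sg, band):
        return
    qseg = qseq[c_hi.q_end : c_lo.q_start]
    sseg = sseq[c_hi.s_end :] + sseq[: c_lo.s_start]
    ev, m, cols = _close_interval(qseg, sseg, c_hi.s_end)
    ev1: list[Event] = []
    ev2: list[Event] = []
    for e in ev:
        if e.s_end <= ls:
            ev1.append(e)
        elif e.s_start >= ls:
            ev2.append(Event(e.s_start - ls, e.s_end - ls, e.alt))
        elif not e.alt:  # pure deletion straddling the origin: split it
            ev1.append(Event(e.s_start, ls, ""))
            ev2.append(Event(0, e.s_end - ls, ""))
        else:
            return  # origin-straddling replacement: leave the sliver open
    q1 = (ls - c_hi.s_end) + sum(len(e.alt) - e.ref_len for e in ev1)
    if not 0 <= q1 <= qg:
        return
    c_hi.events = sorted(c_hi.events + ev1, key=lambda e: e.s_start)
    c_hi.q_end += q1
    c_hi.s_end = ls
    c_hi.matches += m
    c_hi.columns += cols
    c_hi.identity = c_hi.matches / c_hi.columns if c_hi.columns else 0.0
    c_lo.events = sorted(ev2 + c_lo.events, key=lambda e: e.s_start)
    c_lo.q_start = c_hi.q_end
    c_lo.s_start = 0
    c_lo.identity = c_lo.matches / c_lo.columns if c_lo.columns else 0.0


def _split_closure_at_query(events, s_off: int, q_target: int):
    """Cut a closed interval's event list where the query has consumed
    exactly ``q_target`` bases; returns (ev1, ev2, s_cut) or None when the
    cut would fall inside an event."""
    qc = 0
    s_cur = s_off
    ev1: list[Event] = []
    for idx, e in enumerate(events):
        match_len = e.s_start - s_cur
        if qc + match_len >= q_target:
            return ev1, events[idx:], s_cur + (q_target - qc)
        qc += match_len
        if qc + len(e.alt) > q_target:
            return None
        qc += len(e.alt)
        s_cur = e.s_end
        ev1.append(e)
    return ev1, [], s_cur + (q_target - qc)


def _close_query_wrap(chains, qseq: str, sseq: str, band: int) -> None:
    """Close the wrap gap when the query's origin falls mid-subject: the
    chain reaching the query's end and the chain starting at its origin
    flank a contiguous subject sliver."""
    lq = len(qseq)
    plus = [c for c in chains if c.strand == "+"]
    if len(plus) < 2:
        return
    d_hi = max(plus, key=lambda c: c.q_end)
    d_lo = min(plus, key=lambda c: c.q_start)
    if d_hi is d_lo:
        return
    sg = d_lo.s_start - d_hi.s_end
    qg = (lq - d_hi.q_end) + d_lo.q_start
    if sg < 0 or (qg == 0 and sg == 0) or not _joinable(qg, sg, band):
        return
    qseg = qseq[d_hi.q_end :] + qseq[: d_lo.q_start]
    sseg = sseq[d_hi.s_end : d_lo.s_start]
    ev, m, cols = _close_interval(qseg, sseg, d_hi.s_end)
    split = _split_closure_at_query(ev, d_hi.s_end, lq - d_hi.q_end)
    if split is None:
        return
    ev1, ev2, s_cut = split
    if not d_hi.s_end <= s_cut <= d_lo.s_start:
        return
    d_hi.events = sorted(d_hi.events + ev1, key=lambda e: e.s_start)
    d_hi.q_end = lq
    d_hi.s_end = s_cut
    d_hi.matches += m
    d_hi.columns += cols
    d_hi.identity = d_hi.matches / d_hi.columns if d_hi.columns else 0.0
    d_lo.events = sorted(ev2 + d_lo.events, key=lambda e: e.s_start)
    d_lo.q_start = 0
    d_lo.s_start = s_cut
    d_lo.identity = d_lo.matches / d_lo.columns if d_lo.columns else 0.0


def align_pair(
    query: CircularGenome,
    subject: CircularGenome,
    k: int = 31,
    stride: int = 8,
    band: int = DEFAULT_BAND,
    min_identity: float = 0.9,
    min_span: int = 60,
) -> list[AlignmentChain]:
    """Align two normalized near-identical genomes.

    Anchors are k-mers unique in both sequences (counting both strands);
    maximal collinear anchor runs become chains.  Inter-anchor intervals up
    to ``band`` bp on both sides are closed by global edit-distance
    alignment (pure one-sided gaps become insertion/deletion events
    directly); a closure whose smaller side matches poorly splits the
    chain, which is how rearranged segments end up in their own
    (minus-strand) chains.  Chains with substitution-level identity below
    ``min_identity`` are discarded, subject double-coverage from the
    circular wrap is resolved, and the two wrap junctions are closed.
    """
    if k < 15:
        raise ValueError("anchor length k must be >= 15")
    if not query.sequence or not subject.sequence:
        raise ValueError("empty sequence")
    if k > len(query) or k > len(subject):
        raise ValueError("k larger than sequence")
    qseq, sseq = query.sequence, subject.sequence
    lq, ls = len(qseq), len(sseq)
    index = _index_for(subject, k)
    plus, minus = _collect_anchors(qseq, index, k, stride)
    qrc = revcomp(qseq)

    raw: list[AlignmentChain] = []
    for strand, anchors, frame_seq in (("+", plus, qseq), ("-", minus, qrc)):
        if not anchors:
            continue
        for blocks in _build_chains(anchors, frame_seq, k, band):
            raw.extend(
                _finalize_chain(blocks, frame_seq, sseq, query.id, subject.id, strand, band, lq)
            )

    # terminal closure: extend the plus chain that starts earliest / ends
    # latest on the query towards the sequence ends (circular junction).
    plus_chains = [c for c in raw if c.strand == "+"]
    if plus_chains:
        head = min(plus_chains, key=lambda c: c.q_start)
        # terminal gaps are genuine only when both sides are short and
        # comparable; a large one-sided head gap means the rotation frame
        # wraps and the region is covered by the tail chain instead
        if (0 < head.q_start and 0 < head.s_start
                and max(head.q_start, head.s_start) <= 200
                and _joinable(head.q_start, head.s_start, band)):
            ev, m, c = _close_interval(qseq[: head.q_start], sseq[: head.s_start], 0)
            head.events = sorted(ev + head.events, key=lambda e: e.s_start)
            head.matches += m
            head.columns += c
            head.q_start = 0
            head.s_start = 0
            head.identity = head.matches / head.columns
        tail = max(plus_chains, key=lambda c: c.q_end)
        gq, gs = lq - tail.q_end, ls - tail.s_end
        if 0 < gq and 0 < gs and max(gq, gs) <= 200 and _joinable(gq, gs, band):
            ev, m, c = _close_interval(qseq[tail.q_end :], sseq[tail.s_end :], tail.s_end)
            tail.events = sorted(tail.events + ev, key=lambda e: e.s_start)
            tail.matches += m
            tail.columns += c
            tail.q_end = lq
            tail.s_end = ls
            tail.identity = tail.matches / tail.columns

    chains = [
        c
        for c in raw
        if c.identity >= min_identity and (c.q_end - c.q_start) >= min_span
    ]
    # resolve subject double-coverage (a circular wrap can make the query
    # head re-cover the subject tail): keep larger chains greedily; the
    # dropped chain's query span remains an uncovered gap
    chains.sort(key=lambda c: -c.columns)
    kept: list[AlignmentChain] = []
    for c in chains:
        if all(c.s_end <= k.s_start or c.s_start >= k.s_end for k in kept):
            kept.append(c)
    chains = kept
    if not chains:
        raise UnalignableError(f"{query.id} vs {subject.id}: no chain at identity >= {min_identity}")
    chains = _merge_adjacent_chains(chains, qseq, sseq, band)
    if query.circular and subject.circular:
        _close_circular_junction(chains, qseq, sseq, band)
        _close_query_wrap(chains, qseq, sseq, band)
    qcov = sum(c.q_end - c.q_start for c in chains) / lq
    scov = sum(c.s_end - c.s_start for c in chains) / ls
    for c in chains:
        c.query_coverage = min(qcov, 1.0)
        c.subject_coverage = min(scov, 1.0)
    chains.sort(key=lambda c: c.q_start)
    return chains


# ---------------------------------------------------------------------------
# rotation / strand normalization
# ---------------------------------------------------------------------------

def normalize_rotation(
    g: CircularGenome,
    ref: CircularGenome,
    k: int = 31,
    stride: int = 8,
    min_votes: int = 5,
) -> CircularGenome:
    """Return ``g`` rotated (and strand-flipped if needed) into the frame of
    ``ref``.

    Every sampled k-mer of ``g`` that is unique in ``ref`` votes for the
    rotation offset ``(q - s) mod len(g)``; the strand/offset pair with the
    most votes wins, ties broken towards '+' strand and the smallest offset
    (idempotent: a normalized genome wins with offset 0).
    """
    index = _index_for(ref, k)
    lg = len(g)
    best = None  # (votes, strand_rank, offset)
    for strand, seq in (("+", g.sequence), ("-", revcomp(g.sequence))):
        votes: dict[int, int] = {}
        for q in _sample_positions(lg - k + 1, stride):
            s = index.get(seq[q : q + k])
            if s is not None:
                off = (q - s) % lg
                votes[off] = votes.get(off, 0) + 1
        if not votes:
            continue
        n, off = max((n, -o) for o, n in votes.items())
        off = -off
        cand = (n, 0 if strand == "+" else 1, off, strand)
        if best is None or (cand[0], -cand[1], -cand[2]) > (best[0], -best[1], -best[2]):
            best = cand
    if best is None or best[0] < min_votes:
        raise UnalignableError(f"{g.id}: unalignable to {ref.id} (no anchor support)")
    n, _, off, strand = best
    seq = g.sequence if strand == "+" else revcomp(g.sequence)
    return CircularGenome(g.id, rotate(seq, off), circular=g.circular, mitotype=g.mitotype)


# ---------------------------------------------------------------------------
# diffs
# ---------------------------------------------------------------------------

@dataclass
class AlignmentDiff:
    """Categorized differences of a query against a subject genome.

    ``snps`` are (s_pos0, ref_base, alt_base); ``small_indels`` are
    (s_pos0, ref_allele, alt_allele) with length difference 1..10 (alleles
    are the raw replaced/replacement segments, either may be empty);
    ``insertions`` are (s_pos0, inserted_seq) with length > 10;
    ``deletions`` are (s_pos0, deleted_len) with length > 10;
    ``unanchored`` are (q_start0, q_end0, seq) query intervals > 100 bp
    covered by no chain.  ``gaps`` keeps every uncovered query interval
    regardless of size so the alignment stays invertible.
    """

    query_id: str
    subject_id: str
    snps: list[tuple[int, str, str]] = field(default_factory=list)
    small_indels: list[tuple[int, str, str]] = field(default_factory=list)
    insertions: list[tuple[int, str]] = field(default_factory=list)
    deletions: list[tuple[int, int]] = field(default_factory=list)
    unanchored: list[tuple[int, int, str]] = field(default_factory=list)
    gaps: list[tuple[int, int, str]] = field(default_factory=list)
    events: list[Event] = field(default_factory=list)


def diff_from_chains(
    chains: list[AlignmentChain],
    query: CircularGenome,
    subject: CircularGenome,
) -> AlignmentDiff:
    """Categorize all chain events plus uncovered query intervals.

    Chains must be non-overlapping on the subject (raises ValueError
    otherwise, mirroring the aligner's collinearity contract).
    """
    by_s = sorted(chains, key=lambda c: c.s_start)
    for a, b in zip(by_s, by_s[1:]):
        if b.s_start < a.s_end:
            raise ValueError("overlapping chains on subject")
    sseq = subject.sequence
    diff = AlignmentDiff(query.id, subject.id)

    def _junction_echo(ev: Event) -> bool:
        # an insertion right at the subject junction whose content matches
        # junction-adjacent sequence on the circle is a rotation artifact,
        # not novel sequence (the wrap duplicated origin-adjacent bases,
        # possibly spanning the origin itself)
        if not subject.circular:
            return False
        n = len(ev.alt)
        if ev.s_start > 50 and ev.s_start < len(sseq) - 50:
            return False
        window = sseq[-(n + 20):] + sseq[: n + 20]
        d = edlib.align(ev.alt, window, mode="HW")["editDistance"]
        return 0 <= d <= max(1, 0.1 * n)

    for ch in chains:
        for ev in ch.events:
            diff.events.append(ev)
            kind = ev.kind
            if kind == "SNP":
                diff.snps.append((ev.s_start, sseq[ev.s_start], ev.alt))
            elif kind == "insertion":
                if _junction_echo(ev):
                    continue
                diff.insertions.append((ev.s_start, ev.alt))
            elif kind == "deletion":
                diff.deletions.append((ev.s_start, ev.ref_len))
            else:
                diff.small_indels.append(
                    (ev.s_start, sseq[ev.s_start : ev.s_end], ev.alt)
                )
    # uncovered query intervals
    qseq = query.sequence
    covered = sorted((c.q_start, c.q_end) for c in chains)
    cursor = 0
    for qs, qe in covered:
        if qs > cursor:
            diff.gaps.append((cursor, qs, qseq[cursor:qs]))
        cursor = max(cursor, qe)
    if cursor < len(qseq):
        diff.gaps.append((cursor, len(qseq), qseq[cursor:]))
    # an unanchored fragment is sequence absent from the subject; uncovered
    # intervals that do align somewhere (wrap artifacts, repeats) don't count
    diff.unanchored = [
        g for g in diff.gaps
        if g[1] - g[0] > UNANCHORED_MIN and not _aligns_somewhere(g[2], subject)
    ]
    diff.events.sort(key=lambda e: e.s_start)
    return diff


def _aligns_somewhere(seq: str, subject: CircularGenome, min_identity: float = 0.9) -> bool:
    doubled = subject.sequence + subject.sequence
    for q in (seq, revcomp(seq)):
        d = edlib.align(q, doubled, mode="HW")["editDistance"]
        if d >= 0 and 1 - d / len(q) >= min_identity:
            return True
    return False


def apply_events(seq: str, events: list[Event]) -> str:
    """Apply non-overlapping replacement events (subject coords) to ``seq``."""
    out = []
    cursor = 0
    for ev in sorted(events, key=lambda e: e.s_start):
        if ev.s_start < cursor:
            raise ValueError("overlapping events")
        out.append(seq[cursor : ev.s_start])
        out.append(ev.alt)
        cursor = ev.s_end
    out.append(seq[cursor:])
    return "".join(out)


def reconstruct_query(
    chains: list[AlignmentChain], diff: AlignmentDiff, subject: CircularGenome
) -> str:
    """Rebuild the query sequence from the subject and an alignment.

    This is the module's round-trip oracle: for any pair produced by the
    aligner the result must equal the query byte-for-byte.
    """
    sseq = subject.sequence
    pieces: list[tuple[int, str]] = []
    for ch in chains:
        seg = apply_events(sseq[ch.s_start : ch.s_end],
                           [Event(e.s_start - ch.s_start, e.s_end - ch.s_start, e.alt)
                            for e in ch.events])
        if ch.strand == "-":
            seg = revcomp(seg)
        pieces.append((ch.q_start, seg))
    for qs, qe, seq in diff.gaps:
        pieces.append((qs, seq))
    pieces.sort()
    return "".join(seg for _, seg in pieces)


# ---------------------------------------------------------------------------
# tabular chain dump (BLAST outfmt-6 flavoured)
# ---------------------------------------------------------------------------

def circular_chain_runs(
    chains: list[AlignmentChain], lq: int, ls: int, slop: int = 200
) -> int:
    """Number of collinear runs counting the circular topology: chains that
    abut (within ``slop``) on both sequences across the origin are one run.
    Two fully collinear circles give 1; each rearranged segment adds runs."""
    if not chains:
        return 0
    runs = len(chains)
    by_q = sorted(chains, key=lambda c: c.q_start)
    for a, b in zip(by_q, by_q[1:] + by_q[:1]):
        if a is b:
            break
        dq = (b.q_start - a.q_end) % lq
        if a.strand == b.strand == "+":
            ds = (b.s_start - a.s_end) % ls
        elif a.strand == b.strand == "-":
            ds = (a.s_start - b.s_end) % ls
        else:
            continue
        if dq <= slop and ds <= slop:
            runs -= 1
    return max(runs, 1)


def chains_to_tsv(chains: list[AlignmentChain], path) -> None:
    """Write chains as a TSV resembling BLAST outfmt 6 (1-based, inclusive)."""
    with open(path, "w") as fh:
        fh.write(
            "query\tsubject\tidentity\tlength\tq_start\tq_end\ts_start\ts_end\tstrand\n"
        )
        for c in chains:
            fh.write(
                f"{c.query_id}\t{c.subject_id}\t{c.identity:.4f}\t{c.columns}\t"
                f"{c.q_start + 1}\t{c.q_end}\t{c.s_start + 1}\t{c.s_end}\t{c.strand}\n"
            )
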
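"""Cytoplasm haplotype (mitotype) classification.

Brassica mitochondrial genomes fall into discrete haplotype classes
(*nap*, *cam*, *pol*, *ole*, ...) that determine the cytoplasm type of an
accession.  Classification uses two kinds of evidence:

* mitotype-specific sequences (MSS markers, >100 bp), detected by local
  similarity search with per-marker identity thresholds (0.90 for MSS4,
  0.85 for MSS9, 0.80 for the rest), and
* mitotype-variant ORFs, whose presence/absence follows the gene-PAV rule
  (>=60% coverage, >=85% identity).

An accession whose observed presence vector matches exactly one expected
profile column is assigned that mitotype; a near-match (unique best
agreement >= 0.8) becomes the "<mitotype>-like" type; everything else is
unclassified.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import pandas as pd

from . import gene_pav
from .circseq import CircularGenome, revcomp

DEFAULT_MARKER_THRESHOLD = 0.80
MARKER_THRESHOLD_OVERRIDES = {"MSS4": 0.90, "MSS9": 0.85}
MARKER_MIN_COVERAGE = 0.80
LIKE_AGREEMENT_CUTOFF = 0.80


@dataclass
class MitotypeProfile:
    """Marker/ORF sequences plus the expected presence matrix.

    ``expected`` is a boolean DataFrame indexed by marker/ORF id with one
    column per mitotype.  ``thresholds`` maps marker ids to their identity
    thresholds (every marker gets one; ORF presence uses the PAV rule).
    """

    markers: dict[str, str]
    orfs: dict[str, str]
    expected: pd.DataFrame
    thresholds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mid in self.markers:
            self.thresholds.setdefault(
                mid, MARKER_THRESHOLD_OVERRIDES.get(mid, DEFAULT_MARKER_THRESHOLD)
            )

    @property
    def mitotypes(self) -> list[str]:
        return list(self.expected.columns)

    @property
    def ids(self) -> list[str]:
        return list(self.expected.index)

    def validate(self) -> None:
        if len(self.mitotypes) < 2:
            raise ValueError("profile must name at least 2 mitotypes")
        for mid, thr in self.thresholds.items():
            if not 0 < thr <= 1:
                raise ValueError(f"threshold for {mid} outside (0, 1]")
        for mid, seq in self.markers.items():
            if not 100 <= len(seq) <= 2000:
                raise ValueError(f"marker {mid} length {len(seq)} outside 100-2000 bp")
            if re.search("[^ACGTN]", seq):
                raise ValueError(f"marker {mid} contains non-ACGTN characters")
        for mt in self.mitotypes:
            if not self.expected[mt].any():
                raise ValueError(f"mitotype column {mt} has no expected-present marker")
        missing = set(self.expected.index) - set(self.markers) - set(self.orfs)
        if missing:
            raise ValueError(f"expected matrix rows without sequences: {missing}")
        # markers must be mutually non-homologous (< 70% identity)
        mids = list(self.markers)
        for i, a in enumerate(mids):
            for b in mids[i + 1 :]:
                sa, sb = self.markers[a], self.markers[b]
                d = edlib.align(sa, sb, mode="NW")["editDistance"]
                ident = 1 - d / max(len(sa), len(sb))
                if ident >= 0.70:
                    raise ValueError(f"markers {a} and {b} are homologous ({ident:.2f})")

    def write(self, fasta_path, expected_path, thresholds_path) -> None:
        from .circseq import write_fasta

        write_fasta(
            [(i, s) for i, s in list(self.markers.items()) + list(self.orfs.items())],
            fasta_path,
        )
        self.expected.astype(int).to_csv(expected_path, sep="\t")
        pd.Series(self.thresholds, name="threshold").rename_axis("marker").to_csv(
            thresholds_path, sep="\t"
        )


@dataclass
class MarkerHit:
    present: bool
    position: int | None
    identity: float
    coverage: float
    strand: str | None


@dataclass
class MitotypeCall:
    accession_id: str
    call: str
    observed: dict[str, bool]
    agreement: dict[str, float]
    evidence: dict[str, MarkerHit | gene_pav.GenePAVRecord]


def detect_marker(
    genome: CircularGenome,
    marker: str,
    threshold: float = DEFAULT_MARKER_THRESHOLD,
    min_coverage: float = MARKER_MIN_COVERAGE,
) -> MarkerHit:
    """Search a marker on both strands of a circular genome.

    The genome is doubled so hits spanning the junction are found.  The
    marker is present when the best local hit covers at least
    ``min_coverage`` of it at identity >= ``threshold``.
    """
    marker = marker.upper()
    if not 100 <= len(marker) <= 2000:
        raise ValueError("marker length outside 100-2000 bp")
    if re.search("[^ACGTN]", marker):
        raise ValueError("marker contains non-ACGTN characters")
    doubled = genome.sequence + genome.sequence
    best = MarkerHit(False, None, 0.0, 0.0, None)
    for strand, q in (("+", marker), ("-", revcomp(marker))):
        res = edlib.align(q, doubled, task="path", mode="HW")
        if res["editDistance"] < 0:
            continue
        identity, coverage, _ = gene_pav._cigar_stats(res["cigar"], len(marker))
        if identity > best.identity:
            pos = res["locations"][0][0] % len(genome)
            best = MarkerHit(False, pos, identity, coverage, strand)
    best.present = best.identity >= threshold and best.coverage >= min_coverage
    return best


def classify(
    genome: CircularGenome,
    profile: MitotypeProfile,
    like_cutoff: float = LIKE_AGREEMENT_CUTOFF,
    pav_min_cov: float = gene_pav.PAV_MIN_COVERAGE,
    pav_min_ident: float = gene_pav.PAV_MIN_IDENTITY,
) -> MitotypeCall:
    """Classify one accession against a mitotype profile."""
    observed: dict[str, bool] = {}
    evidence: dict[str, object] = {}
    for mid, seq in profile.markers.items():
        hit = detect_marker(genome, seq, threshold=profile.thresholds[mid])
        observed[mid] = hit.present
        evidence[mid] = hit
    if profile.orfs:
        located = gene_pav._locate_from_seeds(genome, dict(profile.orfs))
        for oid, seq in profile.orfs.items():
            rec = gene_pav.call_pav(
                located.get(oid, []),
                len(seq),
                accession_id=genome.id,
                gene_id=oid,
                min_cov=pav_min_cov,
                min_ident=pav_min_ident,
            )
            observed[oid] = rec.present
            evidence[oid] = rec

    ids = profile.ids
    agreement = {}
    exact = []
    for mt in profile.mitotypes:
        col = profile.expected[mt]
        agree = sum(observed[i] == bool(col[i]) for i in ids) / len(ids)
        agreement[mt] = agree
        if agree == 1.0:
            exact.append(mt)
    if len(exact) == 1:
        call = exact[0]
    else:
        ranked = sorted(agreement.items(), key=lambda kv: -kv[1])
        if (
            len(ranked) >= 2
            and ranked[0][1] >= like_cutoff
            and ranked[0][1] > ranked[1][1]
        ):
            call = f"{ranked[0][0]}-like"
        elif len(ranked) == 1 and ranked[0][1] >= like_cutoff:
            call = f"{ranked[0][0]}-like"
        else:
            call = "unclassified"
    return MitotypeCall(genome.id, call, observed, agreement, evidence)


def frequency_table(counts: dict[str, int]) -> pd.DataFrame:
    """Mitotype counts -> a percentage table (two decimals)."""
    total = sum(counts.values())
    rows = [
        {"mitotype": mt, "number": n, "percentage": round(100 * n / total, 2)}
        for mt, n in counts.items()
    ]
    return pd.DataFrame(rows)


def classify_population(
    genomes: list[CircularGenome],
    profile: MitotypeProfile,
    like_cutoff: float = LIKE_AGREEMENT_CUTOFF,
):
    """Classify every accession; return (calls table, frequency table).

    Percentages are computed over classified accessions ("-like" calls
    count towards their base mitotype; unclassified accessions are listed
    but excluded from the percentage denominator).
    """
    if not genomes:
        raise ValueError("need at least one genome")
    calls = [classify(g, profile, like_cutoff=like_cutoff) for g in genomes]
    table = pd.DataFrame(
        {
            "accession": [c.accession_id for c in calls],
            "call": [c.call for c in calls],
        }
    )
    counts: dict[str, int] = {}
    for c in calls:
        if c.call == "unclassified":
            continue
        base = c.call.removesuffix("-like")
        counts[base] = counts.get(base, 0) + 1
    freq = frequency_table(counts) if counts else pd.DataFrame(
        columns=["mitotype", "number", "percentage"]
    )
    return table, freq, calls
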
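"""Assembly support evaluation from read placements.

Assemblies are validated with the reads used to build them: only exactly
matching reads count (mismatch/indel/clipped reads are an upstream filter,
carried here as a flag on each placement).  Two criteria are applied:

* per-position depth of at least 150x along the whole circle, and
* structural support: no interval of >= 150 bp without any read *start*
  (such a start-free gap indicates a possible assembly breakpoint, since
  reads are ~150 bp and depth far exceeds 1x).

Placements are abstract (start, length, strand, exact) records; depth and
gap computations are circular-aware.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

MIN_GAP = 150
MIN_DEPTH = 150


@dataclass
class Placements:
    """Read placements of one accession (vectorized)."""

    accession: str
    starts: np.ndarray  # int64, 0 <= start < genome_length
    lengths: np.ndarray  # int64
    strands: np.ndarray  # '+'/'-' (unit-length str array)
    exact: np.ndarray  # bool

    def __len__(self) -> int:
        return len(self.starts)

    @classmethod
    def build(cls, accession, starts, length=150, strand="+", exact=True):
        starts = np.asarray(starts, dtype=np.int64)
        n = len(starts)
        lengths = np.full(n, length) if np.isscalar(length) else np.asarray(length)
        strands = np.full(n, strand) if isinstance(strand, str) else np.asarray(strand)
        ex = np.full(n, exact) if isinstance(exact, bool) else np.asarray(exact)
        return cls(accession, starts, lengths.astype(np.int64), strands, ex)

    def exact_only(self) -> "Placements":
        m = self.exact
        return Placements(self.accession, self.starts[m], self.lengths[m],
                          self.strands[m], self.exact[m])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("accession\tstart0\tlength\tstrand\texact\n")
            for s, l, st, e in zip(self.starts, self.lengths, self.strands, self.exact):
                fh.write(f"{self.accession}\t{s}\t{l}\t{st}\t{int(e)}\n")

    @classmethod
    def from_tsv(cls, path) -> "Placements":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        return cls(
            str(df["accession"].iloc[0]) if len(df) else "",
            df["start0"].to_numpy(np.int64),
            df["length"].to_numpy(np.int64),
            df["strand"].to_numpy(str),
            df["exact"].to_numpy(bool),
        )


@dataclass
class QcReport:
    accession: str
    min_depth: int
    mean_depth: float
    fraction_positions_ge_threshold: float
    gaps: list[tuple[int, int]]
    pass_150x: bool
    pass_no_gap: bool
    depth_threshold: int = MIN_DEPTH
    min_gap: int = MIN_GAP

    def to_json(self, path=None) -> str:
        payload = {
            "accession": self.accession,
            "min_depth": int(self.min_depth),
            "mean_depth": float(self.mean_depth),
            "fraction_positions_ge_threshold": float(self.fraction_positions_ge_threshold),
            "gaps": [[int(a), int(b)] for a, b in self.gaps],
            "pass_150x": bool(self.pass_150x),
            "pass_no_gap": bool(self.pass_no_gap),
            "depth_threshold": self.depth_threshold,
            "min_gap": self.min_gap,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def depth_profile(placements: Placements, genome_length: int, circular: bool = True) -> np.ndarray:
    """Per-position depth from exact-match placements (wrap-around aware).

    The sum of the profile equals the total number of placed bases.
    """
    p = placements.exact_only()
    if len(p) and (p.starts.min() < 0 or p.starts.max() >= genome_length):
        raise ValueError("placement start outside genome")
    diff = np.zeros(genome_length + 1, dtype=np.int64)
    starts = p.starts
    ends = starts + p.lengths
    within = ends <= genome_length
    np.add.at(diff, starts[within], 1)
    np.add.at(diff, ends[within], -1)
    over = ~within
    if over.any():
        if not circular:
            raise ValueError("placement extends past a linear genome end")
        np.add.at(diff, starts[over], 1)
        diff[genome_length] -= over.sum()
        wrap_ends = ends[over] - genome_length
        diff[0] += over.sum()
        np.add.at(diff, wrap_ends, -1)
    return np.cumsum(diff[:-1])


def detect_gaps(
    placements: Placements | np.ndarray,
    genome_length: int,
    min_gap: int = MIN_GAP,
    circular: bool = True,
) -> list[tuple[int, int]]:
    """Maximal intervals with no read start and length >= ``min_gap``.

    Returned intervals are 0-based half-open; on a circular genome the
    interval between the last and first start wraps and is reported with
    ``end > genome_length`` (i.e. (start, end mod L) crosses the origin).
    An empty list means the assembly is structurally supported.
    """
    starts = placements.starts if isinstance(placements, Placements) else np.asarray(placements)
    if len(starts) == 0:
        raise ValueError("need at least one placement")
    s = np.unique(starts)
    gaps = []
    spacing = np.diff(s)
    for i in np.nonzero(spacing - 1 >= min_gap)[0]:
        gaps.append((int(s[i]) + 1, int(s[i + 1])))
    if circular:
        wrap_len = (genome_length - int(s[-1]) - 1) + int(s[0])
        if wrap_len >= min_gap:
            gaps.append((int(s[-1]) + 1, genome_length + int(s[0])))
    else:
        if s[0] >= min_gap:
            gaps.insert(0, (0, int(s[0])))
        tail = genome_length - int(s[-1]) - 1
        if tail >= min_gap:
            gaps.append((int(s[-1]) + 1, genome_length))
    return gaps


def gaps_to_bed(gaps, genome_length: int, name: str, path) -> None:
    """Write gaps as BED (0-based half-open); wrapped gaps split in two."""
    with open(path, "w") as fh:
        for a, b in gaps:
            if b <= genome_length:
                fh.write(f"{name}\t{a}\t{b}\n")
            else:
                fh.write(f"{name}\t{a}\t{genome_length}\n")
                fh.write(f"{name}\t0\t{b - genome_length}\n")


def qc_summary(
    placements: Placements,
    genome,
    depth_threshold: int = MIN_DEPTH,
    min_gap: int = MIN_GAP,
) -> QcReport:
    """Full QC report for one accession (depth + structural gaps)."""
    L = len(genome)
    depth = depth_profile(placements, L, circular=getattr(genome, "circular", True))
    gaps = detect_gaps(placements.exact_only(), L, min_gap=min_gap,
                       circular=getattr(genome, "circular", True))
    frac = float((depth >= depth_threshold).mean())
    return QcReport(
        accession=placements.accession,
        min_depth=int(depth.min()),
        mean_depth=float(depth.mean()),
        fraction_positions_ge_threshold=frac,
        gaps=gaps,
        pass_150x=bool(depth.min() >= depth_threshold),
        pass_no_gap=not gaps,
        depth_threshold=depth_threshold,
        min_gap=min_gap,
    )
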
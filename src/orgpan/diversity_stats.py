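"""Windowed nucleotide diversity, Fst and reduction-of-diversity regions.

Nucleotide diversity per site is the unordered-pair mismatch fraction
pi = sum_{i<j} c_i c_j * 2 / (n (n-1)) over haploid allele counts; window
pi averages site values over the full window length (500 bp windows,
100 bp step, vcftools-style denominator).  Between-group differentiation
uses the Hudson estimator as a ratio of averages,
Fst = 1 - mean(Hw) / mean(Hb), appropriate for haploid organelle samples.
ROD contrasts a subgroup's window diversity against the whole population,
ROD = 1 - pi_group / pi_all; windows in the top 1% of ROD are merged into
candidate differentiation regions.

Only SNP records enter these statistics; sites with fewer than two
non-missing haplotypes in a group are skipped for that group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

WINDOW = 500
STEP = 100
ROD_TOP_FRACTION = 0.01


def site_pi(allele_counts, n: int | None = None) -> float:
    """Unordered-pair mismatch fraction at one site.

    ``allele_counts`` maps allele -> haploid count (or is a sequence of
    counts).  N genotypes must already be excluded; n < 2 is undefined.
    """
    counts = list(allele_counts.values()) if hasattr(allele_counts, "values") \
        else list(allele_counts)
    if n is None:
        n = sum(counts)
    if sum(counts) != n:
        raise ValueError("allele counts must sum to n")
    if n < 2:
        raise ValueError("site_pi undefined for n < 2")
    same = sum(c * (c - 1) for c in counts)
    return 1.0 - same / (n * (n - 1))


def _site_arrays(records, sample_idx):
    """positions (0-based), per-site pi and heterozygosity pieces for a
    sample subset; sites with < 2 non-missing calls get NaN."""
    pos = np.array([r.pos1 - 1 for r in records], dtype=np.int64)
    pis = np.full(len(records), np.nan)
    for i, rec in enumerate(records):
        gt = rec.genotypes[sample_idx]
        gt = gt[gt >= 0]
        if len(gt) < 2:
            continue
        _, counts = np.unique(gt, return_counts=True)
        pis[i] = site_pi(counts, int(counts.sum()))
    return pos, pis


def window_starts(genome_length: int, step: int = STEP) -> np.ndarray:
    return np.arange(0, genome_length, step, dtype=np.int64)


def _window_sums(pos, values, genome_length, window, step):
    """Sum ``values`` of sites falling in each circular window."""
    starts = window_starts(genome_length, step)
    sums = np.zeros(len(starts))
    counts = np.zeros(len(starts), dtype=np.int64)
    ok = ~np.isnan(values)
    for p, v in zip(pos[ok], values[ok]):
        # windows with start in (p - window, p] modulo L contain p
        lo = (p - window) // step + 1
        hi = p // step
        for w in range(lo, hi + 1):
            idx = w % len(starts)
            if starts[idx] <= p < starts[idx] + window or \
                    (starts[idx] + window > genome_length and p < (starts[idx] + window) % genome_length):
                sums[idx] += v
                counts[idx] += 1
    return starts, sums, counts


def window_pi(
    records,
    groups: dict[str, str],
    accession_order: list[str],
    genome_length: int,
    window: int = WINDOW,
    step: int = STEP,
) -> pd.DataFrame:
    """Sliding-window pi for the whole sample and per group.

    Returns a DataFrame with start0/end0, n_variants, ``pi_all`` and one
    ``pi_<group>`` column per group; monomorphic windows are 0.
    """
    snps = [r for r in records if r.type == "SNP"]
    order = {a: i for i, a in enumerate(accession_order)}
    subsets = {"all": np.arange(len(accession_order))}
    for g in sorted(set(groups.values())):
        subsets[g] = np.array([order[a] for a in accession_order if groups[a] == g])
    starts = window_starts(genome_length, step)
    out = pd.DataFrame({"start0": starts, "end0": starts + window})
    for name, idx in subsets.items():
        if len(snps) == 0:
            out[f"pi_{name}"] = 0.0
            if name == "all":
                out["n_variants"] = 0
            continue
        pos, pis = _site_arrays(snps, idx)
        _, sums, counts = _window_sums(pos, pis, genome_length, window, step)
        out[f"pi_{name}"] = sums / window
        if name == "all":
            out["n_variants"] = counts
    return out


def genomewide_pi(records, sample_ids, accession_order, genome_length) -> float:
    """Mean pairwise diversity per bp over the whole genome."""
    order = {a: i for i, a in enumerate(accession_order)}
    idx = np.array([order[a] for a in sample_ids])
    snps = [r for r in records if r.type == "SNP"]
    if not snps:
        return 0.0
    _, pis = _site_arrays(snps, idx)
    return float(np.nansum(pis) / genome_length)


def _hudson_site(recs, idx_a, idx_b):
    """Per-site (Hw, Hb) components for the Hudson Fst estimator."""
    pos, hw, hb = [], [], []
    for rec in recs:
        ga = rec.genotypes[idx_a]
        gb = rec.genotypes[idx_b]
        ga, gb = ga[ga >= 0], gb[gb >= 0]
        if len(ga) < 2 or len(gb) < 2:
            continue
        alleles = sorted(set(ga) | set(gb))
        pa = np.array([(ga == al).mean() for al in alleles])
        pb = np.array([(gb == al).mean() for al in alleles])
        na, nb = len(ga), len(gb)
        hwa = (1 - ((ga[:, None] == ga[None, :]).sum() - na) / (na * (na - 1)))
        hwb = (1 - ((gb[:, None] == gb[None, :]).sum() - nb) / (nb * (nb - 1)))
        pos.append(rec.pos1 - 1)
        hw.append((hwa + hwb) / 2)
        hb.append(1 - float((pa * pb).sum()))
    return np.array(pos), np.array(hw), np.array(hb)


def pairwise_fst(
    records,
    groups: dict[str, str],
    group_a: str,
    group_b: str,
    accession_order: list[str],
    genome_length: int | None = None,
    window: int = WINDOW,
    step: int = STEP,
):
    """Hudson Fst between two groups: genome-wide and (optionally) per
    window as ratio-of-averages; undefined (NaN) where sum(Hb) == 0.
    Negative estimates are reported as-is, not clipped."""
    order = {a: i for i, a in enumerate(accession_order)}
    idx_a = np.array([order[a] for a in accession_order if groups[a] == group_a])
    idx_b = np.array([order[a] for a in accession_order if groups[a] == group_b])
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("empty group")
    snps = [r for r in records if r.type == "SNP"]
    pos, hw, hb = _hudson_site(snps, idx_a, idx_b)
    total = float(1 - hw.sum() / hb.sum()) if len(pos) and hb.sum() > 0 else float("nan")
    if genome_length is None:
        return total, None
    starts, hw_sums, _ = _window_sums(pos, hw, genome_length, window, step)
    _, hb_sums, _ = _window_sums(pos, hb, genome_length, window, step)
    with np.errstate(invalid="ignore", divide="ignore"):
        wfst = 1 - hw_sums / hb_sums
    wfst[hb_sums == 0] = np.nan
    df = pd.DataFrame({"start0": starts, "end0": starts + window, "fst": wfst})
    return total, df


@dataclass
class DifferentiationRegion:
    start0: int
    end0: int
    n_windows: int
    n_variants: int
    pi: dict[str, float | None]  # per group; None -> 'na' (no SNPs in group)
    genes: list[str]

    def row(self):
        d = {"start": self.start0 + 1, "end": self.end0,
             "n_windows": self.n_windows, "n_variants": self.n_variants}
        for g, v in self.pi.items():
            d[f"pi_{g}"] = "na" if v is None else f"{v:.2e}"
        d["genes"] = ",".join(self.genes)
        return d


def rod_windows(windows: pd.DataFrame, group: str) -> pd.Series:
    """ROD = 1 - pi_group / pi_all per window; NaN where pi_all == 0."""
    pi_all = windows["pi_all"].to_numpy(float)
    pi_g = windows[f"pi_{group}"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rod = 1.0 - pi_g / pi_all
    rod[pi_all == 0] = np.nan
    return pd.Series(rod, index=windows.index, name=f"rod_{group}")


def rod_regions(
    windows: pd.DataFrame,
    group: str,
    records=None,
    groups: dict[str, str] | None = None,
    accession_order: list[str] | None = None,
    gene_models=None,
    top_fraction: float = ROD_TOP_FRACTION,
    merge_adjacent: bool = True,
    genome_length: int | None = None,
) -> list[DifferentiationRegion]:
    """Select top-ROD windows for ``group`` and merge them into regions.

    Windows whose ROD reaches the (1 - top_fraction) quantile of defined
    values are kept; overlapping or abutting windows merge.  Per-region
    per-group pi is recomputed over the region span ('na' when a group has
    no polymorphic site there); overlapping genes come from gene models.
    """
    rod = rod_windows(windows, group)
    defined = rod.dropna()
    if defined.empty:
        return []
    thr = float(np.quantile(defined.to_numpy(), 1 - top_fraction))
    sel = windows.loc[rod >= thr].sort_values("start0")
    L = genome_length
    if L is not None:
        sel = sel[sel["end0"] <= L]  # origin-wrapping windows are not merged
    regions: list[list] = []
    for _, w in sel.iterrows():
        if merge_adjacent and regions and w["start0"] <= regions[-1][1]:
            regions[-1][1] = max(regions[-1][1], int(w["end0"]))
            regions[-1][2] += 1
        else:
            regions.append([int(w["start0"]), int(w["end0"]), 1])
    out = []
    group_names = sorted({g for g in (groups or {}).values()})
    for start0, end0, n_win in regions:
        n_var = 0
        pis: dict[str, float | None] = {}
        if records is not None and groups is not None:
            snps = [r for r in records
                    if r.type == "SNP" and start0 <= r.pos1 - 1 < end0]
            n_var = len(snps)
            order = {a: i for i, a in enumerate(accession_order)}
            subsets = {"all": np.arange(len(accession_order))}
            for g in group_names:
                subsets[g] = np.array(
                    [order[a] for a in accession_order if groups[a] == g]
                )
            for name, idx in subsets.items():
                if snps:
                    _, pis_arr = _site_arrays(snps, idx)
                    tot = np.nansum(pis_arr)
                else:
                    tot = 0.0
                pis[name] = (tot / (end0 - start0)) if tot > 0 else None
        genes = []
        if gene_models:
            genes = [m.gene_id for m in gene_models
                     if m.start < end0 and m.end > start0]
        out.append(DifferentiationRegion(start0, end0, n_win, n_var, pis, genes))
    return out


def regions_table(regions: list[DifferentiationRegion]) -> pd.DataFrame:
    return pd.DataFrame([r.row() for r in regions])
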
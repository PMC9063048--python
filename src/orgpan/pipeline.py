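"""End-to-end pipeline orchestration.

Runs the stages in dependency order on a synthetic population --
simulate -> qc -> pangenome -> variants -> mitotype -> pav -> diversity ->
structure -- writing each stage's standard outputs into a run directory
plus a manifest with content hashes, so a rerun with the same configuration
is byte-identical.  Stage functions are also usable individually; each one
checks that the results it consumes are present and names the missing
stage otherwise.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import (
    assembly_qc,
    diversity_stats,
    gene_pav,
    mitotyper,
    pangenome_builder,
    popstructure,
    synthetic_data,
    variant_catalog,
)
from .circseq import write_fasta
from .synthetic_data import SimulationConfig

log = logging.getLogger("orgpan")

STAGES = ("simulate", "qc", "pangenome", "variants", "mitotype", "pav",
          "diversity", "structure")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All knobs of the pipeline in one flat, documented structure."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    stages: tuple[str, ...] = STAGES
    # pan-genome editing
    min_insert: int = 10  # bp; larger insertions edit the backbone
    min_unanchored: int = 100  # bp; larger non-aligning fragments considered
    min_support: int = 2  # accessions per dispensable scaffold
    # gene presence/absence
    pav_min_cov: float = 0.60
    pav_min_ident: float = 0.85
    # diversity
    window: int = 500
    step: int = 100
    rod_top: float = 0.01
    # structure filters
    min_maf: float = 0.005
    max_missing: float = 0.20
    # assembly QC
    qc_min_gap: int = 150
    qc_depth: int = 150
    qc_mask: tuple[int, int] | None = None  # mask read starts on accession 0
    # aligner
    k: int = 31
    stride: int = 8

    @property
    def seed(self) -> int:
        return self.simulation.seed

    def validate(self) -> None:
        self.simulation.validate()
        if not 0 < self.rod_top <= 0.5:
            raise ValueError("rod_top outside (0, 0.5]")
        if not 0 <= self.min_maf <= 0.5 or not 0 <= self.max_missing <= 1:
            raise ValueError("MAF/missingness thresholds out of range")
        if self.min_insert < 0 or self.min_unanchored < 0 or self.min_support < 1:
            raise ValueError("pan-genome thresholds out of range")
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s}")

    def to_yaml(self, path) -> None:
        import yaml

        d = {k: v for k, v in self.__dict__.items() if k != "simulation"}
        d["stages"] = list(self.stages)
        if d.get("qc_mask"):
            d["qc_mask"] = list(d["qc_mask"])
        sim = dict(self.simulation.__dict__)
        sim["collinear_pair"] = list(sim["collinear_pair"])
        if sim.get("rod_block"):
            sim["rod_block"] = list(sim["rod_block"])
        d["simulation"] = sim
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        sim = d.pop("simulation", {})
        if "collinear_pair" in sim and sim["collinear_pair"] is not None:
            sim["collinear_pair"] = tuple(sim["collinear_pair"])
        if sim.get("rod_block"):
            sim["rod_block"] = tuple(sim["rod_block"])
        if d.get("qc_mask"):
            d["qc_mask"] = tuple(d["qc_mask"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        cfg = cls(simulation=SimulationConfig(**sim), **d)
        cfg.validate()
        return cfg


def _need(results: dict, key: str, stage: str, needed_by: str):
    if key not in results:
        raise PipelineError(
            f"stage '{needed_by}' requires output of stage '{stage}', "
            f"which did not run (enable it in config.stages)"
        )
    return results[key]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, outdir: Path, results: dict) -> None:
    sim = cfg.simulation
    profile = synthetic_data.default_profile(seed=sim.seed, gc=sim.gc_content)
    founders = synthetic_data.build_founders(sim, profile)
    genomes, truth = synthetic_data.simulate_population(sim, founders)
    results.update(profile=profile, founders=founders, genomes=genomes, truth=truth)
    write_fasta(genomes, outdir / "accessions.fasta")
    truth.labels_to_tsv(outdir / "truth_labels.tsv")
    truth.events_to_tsv(outdir / "truth_events.tsv")
    founders.gene_set.write(outdir / "genes.fasta", outdir / "gene_features.tsv")
    profile.write(outdir / "profile.fasta", outdir / "profile_expected.tsv",
                  outdir / "profile_thresholds.tsv")
    sim.to_yaml(outdir / "simulation.yaml")
    log.info("simulate: %d accessions, %d truth events", len(genomes), len(truth.events))


def stage_qc(cfg: PipelineConfig, outdir: Path, results: dict) -> None:
    genomes = _need(results, "genomes", "simulate", "qc")
    reports = []
    for i, g in enumerate(genomes):
        mask = cfg.qc_mask if i == 0 and cfg.qc_mask else None
        pl = synthetic_data.simulate_read_placements(
            g, cfg.simulation, seed=cfg.seed + i, mask=mask
        )
        rep = assembly_qc.qc_summary(pl, g, depth_threshold=cfg.qc_depth,
                                     min_gap=cfg.qc_min_gap)
        reports.append(rep)
    results["qc_reports"] = reports
    with open(outdir / "qc_reports.json", "w") as fh:
        fh.write("[\n" + ",\n".join(r.to_json() for r in reports) + "\n]\n")
    for rep, g in zip(reports, genomes):
        if rep.gaps:
            assembly_qc.gaps_to_bed(rep.gaps, len(g), g.id, outdir / f"qc_gaps_{g.id}.bed")
    log.info("qc: %d/%d pass structural check", sum(r.pass_no_gap for r in reports),
             len(reports))


def stage_pangenome(cfg: PipelineConfig, outdir: Path, results: dict) -> None:
    genomes = _need(results, "genomes", "simulate", "pangenome")
    founders = _need(results, "founders", "simulate", "pangenome")
    ref_id = pangenome_builder.choose_reference(genomes, k=cfg.k, stride=cfg.stride)
    by_id = {g.id: g for g in genomes}
    anchor = founders.gene_set.genes[0]
    reference = pangenome_builder.orient_reference(by_id[ref_id], anchor.genomic_seq)
    diffs = pangenome_builder.compute_diffs(genomes, reference, k=cfg.k, stride=cfg.stride)
    pan = pangenome_builder.build_pangenome(
        genomes, reference,
        min_insert=cfg.min_insert, min_unanchored=cfg.min_unanchored,
        min_support=cfg.min_support, diffs=diffs,
    )
    results.update(reference=reference, pangenome=pan)
    pan.write_fasta(outdir / "pangenome.fasta")
    rows = [
        {"draft_pos0": e.draft_pos, "length": e.length, "support": e.support,
         "accessions": ",".join(e.accessions)}
        for e in pan.provenance
    ]
    pd.DataFrame(rows).to_csv(outdir / "pangenome_edits.tsv", sep="\t", index=False)
    cmap_rows = [
        {"accession": acc, "acc_start0": qs, "acc_end0": qe, "target": t,
         "target_start0": ts, "target_end0": te, "strand": st}
        for acc, rows_ in sorted(pan.coordinate_map.items())
        for qs, qe, t, ts, te, st in rows_
    ]
    pd.DataFrame(cmap_rows).to_csv(outdir / "coordinate_map.tsv", sep="\t", index=False)
    stats = pangenome_builder.pangenome_stats(pan)
    with open(outdir / "pangenome_stats.json", "w") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)
    log.info("pangenome: reference %s, %d edits, %d scaffolds, total %d bp",
             ref_id, len(pan.provenance), len(pan.scaffolds), pan.total_length)


def stage_variants(cfg: PipelineConfig, outdir: Path, results: dict) -> None:
    genomes = _need(results, "genomes", "simulate", "variants")
    pan = _need(results, "pangenome", "pangenome", "variants")
    founders = _need(results, "founders", "simulate", "variants")
    diffs = pangenome_builder.compute_diffs(genomes, pan.backbone, k=cfg.k,
                                            stride=cfg.stride)
    records = variant_catalog.merge_calls(diffs, pan.backbone)
    records = variant_catalog.filter_singletons(records)
    models = variant_catalog.build_gene_models(
        pan.backbone, founders.gene_set,
        min_cov=cfg.pav_min_cov, min_ident=cfg.pav_min_ident,
    )
    variant_catalog.annotate(records, models, pan.backbone)
    accessions = list(diffs)
    results.update(records=records, accession_order=accessions, gene_models=models)
    variant_catalog.write_vcf(records, accessions, outdir / "variants.vcf",
                              contig=pan.backbone.id, contig_length=len(pan.backbone))
    variant_catalog.write_gene_models_gff3(models, pan.backbone.id,
                                           outdir / "gene_models.gff3")
    log.info("variants: %d records after singleton filter", len(records))


def stage_variant_summary(cfg: PipelineConfig, outdir: Path, results: dict) -> None:
    """Table-style summaries; runs with the mitotype stage available."""
    records = results["records"]
    accessions = results["accession_order"]
    calls = results["mitotype_calls"]
    pan = results["pangenome"]
    groups = _groups_from_calls(calls)
    groups = {a: g for a, g in groups.items() if a in set(accessions)}
    summary = variant_catalog.summarize(records, groups, accessions,
                                        len(pan.backbone))
    summary.per_group.to_csv(outdir / "variant_summary_groups.tsv", sep="\t")
    summary.region_counts.to_csv(outdir / "variant_summary_regions.tsv", sep="\t")
    results["variant_summary"] = summary


def stage_mitotype(cfg: PipelineConfig, outdir: Path, results: dict) -> None:
    genomes = _need(results, "genomes", "simulate", "mitotype")
    profile = _need(results, "profile", "simulate", "mitotype")
    table, freq, calls = mitotyper.classify_population(genomes, profile)
    results.update(mitotype_calls=table, mitotype_freq=freq)
    table.to_csv(outdir / "mitotype_calls.tsv", sep="\t", index=False)
    freq.to_csv(outdir / "mitotype_frequencies.tsv", sep="\t", index=False)
    log.info("mitotype: %s", dict(zip(freq["mitotype"], freq["number"])))
    if "records" in results:
        stage_variant_summary(cfg, outdir, results)


def stage_pav(cfg: PipelineConfig, outdir: Path, results: dict) -> None:
    genomes = _need(results, "genomes", "simulate", "pav")
    founders = _need(results, "founders", "simulate", "pav")
    mat, summary = gene_pav.pav_matrix(
        genomes, founders.gene_set,
        min_cov=cfg.pav_min_cov, min_ident=cfg.pav_min_ident,
    )
    results.update(pav_matrix=mat, pav_summary=summary)
    mat.to_csv(outdir / "pav_matrix.tsv", sep="\t")
    summary.to_csv(outdir / "pav_summary.tsv", sep="\t")
    log.info("pav: %d/%d genes core", int(summary["core"].sum()), len(summary))


def _groups_from_calls(table: pd.DataFrame) -> dict[str, str]:
    groups = {}
    for row in table.itertuples():
        if row.call == "unclassified":
            continue
        groups[row.accession] = row.call.removesuffix("-like")
    return groups


def stage_diversity(cfg: PipelineConfig, outdir: Path, results: dict) -> None:
    records = _need(results, "records", "variants", "diversity")
    accessions = _need(results, "accession_order", "variants", "diversity")
    calls = _need(results, "mitotype_calls", "mitotype", "diversity")
    pan = _need(results, "pangenome", "pangenome", "diversity")
    groups = _groups_from_calls(calls)
    groups = {a: g for a, g in groups.items() if a in set(accessions)}
    L = len(pan.backbone)
    windows = diversity_stats.window_pi(records, groups, accessions, L,
                                        window=cfg.window, step=cfg.step)
    for g in sorted(set(groups.values())):
        windows[f"rod_{g}"] = diversity_stats.rod_windows(windows, g)
    windows.to_csv(outdir / "diversity_windows.tsv", sep="\t", index=False)
    fst_rows = []
    names = sorted(set(groups.values()))
    counts = {g: sum(1 for v in groups.values() if v == g) for g in names}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if counts[a] < 2 or counts[b] < 2:
                continue
            total, _ = diversity_stats.pairwise_fst(records, groups, a, b, accessions)
            fst_rows.append({"group_a": a, "group_b": b, "fst": round(total, 4)})
    fst = pd.DataFrame(fst_rows)
    fst.to_csv(outdir / "fst.tsv", sep="\t", index=False)
    regions_by_group = {}
    for g in names:
        regions = diversity_stats.rod_regions(
            windows, g, records=records, groups=groups, accession_order=accessions,
            gene_models=results.get("gene_models"), top_fraction=cfg.rod_top,
            genome_length=L,
        )
        regions_by_group[g] = regions
        diversity_stats.regions_table(regions).to_csv(
            outdir / f"rod_regions_{g}.tsv", sep="\t", index=False
        )
    results.update(windows=windows, fst=fst, rod_regions=regions_by_group,
                   groups=groups)
    log.info("diversity: %d windows, Fst pairs %d", len(windows), len(fst_rows))


def stage_structure(cfg: PipelineConfig, outdir: Path, results: dict) -> None:
    records = _need(results, "records", "variants", "structure")
    accessions = _need(results, "accession_order", "variants", "structure")
    m = popstructure.GenotypeMatrix.from_records(records, accessions)
    m = popstructure.filter_sites(m, min_maf=cfg.min_maf, max_missing=cfg.max_missing)
    coords, explained = popstructure.pca(m, n_components=4)
    newick = popstructure.nj_tree(m)
    results.update(genotypes=m, pca_coords=coords, pca_explained=explained,
                   newick=newick)
    coords.round(6).to_csv(outdir / "pca_coordinates.tsv", sep="\t")
    pd.Series(explained, index=[f"PC{i+1}" for i in range(len(explained))],
              name="explained_fraction").round(6).to_csv(
        outdir / "pca_explained.tsv", sep="\t")
    with open(outdir / "tree.nwk", "w") as fh:
        fh.write(newick + "\n")
    log.info("structure: %d sites after filtering, PC1 %.1f%%",
             m.n_sites, 100 * explained[0])


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "pangenome": stage_pangenome,
    "variants": stage_variants,
    "mitotype": stage_mitotype,
    "pav": stage_pav,
    "diversity": stage_diversity,
    "structure": stage_structure,
}
# mitotype runs before diversity (groups come from the classification)
_STAGE_ORDER = ("simulate", "qc", "pangenome", "variants", "mitotype", "pav",
                "diversity", "structure")


def run(cfg: PipelineConfig, outdir, results: dict | None = None) -> dict:
    """Execute the configured stages; returns the in-memory results dict.

    Writes a manifest with a sha256 of every output file, the seed and the
    package version; a rerun with the same config is byte-identical.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    results = {} if results is None else results
    for stage in _STAGE_ORDER:
        if stage not in cfg.stages:
            continue
        try:
            _STAGE_FUNCS[stage](cfg, outdir, results)
        except PipelineError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
    manifest = {
        "seed": cfg.seed,
        "version": _version(),
        "stages": [s for s in _STAGE_ORDER if s in cfg.stages],
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results


def _version() -> str:
    from . import __version__

    return __version__


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()
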
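"""Shared fixtures: full synthetic-to-catalog runs at two scales.

The session-scoped runs execute the whole chain (simulate -> reference
choice -> pan-genome -> variant catalog) once and are shared by the module
and acceptance tests; truth-derived expectations ride along.
"""

from types import SimpleNamespace

import edlib
import pytest

from orgpan import pangenome_builder as pb
from orgpan import variant_catalog as vc
from orgpan.circseq import revcomp
from orgpan.synthetic_data import (
    SimulationConfig,
    build_founders,
    default_profile,
    simulate_population,
)


def seq_identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def insertion_matches(expected, applied, pos_slack=25, min_identity=0.95):
    return abs(expected[0] - applied[0]) <= pos_slack and (
        seq_identity(expected[1], applied[1]) >= min_identity
    )


def scaffold_matches(scaffold, fragment, min_identity=0.95):
    return any(
        seq_identity(q, fragment["seq"]) >= min_identity
        for q in (scaffold.seq, revcomp(scaffold.seq))
    )


def catalog_tuples(records):
    return sorted(
        (r.pos1, r.ref, tuple(r.alts), tuple(int(g) for g in r.genotypes))
        for r in records
    )


def run_flow(seed: int, kind: str, n: int, genome_length: int | None = None,
             **cfg_kwargs) -> SimpleNamespace:
    cfg = SimulationConfig(seed=seed, n_accessions=n, genome_kind=kind,
                           genome_length=genome_length, **cfg_kwargs)
    profile = default_profile(seed=seed, gc=cfg.gc_content)
    founders = build_founders(cfg, profile)
    genomes, truth = simulate_population(cfg, founders)
    by_id = {g.id: g for g in genomes}
    ref_id = pb.choose_reference(genomes)
    reference = pb.orient_reference(by_id[ref_id], founders.gene_set.genes[0].genomic_seq)
    diffs = pb.compute_diffs(genomes, reference)
    pan = pb.build_pangenome(genomes, reference, diffs=diffs)
    backbone_diffs = pb.compute_diffs(genomes, pan.backbone)
    records = vc.filter_singletons(vc.merge_calls(backbone_diffs, pan.backbone))
    accessions = list(backbone_diffs)
    return SimpleNamespace(
        cfg=cfg,
        profile=profile,
        founders=founders,
        genomes=genomes,
        by_id=by_id,
        truth=truth,
        ref_id=ref_id,
        reference=reference,
        diffs=diffs,
        pan=pan,
        backbone_diffs=backbone_diffs,
        records=records,
        accessions=accessions,
        groups={a: truth.labels[a] for a in accessions},
    )


@pytest.fixture(scope="session")
def cp_run():
    """Chloroplast-like study conditions: 60 accessions x 153 kb."""
    return run_flow(11, "cp", 60)


@pytest.fixture(scope="session")
def mt_run():
    """Mitochondrion-like study conditions: 24 accessions x 222 kb."""
    return run_flow(11, "mt", 24)


@pytest.fixture(scope="session")
def small_cp():
    """A small chloroplast population for module-level tests."""
    return run_flow(5, "cp", 12, genome_length=60000)


@pytest.fixture(scope="session")
def small_mt():
    """A small mitochondrial population (rearrangements, fragments)."""
    return run_flow(31, "mt", 12, genome_length=80000)
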
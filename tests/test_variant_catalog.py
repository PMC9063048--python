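"""Variant merging, singleton filter, annotation, summaries, VCF."""

import random

import numpy as np
import pytest

from orgpan.circseq import AlignmentDiff, CircularGenome, Event
from orgpan.variant_catalog import (
    GeneModel,
    VariantRecord,
    annotate,
    filter_singletons,
    merge_calls,
    normalize_site,
    read_vcf,
    summarize,
    ts_tv,
    variant_density_per_kb,
    write_vcf,
)


@pytest.fixture(scope="module")
def backbone():
    rng = random.Random(1)
    return CircularGenome("bb", "".join(rng.choice("ACGT") for _ in range(5000)))


def diff_with(acc, backbone, events):
    d = AlignmentDiff(acc, backbone.id)
    d.events = events
    return d


class TestNormalizeSite:
    def test_snp_unchanged(self, backbone):
        pos1, ref, alts = normalize_site(10, backbone.sequence[10], ["A"],
                                         backbone.sequence)
        assert pos1 == 11 and len(ref) == 1

    def test_equivalent_deletions_collapse(self):
        seq = "GGGCACACACAGGG"
        # deleting AC at 4 or at 6 is the same edit inside the CA repeat;
        # both left-align to the anchor before the run
        a = normalize_site(4, "AC", [""], seq)
        b = normalize_site(6, "AC", [""], seq)
        assert a == b
        assert a == (3, "GCA", ["G"])

    def test_insertion_left_aligned(self):
        seq = "GGGTTTTAGGG"
        a = normalize_site(7, "", ["T"], seq)
        b = normalize_site(4, "", ["T"], seq)
        assert a == b


class TestMergeCalls:
    def test_shared_snp_single_record(self, backbone):
        ev = Event(500, 501, "G" if backbone.sequence[500] != "G" else "T")
        diffs = {f"a{i}": diff_with(f"a{i}", backbone, [Event(ev.s_start, ev.s_end, ev.alt)])
                 for i in range(3)}
        diffs["ref_like"] = diff_with("ref_like", backbone, [])
        records = merge_calls(diffs, backbone)
        assert len(records) == 1
        rec = records[0]
        assert rec.pos1 == 501 and rec.alts == [ev.alt]
        assert int((rec.genotypes == 1).sum()) == 3
        assert int((rec.genotypes == 0).sum()) == 1

    def test_multiallelic_merge(self, backbone):
        refb = backbone.sequence[500]
        alts = [b for b in "ACGT" if b != refb][:2]
        diffs = {
            "a1": diff_with("a1", backbone, [Event(500, 501, alts[0])]),
            "a2": diff_with("a2", backbone, [Event(500, 501, alts[1])]),
        }
        records = merge_calls(diffs, backbone)
        assert len(records) == 1
        assert sorted(records[0].alts) == sorted(alts)

    def test_deletion_region_genotyped_n(self, backbone):
        refb = backbone.sequence[600]
        alt = "G" if refb != "G" else "T"
        diffs = {
            "a1": diff_with("a1", backbone, [Event(600, 601, alt)]),
            "a2": diff_with("a2", backbone, [Event(600, 601, alt)]),
            "del": diff_with("del", backbone, [Event(550, 700, "")]),
        }
        records = merge_calls(diffs, backbone)
        rec = records[0]
        gt = dict(zip(diffs, rec.genotypes))
        assert gt["del"] == -1 and gt["a1"] == 1

    def test_structural_events_excluded(self, backbone):
        diffs = {
            "a1": diff_with("a1", backbone, [Event(100, 100, "A" * 25)]),
            "a2": diff_with("a2", backbone, [Event(100, 100, "A" * 25)]),
        }
        assert merge_calls(diffs, backbone) == []


class TestFilterSingletons:
    def _rec(self, genotypes, alts=("G",)):
        return VariantRecord("bb", 10, "A", list(alts),
                             np.array(genotypes, dtype=np.int8))

    def test_singleton_dropped(self):
        assert filter_singletons([self._rec([1, 0, 0, 0])]) == []

    def test_doubleton_kept(self):
        out = filter_singletons([self._rec([1, 1, 0, 0])])
        assert len(out) == 1

    def test_multiallelic_per_allele(self):
        rec = self._rec([1, 2, 2, 2, 0], alts=("C", "G"))
        out = filter_singletons([rec])
        assert len(out) == 1
        assert out[0].alts == ["G"]  # the singleton C allele is removed
        assert int((out[0].genotypes == 1).sum()) == 3
        assert int((out[0].genotypes == 0).sum()) == 2

    def test_identity_without_singletons(self):
        recs = [self._rec([1, 1, 0]), self._rec([0, 1, 1])]
        assert filter_singletons(recs) == recs


class TestAnnotate:
    @pytest.fixture()
    def gene_backbone(self):
        rng = random.Random(2)
        pre = "".join(rng.choice("ACGT") for _ in range(2000))
        cds = "ATG" + "GAA" + "TGG" + "CAT" + "TAA"  # M E W H *
        post = "".join(rng.choice("ACGT") for _ in range(3000))
        bb = CircularGenome("bb", pre + cds + post)
        model = GeneModel("g1", "+", "protein", cds=[(2000, 2015)])
        return bb, model

    def _record(self, pos1, ref, alts):
        return VariantRecord("bb", pos1, ref, alts, np.zeros(2, dtype=np.int8))

    def test_synonymous_gaa_gag(self, gene_backbone):
        bb, model = gene_backbone
        # third base of the GAA codon: A->G keeps Glu
        rec = self._record(2006, "A", ["G"])
        annotate([rec], [model], bb)
        assert rec.region == "exonic" and rec.effect == "synonymous"

    def test_nonsynonymous_and_stopgain(self, gene_backbone):
        bb, model = gene_backbone
        rec_nonsyn = self._record(2004, "G", ["C"])  # GAA -> CAA (E->Q)
        rec_stop = self._record(2008, "G", ["A"])  # TGG -> TAG (stop)
        annotate([rec_nonsyn, rec_stop], [model], bb)
        assert rec_nonsyn.effect == "nonsynonymous"
        assert rec_stop.effect == "stopgain"

    def test_frameshift_mod3_rule(self, gene_backbone):
        bb, model = gene_backbone
        rec2 = VariantRecord("bb", 2004, "AGA", ["A"], np.zeros(2, np.int8))
        rec3 = VariantRecord("bb", 2004, "AGAA", ["A"], np.zeros(2, np.int8))
        annotate([rec2, rec3], [model], bb)
        assert rec2.effect == "frameshift"  # 2 bp deletion
        assert rec3.effect == "nonframeshift"  # 3 bp deletion

    def test_upstream_flank_and_intergenic(self, gene_backbone):
        bb, model = gene_backbone
        rec_up = self._record(1500, bb.sequence[1499], ["A"])  # 500 bp upstream
        rec_far = self._record(4500, bb.sequence[4499], ["A"])
        annotate([rec_up, rec_far], [model], bb, flank=1000)
        assert rec_up.region == "upstream/downstream"
        assert rec_far.region == "intergenic"

    def test_intron_and_splice_sites(self):
        rng = random.Random(3)
        pre = "".join(rng.choice("ACGT") for _ in range(1000))
        bb = CircularGenome("bb", pre + "".join(rng.choice("ACGT") for _ in range(2000)))
        model = GeneModel("g2", "+", "protein",
                          cds=[(1000, 1100), (1200, 1300)],
                          introns=[(1100, 1200)])
        rec_splice = VariantRecord("bb", 1102, bb.sequence[1101], ["A"],
                                   np.zeros(1, np.int8))
        rec_intron = VariantRecord("bb", 1150, bb.sequence[1149], ["A"],
                                   np.zeros(1, np.int8))
        annotate([rec_splice, rec_intron], [model], bb)
        assert rec_splice.region == "splicing"
        assert rec_intron.region == "intronic"

    def test_ncrna_exonic(self):
        rng = random.Random(4)
        bb = CircularGenome("bb", "".join(rng.choice("ACGT") for _ in range(3000)))
        model = GeneModel("trnX", "+", "tRNA", cds=[(1000, 1075)])
        rec = VariantRecord("bb", 1030, bb.sequence[1029], ["A"], np.zeros(1, np.int8))
        annotate([rec], [model], bb)
        assert rec.region == "ncRNA_exonic" and rec.effect == "na"

    def test_cds_not_divisible_by_three_unknown(self):
        rng = random.Random(5)
        bb = CircularGenome("bb", "".join(rng.choice("ACGT") for _ in range(3000)))
        model = GeneModel("bad", "+", "protein", cds=[(1000, 1100)])  # 100 bp
        rec = VariantRecord("bb", 1050, bb.sequence[1049], ["A"], np.zeros(1, np.int8))
        annotate([rec], [model], bb)
        assert rec.effect == "unknown"
        assert any("divisible" in w for w in annotate.warnings)


class TestSummaries:
    def test_ts_tv_balanced_set(self):
        # {A->G, C->T} transitions vs {A->T, G->C} transversions
        assert ts_tv([("A", "G"), ("C", "T"), ("A", "T"), ("G", "C")]) == 1.0

    def test_density_printed_example(self):
        assert variant_density_per_kb(326, 222_076) == 1.5

    def test_snp_share_printed_example(self):
        assert round(100 * 254 / (254 + 72), 2) == 77.91

    def test_group_counts_polymorphic_within(self):
        recs = [
            VariantRecord("bb", 10, "A", ["G"], np.array([1, 1, 0, 0], np.int8)),
            VariantRecord("bb", 20, "C", ["T"], np.array([1, 1, 1, 1], np.int8)),
        ]
        groups = {"a1": "x", "a2": "x", "b1": "y", "b2": "y"}
        order = ["a1", "a2", "b1", "b2"]
        summary = summarize(recs, groups, order, 10_000)
        # site 20 is fixed everywhere: polymorphic in no group, counted in none
        assert summary.per_group.loc["x", "SNPs"] == 0
        assert summary.per_group.loc["y", "SNPs"] == 0
        assert summary.per_group.loc["All", "SNPs"] == 1
        assert summary.per_group.loc["x", "Ts/Tv"] == "undefined"

    def test_density_uses_backbone_length(self):
        recs = [
            VariantRecord("bb", i, "A", ["G"], np.array([1, 1], np.int8))
            for i in range(1, 31)
        ]
        summary = summarize(recs, {"a": "x", "b": "x"}, ["a", "b"], 20_000)
        assert summary.density_per_kb == 1.5


class TestGeneModelsGff3:
    def test_round_trip(self, small_cp, tmp_path):
        from orgpan.variant_catalog import (
            build_gene_models,
            read_gene_models_gff3,
            write_gene_models_gff3,
        )

        models = build_gene_models(small_cp.pan.backbone,
                                   small_cp.founders.gene_set)
        assert len(models) >= 20
        path = tmp_path / "models.gff3"
        write_gene_models_gff3(models, small_cp.pan.backbone.id, path)
        back = read_gene_models_gff3(path)
        key = lambda m: (m.gene_id, m.strand, m.kind, sorted(m.cds),
                         sorted(m.introns))
        assert sorted(map(key, back)) == sorted(map(key, models))

    def test_hits_gff3(self, small_cp, tmp_path):
        from orgpan.gene_pav import hits_to_gff3, pav_records

        recs = pav_records(small_cp.genomes[0], small_cp.founders.gene_set)
        path = tmp_path / "hits.gff3"
        hits_to_gff3(recs, small_cp.genomes[0].id, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "##gff-version 3"
        assert len(lines) > 20


class TestVcf:
    def test_round_trip(self, small_cp, tmp_path):
        path = tmp_path / "v.vcf"
        write_vcf(small_cp.records, small_cp.accessions, path,
                  contig=small_cp.pan.backbone.id,
                  contig_length=len(small_cp.pan.backbone))
        back, accs = read_vcf(path)
        assert accs == small_cp.accessions
        assert len(back) == len(small_cp.records)
        for a, b in zip(sorted(back, key=lambda r: r.pos1),
                        sorted(small_cp.records, key=lambda r: r.pos1)):
            assert (a.chrom, a.pos1, a.ref, a.alts) == (b.chrom, b.pos1, b.ref, b.alts)
            assert np.array_equal(a.genotypes, b.genotypes)

    def test_external_parser_agrees(self, small_cp, tmp_path):
        """cyvcf2 (htslib) reads our VCF identically -- format conformance."""
        cyvcf2 = pytest.importorskip("cyvcf2")
        path = tmp_path / "v.vcf"
        write_vcf(small_cp.records, small_cp.accessions, str(path),
                  contig=small_cp.pan.backbone.id,
                  contig_length=len(small_cp.pan.backbone))
        seen = []
        for v in cyvcf2.VCF(str(path)):
            seen.append((v.CHROM, v.POS, v.REF, tuple(v.ALT)))
        ours = sorted(
            (r.chrom, r.pos1, r.ref, tuple(r.alts)) for r in small_cp.records
        )
        assert sorted(seen) == ours
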
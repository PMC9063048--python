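"""Synthetic population generator: determinism, truth consistency, design."""

import numpy as np
import pytest

from orgpan.circseq import revcomp, rotate
from orgpan.synthetic_data import (
    SimulationConfig,
    build_founders,
    default_profile,
    largest_remainder_counts,
    simulate_population,
)


class TestConfig:
    def test_defaults_by_kind(self):
        cp = SimulationConfig(genome_kind="cp")
        mt = SimulationConfig(genome_kind="mt")
        assert cp.genome_length == 153_000 and abs(cp.gc_content - 0.363) < 1e-9
        assert mt.genome_length == 222_000 and abs(mt.gc_content - 0.452) < 1e-9

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(mitotype_proportions={"nap": 0.6, "cam": 0.5})

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(snp_rate=-1e-5)

    def test_genome_must_exceed_reads(self):
        with pytest.raises(ValueError):
            SimulationConfig(genome_length=1000, read_length=150)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=3, n_accessions=10, genome_kind="mt",
                               genome_length=50000)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SimulationConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg


class TestCounts:
    def test_largest_remainder_forced_example(self):
        counts = largest_remainder_counts(
            60, {"nap": 0.5, "cam": 0.3, "pol": 0.15, "ole": 0.05}
        )
        assert counts == {"nap": 30, "cam": 18, "pol": 9, "ole": 3}

    @pytest.mark.parametrize("n", [7, 13, 24, 61])
    def test_counts_sum_to_n(self, n):
        counts = largest_remainder_counts(
            n, {"nap": 0.5, "cam": 0.3, "pol": 0.15, "ole": 0.05}
        )
        assert sum(counts.values()) == n


class TestFounders:
    def test_gc_content_within_one_percent(self, small_cp, small_mt):
        for run in (small_cp, small_mt):
            for f in run.founders.founders.values():
                assert abs(f.gc_content() - run.cfg.gc_content) < 0.01

    def test_marker_content_matches_profile(self, small_mt):
        """Each founder contains exactly the markers its column expects."""
        from orgpan.mitotyper import detect_marker

        profile = small_mt.profile
        for group, founder in small_mt.founders.items():
            for mid, seq in profile.markers.items():
                hit = detect_marker(founder, seq, threshold=profile.thresholds[mid])
                assert hit.present == bool(profile.expected.loc[mid, group]), (
                    f"{group}/{mid}"
                )

    def test_marker_absent_everywhere_appears_nowhere(self):
        cfg = SimulationConfig(seed=9, n_accessions=8, genome_kind="cp",
                               genome_length=60000)
        profile = default_profile(seed=9, gc=cfg.gc_content)
        profile.expected.loc["MSS5", :] = False
        fs = build_founders(cfg, profile)
        from orgpan.mitotyper import detect_marker

        for founder in fs.founders.values():
            assert not detect_marker(founder, profile.markers["MSS5"]).present

    def test_marker_longer_than_genome_rejected(self):
        cfg = SimulationConfig(seed=9, n_accessions=8, genome_kind="cp",
                               genome_length=2000, read_length=100)
        profile = default_profile(seed=9)
        with pytest.raises(ValueError):
            build_founders(cfg, profile)

    def test_profile_column_without_markers_rejected(self):
        profile = default_profile(seed=1)
        profile.expected.loc[:, "ole"] = False
        with pytest.raises(ValueError):
            profile.validate()


class TestPopulation:
    def test_seed_reproducibility(self, small_cp):
        cfg = small_cp.cfg
        fs = build_founders(cfg, small_cp.profile)
        g2, t2 = simulate_population(cfg, fs)
        assert all(a.sequence == b.sequence for a, b in zip(small_cp.genomes, g2))
        assert t2.labels == small_cp.truth.labels

    def test_zero_rates_give_founder_copies(self):
        cfg = SimulationConfig(
            seed=4, n_accessions=8, genome_kind="cp", genome_length=60000,
            snp_rate=0, small_indel_rate=0, large_insertion_rate=0,
            unanchored_rate=0, site_spacing=None, gene_deletion_rate=0,
            gene_duplication_rate=0, randomize_rotation=False,
        )
        profile = default_profile(seed=4, gc=cfg.gc_content)
        fs = build_founders(cfg, profile)
        genomes, truth = simulate_population(cfg, fs)
        for g in genomes:
            assert g.sequence == fs[truth.labels[g.id]].sequence

    def test_truth_alleles_extractable(self, small_cp):
        """Extracting the recorded coordinate from the accession sequence
        shows the recorded alternate allele (through rotation and founder
        coordinate shifts)."""
        truth = small_cp.truth
        checked = 0
        for ev in truth.events:
            if ev.tag.startswith("founder") or not ev.alt:
                continue
            for acc in sorted(ev.carriers)[:1]:
                g = truth.labels[acc]
                fp = truth.founder_set.shift(g)(ev.pos)
                ff = truth.founder_frame_seq(acc)
                # position within the accession's own frame includes its
                # other events before this one
                own = [
                    (truth.founder_set.shift(g)(e.pos), e.ref, e.alt)
                    for e in truth.events
                    if acc in e.carriers and not e.tag.startswith("founder")
                    and e.pos < ev.pos
                ]
                delta = sum(len(a) - len(r) for _, r, a in own)
                assert ff[fp + delta : fp + delta + len(ev.alt)] == ev.alt
                checked += 1
        assert checked > 50

    def test_rotation_and_flip_recorded(self, small_cp):
        truth = small_cp.truth
        for g in small_cp.genomes[:4]:
            off, flip = truth.rotations[g.id]
            ff = truth.founder_frame_seq(g.id)
            expected = rotate(ff, off)
            if flip:
                expected = revcomp(expected)
            assert g.sequence == expected
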
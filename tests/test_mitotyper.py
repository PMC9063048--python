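"""Mitotype classification from MSS markers and ORF profiles."""

import random

import numpy as np
import pandas as pd
import pytest

from orgpan.circseq import CircularGenome, revcomp, rotate
from orgpan.mitotyper import (
    MitotypeProfile,
    classify,
    detect_marker,
    frequency_table,
)
from orgpan.synthetic_data import default_profile


@pytest.fixture(scope="module")
def genome_with_marker():
    rng = random.Random(1)
    marker = "".join(rng.choice("ACGT") for _ in range(300))
    bg = "".join(rng.choice("ACGT") for _ in range(20000))
    return CircularGenome("g", bg[:8000] + marker + bg[8000:]), marker


class TestDetectMarker:
    def test_verbatim_marker_found(self, genome_with_marker):
        genome, marker = genome_with_marker
        hit = detect_marker(genome, marker)
        assert hit.present and hit.identity == 1.0 and hit.position == 8000

    def test_reverse_strand_found(self, genome_with_marker):
        genome, marker = genome_with_marker
        hit = detect_marker(genome, revcomp(marker))
        assert hit.present and hit.strand == "-"

    def test_scrambled_quarter_below_threshold(self, genome_with_marker):
        genome, marker = genome_with_marker
        rng = random.Random(2)
        m = list(marker)
        for p in rng.sample(range(300), 75):  # identity drops to ~0.75
            m[p] = rng.choice([c for c in "ACGT" if c != m[p]])
        hit = detect_marker(genome, "".join(m), threshold=0.80)
        assert not hit.present
        assert hit.identity < 0.80

    def test_marker_straddling_origin(self, genome_with_marker):
        genome, marker = genome_with_marker
        # rotate so the marker spans position 0
        g = CircularGenome("r", rotate(genome.sequence, 8150))
        hit = detect_marker(g, marker)
        assert hit.present and hit.identity == 1.0

    def test_absent_marker(self, genome_with_marker):
        genome, _ = genome_with_marker
        rng = random.Random(3)
        other = "".join(rng.choice("ACGT") for _ in range(300))
        assert not detect_marker(genome, other).present

    def test_lowering_threshold_never_hides_marker(self, genome_with_marker):
        """Monotonicity: a present marker stays present at lower thresholds."""
        genome, marker = genome_with_marker
        rng = random.Random(4)
        m = list(marker)
        for p in rng.sample(range(300), 30):
            m[p] = rng.choice([c for c in "ACGT" if c != m[p]])
        m = "".join(m)
        presences = [detect_marker(genome, m, threshold=t).present
                     for t in (0.95, 0.9, 0.85, 0.8, 0.7)]
        # once present, present for every lower threshold
        assert presences == sorted(presences)

    def test_bad_alphabet_rejected(self, genome_with_marker):
        genome, _ = genome_with_marker
        with pytest.raises(ValueError):
            detect_marker(genome, "ACGU" * 50)

    def test_default_thresholds_per_marker(self):
        profile = default_profile(seed=0)
        assert profile.thresholds["MSS4"] == 0.90
        assert profile.thresholds["MSS9"] == 0.85
        assert profile.thresholds["MSS1"] == 0.80


class TestClassify:
    def test_exact_profile_match(self, small_mt):
        g = small_mt.genomes[0]
        call = classify(g, small_mt.profile)
        assert call.call == small_mt.truth.labels[g.id]
        assert call.agreement[call.call] == 1.0

    def test_rotation_and_strand_invariance(self, small_mt):
        g = small_mt.genomes[0]
        expected = small_mt.truth.labels[g.id]
        for variant in (rotate(g.sequence, 50_000), revcomp(g.sequence)):
            call = classify(CircularGenome("v", variant), small_mt.profile)
            assert call.call == expected

    def test_mixed_vector_becomes_like(self, small_mt):
        """A genome whose markers mostly-but-not-exactly match one column is
        called '<type>-like'."""
        profile = small_mt.profile
        fs = small_mt.founders
        base_group = small_mt.cfg.base_group
        founder = fs[base_group]
        # blank out one MSS the base column expects present; the resulting
        # vector matches no column exactly but stays closest to base_group
        mid = next(
            m for m in profile.markers
            if profile.expected.loc[m, base_group] and m in fs.marker_intervals
        )
        s, e = fs.marker_intervals[mid]
        rng = random.Random(7)
        filler = "".join(rng.choice("ACGT") for _ in range(e - s))
        seq2 = founder.sequence[:s] + filler + founder.sequence[e:]
        call = classify(CircularGenome("m", seq2), profile)
        assert call.call == f"{base_group}-like"

    def test_tie_is_unclassified(self):
        rng = random.Random(5)
        markers = {
            f"M{i}": "".join(rng.choice("ACGT") for _ in range(200)) for i in range(4)
        }
        expected = pd.DataFrame(
            {"x": [True, True, False, False], "y": [False, False, True, True]},
            index=list(markers),
        )
        profile = MitotypeProfile(markers=markers, orfs={}, expected=expected)
        # genome carries M0 and M2: agreement 0.5 with both columns
        bg = "".join(rng.choice("ACGT") for _ in range(20000))
        seq = bg[:5000] + markers["M0"] + bg[5000:10000] + markers["M2"] + bg[10000:]
        call = classify(CircularGenome("g", seq), profile, like_cutoff=0.4)
        assert call.call == "unclassified"


class TestFrequencyTable:
    def test_published_style_percentages(self):
        freq = frequency_table({"nap": 1215, "cam": 170, "pol": 53, "ole": 18})
        got = dict(zip(freq["mitotype"], freq["percentage"]))
        assert got == {"nap": 83.45, "cam": 11.68, "pol": 3.64, "ole": 1.24}

    def test_single_type_is_hundred(self):
        freq = frequency_table({"nap": 7})
        assert freq["percentage"].tolist() == [100.00]


class TestProfileValidation:
    def test_homologous_markers_rejected(self):
        rng = random.Random(6)
        seq = "".join(rng.choice("ACGT") for _ in range(300))
        near = seq[:290] + "ACGTACGTAC"
        profile = MitotypeProfile(
            markers={"A": seq, "B": near},
            orfs={},
            expected=pd.DataFrame({"x": [True, False], "y": [False, True]},
                                  index=["A", "B"]),
        )
        with pytest.raises(ValueError):
            profile.validate()

    def test_threshold_range_checked(self):
        profile = default_profile(seed=0)
        profile.thresholds["MSS1"] = 1.5
        with pytest.raises(ValueError):
            profile.validate()
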
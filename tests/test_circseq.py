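"""Circular-sequence model and pairwise aligner."""

import random

import pytest

from orgpan.circseq import (
    CircularGenome,
    UnalignableError,
    align_pair,
    circular_chain_runs,
    diff_from_chains,
    normalize_rotation,
    reconstruct_query,
    revcomp,
    rotate,
)


@pytest.fixture(scope="module")
def base20k():
    rng = random.Random(1)
    return "".join(rng.choice("ACGT") for _ in range(20000))


def mutate(seq, positions, rng):
    s = list(seq)
    for p in positions:
        s[p] = rng.choice([c for c in "ACGT" if c != s[p]])
    return "".join(s)


class TestCircularGenome:
    def test_rejects_bad_alphabet(self):
        with pytest.raises(ValueError):
            CircularGenome("x", "ACGTX" * 100)

    def test_rejects_excess_n(self):
        with pytest.raises(ValueError):
            CircularGenome("x", "ACGTN" * 100)  # 20% N

    def test_length_and_gc(self):
        g = CircularGenome("x", "ACGT" * 100)
        assert len(g) == 400 and g.gc_content() == 0.5


class TestNormalizeRotation:
    def test_derotates_exactly(self, base20k):
        ref = CircularGenome("ref", base20k)
        g = CircularGenome("g", rotate(base20k, 10000))
        assert normalize_rotation(g, ref).sequence == base20k

    def test_reverse_complement_restored(self, base20k):
        ref = CircularGenome("ref", base20k)
        g = CircularGenome("g", revcomp(base20k))
        assert normalize_rotation(g, ref).sequence == base20k

    def test_idempotent(self, base20k):
        rng = random.Random(2)
        ref = CircularGenome("ref", base20k)
        mut = mutate(base20k, rng.sample(range(100, 19900), 40), rng)
        g = CircularGenome("g", revcomp(rotate(mut, 777)))
        once = normalize_rotation(g, ref)
        twice = normalize_rotation(once, ref)
        assert once.sequence == twice.sequence

    def test_snps_preserved_through_derotation(self, base20k):
        rng = random.Random(3)
        ref = CircularGenome("ref", base20k)
        positions = sorted(rng.sample(range(200, 19800), 50))
        mut = mutate(base20k, positions, rng)
        g = normalize_rotation(CircularGenome("g", rotate(mut, 3000)), ref)
        diffs = sum(1 for a, b in zip(g.sequence, base20k) if a != b)
        assert diffs == 50

    def test_unalignable_error(self, base20k):
        rng = random.Random(4)
        other = "".join(rng.choice("ACGT") for _ in range(5000))
        with pytest.raises(UnalignableError):
            normalize_rotation(CircularGenome("g", other), CircularGenome("r", base20k))


class TestAlignPair:
    def test_self_alignment_single_full_chain(self, base20k):
        a = CircularGenome("a", base20k)
        chains = align_pair(a, CircularGenome("b", base20k))
        assert len(chains) == 1
        assert chains[0].identity == 1.0
        assert chains[0].query_coverage == 1.0
        assert chains[0].subject_coverage == 1.0

    def test_k_constraints(self, base20k):
        a = CircularGenome("a", base20k)
        with pytest.raises(ValueError):
            align_pair(a, a, k=10)
        with pytest.raises(ValueError):
            align_pair(CircularGenome("s", "ACGT" * 10), a, k=50)

    def test_inverted_segment_yields_strand_flip(self, base20k):
        ref = CircularGenome("ref", base20k)
        q = base20k[:15000] + revcomp(base20k[15000:15500]) + base20k[15500:]
        chains = align_pair(CircularGenome("q", q), ref)
        assert {"+", "-"} <= {c.strand for c in chains}
        assert len(chains) >= 2

    def test_inverted_repeat_bridged_in_one_chain(self, base20k):
        # IRa ... IRb=revcomp(IRa): anchors inside are strand-ambiguous and
        # excluded, but banded closing keeps the chain whole
        ira = base20k[5000:7000]
        cp = base20k[:10000] + ira + base20k[10000:15000] + revcomp(ira) + base20k[15000:]
        g = CircularGenome("cp", cp)
        chains = align_pair(g, CircularGenome("cp2", cp))
        assert len(chains) == 1 and chains[0].identity == 1.0


class TestDiffAndRoundTrip:
    def test_single_snp(self, base20k):
        ref = CircularGenome("ref", base20k)
        q = base20k[:1000] + ("A" if base20k[1000] != "A" else "G") + base20k[1001:]
        qg = CircularGenome("q", q)
        chains = align_pair(qg, ref)
        d = diff_from_chains(chains, qg, ref)
        assert len(d.snps) == 1
        assert d.snps[0][0] == 1000 and d.snps[0][1] == base20k[1000]
        assert not d.small_indels and not d.insertions and not d.deletions

    def test_small_deletion_vs_insertion_thresholds(self, base20k):
        rng = random.Random(5)
        ref = CircularGenome("ref", base20k)
        novel = "".join(rng.choice("ACGT") for _ in range(25))
        q = base20k[:4000] + base20k[4007:9000] + novel + base20k[9000:]
        qg = CircularGenome("q", q)
        chains = align_pair(qg, ref)
        d = diff_from_chains(chains, qg, ref)
        assert len(d.small_indels) == 1  # 7 bp <= 10
        assert len(d.insertions) == 1 and len(d.insertions[0][1]) == 25
        assert not d.deletions

    def test_unanchored_fragment_at_breakpoint(self, base20k):
        rng = random.Random(6)
        ref = CircularGenome("ref", base20k)
        frag = "".join(rng.choice("ACGT") for _ in range(300))
        q = base20k[:8000] + frag + revcomp(base20k[8000:13000]) + base20k[13000:]
        qg = CircularGenome("q", q)
        chains = align_pair(qg, ref)
        d = diff_from_chains(chains, qg, ref)
        assert len(d.unanchored) == 1
        qs, qe, seq = d.unanchored[0]
        assert qe - qs > 100 and frag in seq

    @pytest.mark.parametrize("seed", [7, 8, 9])
    def test_round_trip_reconstructs_query(self, base20k, seed):
        """Applying the diff to the subject rebuilds the query exactly."""
        rng = random.Random(seed)
        ref = CircularGenome("ref", base20k)
        q = base20k
        # inversion, insertion, deletion, SNPs -- well separated
        q = q[:2000] + "".join(rng.choice("ACGT") for _ in range(400)) + q[2000:]
        q = q[:6000] + q[6300:]
        q = q[:10000 + 100] + revcomp(q[10100:11100]) + q[11100:]
        q = mutate(q, rng.sample(range(15000, 19000), 20), rng)
        qg = CircularGenome("q", rotate(q, rng.randrange(len(q))))
        qn = normalize_rotation(qg, ref)
        chains = align_pair(qn, ref)
        d = diff_from_chains(chains, qn, ref)
        assert reconstruct_query(chains, d, ref) == qn.sequence

    def test_alignment_invariant_to_rotation(self, base20k):
        rng = random.Random(10)
        ref = CircularGenome("ref", base20k)
        mut = mutate(base20k, rng.sample(range(200, 19800), 30), rng)
        results = []
        for off in (0, 5000, 12345):
            g = normalize_rotation(CircularGenome("g", rotate(mut, off)), ref)
            chains = align_pair(g, ref)
            d = diff_from_chains(chains, g, ref)
            results.append(sorted(d.snps))
        assert results[0] == results[1] == results[2]


class TestCircularChainRuns:
    def test_collinear_pair_is_one_run(self, small_mt):
        fs = small_mt.founders
        a, b = fs[small_mt.cfg.collinear_pair[0]], fs[small_mt.cfg.collinear_pair[1]]
        an = normalize_rotation(a, b)
        chains = align_pair(an, b)
        assert circular_chain_runs(chains, len(an), len(b)) == 1

    def test_rearranged_pair_has_extra_runs(self, small_mt):
        fs = small_mt.founders
        base_group = small_mt.cfg.base_group
        other = small_mt.cfg.collinear_pair[0]
        a, b = fs[base_group], fs[other]
        an = normalize_rotation(a, b)
        chains = align_pair(an, b)
        assert circular_chain_runs(chains, len(an), len(b)) >= 2
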
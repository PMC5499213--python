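import numpy as np
import pytest

from segdup.align import (
    AlignmentPair,
    align_codes_ext,
    align_strings,
    discard_self,
    encode,
    refine,
    reinsert,
    revcomp_codes,
    self_align,
)
from segdup.masking import RepeatAnnotation, fuguize

from conftest import mutate_seq, random_seq, revcomp
from _dp_oracle import gotoh_full


class TestPairwiseCore:
    def test_identical_sequences(self):
        score, mat, mis, gap = align_strings("ACGT" * 500, "ACGT" * 500)
        assert (score, mat, mis, gap) == (2000, 2000, 0, 0)

    def test_known_substitution_and_gap(self):
        assert align_strings("ACGTACGT", "ACGAACGT") == (5, 7, 1, 0)
        # one-base deletion inside a longer context survives trimming
        a = "ACGTTGCAACGTGGCA"
        b = "ACGTTGCACGTGGCA"
        score, mat, mis, gap = align_strings(a, b)
        assert (mat, mis, gap) == (15, 0, 1)
        assert score == 15 - 6

    def test_symmetry_of_identity(self):
        rng = np.random.default_rng(3)
        a = random_seq(rng, 800)
        b = mutate_seq(rng, a, 0.1)
        r1 = align_strings(a, b)
        r2 = align_strings(b, a)
        assert r1[1:] == r2[1:] and r1[0] == r2[0]

    def test_ns_never_match(self):
        score, mat, mis, gap = align_strings("NNNN", "NNNN")
        assert mat == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_full_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_seq(rng, 600)
        b = mutate_seq(rng, a, 0.12)
        # also throw in a small indel
        b = b[:200] + b[204:]
        got = align_codes_ext(encode(a), encode(b))
        want = gotoh_full(encode(a), encode(b))
        assert got[:5] == want

    def test_global_score_matches_biopython(self):
        from Bio import Align

        aligner = Align.PairwiseAligner(
            mode="global", match_score=1, mismatch_score=-2,
            open_gap_score=-6, extend_gap_score=-1,
        )
        rng = np.random.default_rng(5)
        for n in (80, 300, 1200):
            a = random_seq(rng, n)
            b = mutate_seq(rng, a, 0.15)[: n - 7]
            global_score = align_codes_ext(encode(a), encode(b))[0]
            assert global_score == aligner.score(a, b)


class TestSelfAlign:
    def test_exact_duplicate_block(self):
        rng = np.random.default_rng(1)
        block = random_seq(rng, 1500)
        seq = random_seq(rng, 2000) + block + random_seq(rng, 2000) + block + random_seq(rng, 500)
        (p,) = self_align({"chr1": seq})
        assert p.identity == 100.0
        # boundaries within a few chance-matched bases of the planted copy
        assert abs(p.start_a - 2000) <= 8 and abs(p.start_b - 5500) <= 8
        assert p.aligned_columns >= 1500

    def test_planted_divergence_identity(self):
        rng = np.random.default_rng(2)
        block = random_seq(rng, 1500)
        copy = mutate_seq(rng, block, 0.10)
        true_id = 100 * sum(a == b for a, b in zip(block, copy)) / 1500
        seq = random_seq(rng, 1000) + block + random_seq(rng, 1000) + copy + random_seq(rng, 500)
        (p,) = self_align({"chr1": seq})
        assert p.identity == pytest.approx(true_id, abs=1.0)

    def test_reverse_strand_copy_found(self):
        rng = np.random.default_rng(4)
        block = random_seq(rng, 1400)
        seq = random_seq(rng, 900) + block + random_seq(rng, 1100) + revcomp(block) + random_seq(rng, 700)
        (p,) = self_align({"chr1": seq})
        assert p.strand == "-"
        assert abs(p.start_a - 900) <= 8
        assert abs(p.start_b - (900 + 1400 + 1100)) <= 8

    def test_random_genome_yields_no_long_alignment(self):
        rng = np.random.default_rng(16)
        seq = random_seq(rng, 200_000)
        pairs = self_align({"chr1": seq}, k=16)
        assert all(p.aligned_columns < 1000 for p in pairs)

    def test_min_score_monotonicity(self):
        rng = np.random.default_rng(6)
        parts = [random_seq(rng, 800)]
        for _ in range(4):
            block = random_seq(rng, 1200)
            parts += [block, random_seq(rng, 500), mutate_seq(rng, block, 0.2), random_seq(rng, 400)]
        seq = "".join(parts)
        n_low = len(self_align({"chr1": seq}, min_score=100))
        n_high = len(self_align({"chr1": seq}, min_score=400))
        assert n_high <= n_low

    def test_k_larger_than_sequences_returns_empty(self):
        assert self_align({"c": "ACGT"}, k=14) == []


class TestDiscardSelf:
    def _pair(self, sa, ea, sb, eb, strand="+"):
        return AlignmentPair("c", sa, ea, "c", sb, eb, strand, ea - sa, 0, 0, ea - sa)

    def test_identical_intervals_removed(self):
        assert discard_self([self._pair(0, 2000, 0, 2000)]) == []

    def test_tandem_retained_at_half_overlap(self):
        p = self._pair(0, 2000, 1000, 3000)
        assert discard_self([p]) == [p]

    def test_near_self_overlap_removed(self):
        p = self._pair(0, 2000, 100, 2100)
        assert discard_self([p]) == []

    def test_reverse_strand_untouched(self):
        p = self._pair(0, 2000, 100, 2100, strand="-")
        assert discard_self([p]) == [p]


class TestReinsertRefine:
    def test_toy_liftover(self):
        genome = {"c": "ACGTACGT"}
        _, cmap = fuguize(genome, [RepeatAnnotation("c", 2, 4, "DNA")])
        p = AlignmentPair("c", 0, 6, "c", 0, 6, "+", 6, 0, 0, 6)
        (out,) = reinsert([p], cmap, min_anchor=1)
        assert (out.start_a, out.end_a) == (0, 8)
        assert out.stale

    def test_interior_repeat_expands_interval_exactly(self):
        rng = np.random.default_rng(8)
        te = random_seq(rng, 300)
        left, right = random_seq(rng, 700), random_seq(rng, 700)
        block = left + te + right
        seq = random_seq(rng, 500) + block + random_seq(rng, 800) + block + random_seq(rng, 400)
        genome = {"c": seq}
        reps = [
            RepeatAnnotation("c", 500 + 700, 500 + 700 + 300, "DNA"),
            RepeatAnnotation("c", 500 + 1700 + 800 + 700, 500 + 1700 + 800 + 700 + 300, "DNA"),
        ]
        fugu, cmap = fuguize(genome, reps)
        pairs = discard_self(self_align(fugu))
        assert len(pairs) == 1
        fugu_len = pairs[0].len_a
        (out,) = reinsert(pairs, cmap)
        assert out.len_a == fugu_len + 300  # exactly the interior repeat bp
        (ref,) = refine([out], genome)
        assert not ref.stale
        assert ref.identity == 100.0

    def test_divergent_repeat_copies_lower_refined_identity(self):
        rng = np.random.default_rng(9)
        te = random_seq(rng, 300)
        te_div = mutate_seq(rng, te, 0.2)  # repeat copies differ at 20%
        left, right = random_seq(rng, 800), random_seq(rng, 800)
        seq = (
            random_seq(rng, 400)
            + left + te + right
            + random_seq(rng, 900)
            + left + te_div + right
            + random_seq(rng, 300)
        )
        genome = {"c": seq}
        s1 = 400 + 800
        s2 = 400 + 1900 + 900 + 800
        reps = [
            RepeatAnnotation("c", s1, s1 + 300, "DNA"),
            RepeatAnnotation("c", s2, s2 + 300, "DNA"),
        ]
        fugu, cmap = fuguize(genome, reps)
        pairs = discard_self(self_align(fugu))
        assert len(pairs) == 1
        fugu_identity = pairs[0].identity
        (ref,) = refine(reinsert(pairs, cmap), genome)
        assert ref.identity < fugu_identity  # divergent repeat copies included
        assert ref.identity == pytest.approx(100 * (1900 - 60) / 1900, abs=1.5)

    def test_refine_skips_oversized_intervals(self, caplog):
        genome = {"c": "ACGT" * 600}
        p = AlignmentPair("c", 0, 2400, "c", 0, 2400, "+", 0, 0, 0, 0, stale=True)
        out = refine([p], genome, max_interval=1000)
        assert out == []
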
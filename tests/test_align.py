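import numpy as np
import pytest
from Bio import Align

from cnekit._seqtools import revcomp
from cnekit.align import AlignerParams, AlignmentBlock, seed_extend_align, slice_block, two_round_align, hard_mask
from cnekit.chain import Chain, chain_blocks, net_chains, net_blocks
from cnekit.model import Interval

from conftest import random_dna


def sw_aligner(params: AlignerParams) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = params.match
    a.mismatch_score = params.mismatch
    a.open_gap_score = params.gap_open + params.gap_extend
    a.extend_gap_score = params.gap_extend
    return a


class TestSeedExtend:
    def test_exact_copy_single_block(self, rng):
        ref = {"chr1": random_dna(rng, 20_000)}
        insert = ref["chr1"][3_000:3_500]
        query = {"q": random_dna(rng, 5_000) + insert + random_dna(rng, 5_000)}
        blocks = seed_extend_align(ref, query, AlignerParams())
        spans = [b for b in blocks if b.ref.start <= 3_000 and b.ref.end >= 3_500]
        assert len(spans) == 1
        assert spans[0].identity() == 1.0 and spans[0].strand == "+"

    def test_revcomp_copy_minus_strand(self, rng):
        ref = {"chr1": random_dna(rng, 20_000)}
        insert = revcomp(ref["chr1"][3_000:3_500])
        query = {"q": insert}
        blocks = seed_extend_align(ref, query, AlignerParams())
        assert len(blocks) == 1
        b = blocks[0]
        assert b.strand == "-" and b.ref.start <= 3_000 and b.ref.end >= 3_500

    def test_masked_repeats_never_seeded(self, rng):
        seq = random_dna(rng, 10_000)
        ref = {"chr1": seq}
        masked = hard_mask(ref, [Interval("chr1", 2_000, 3_000)])
        query = {"q": seq[2_100, ] if False else seq[2_100:2_900]}
        assert seed_extend_align(masked, query, AlignerParams()) == []

    def test_planted_homologies_match_smith_waterman(self, rng):
        """Planted 85%-identity homologies are recovered with the score an
        exhaustive Smith-Waterman assigns to them."""
        params = AlignerParams()
        aligner = sw_aligner(params)
        for case in range(4):
            core = random_dna(rng, 300)
            mutated = "".join(
                c if rng.random() > 0.15 else "ACGT"[rng.integers(0, 4)] for c in core
            )
            g1 = random_dna(rng, 25_000) + core + random_dna(rng, 25_000)
            g2 = random_dna(rng, 10_000) + mutated + random_dna(rng, 10_000)
            blocks = seed_extend_align({"r": g1}, {"q": g2}, params)
            hits = [b for b in blocks if b.ref.start < 25_300 and b.ref.end > 25_000]
            assert hits, "planted homology not recovered"
            best = max(h.score for h in hits)
            sw = aligner.score(core, mutated)
            assert best == pytest.approx(sw, abs=2)


class TestTwoRound:
    def test_vacuous_masking_equals_single_round(self, rng):
        ref = {"r": random_dna(rng, 8_000)}
        query = {"q": random_dna(rng, 8_000)}
        assert two_round_align(ref, query) == seed_extend_align(ref, query) == []

    def test_round2_equals_manual_masking(self, rng):
        """Round-2 output equals a single round on inputs with round-1
        coverage hard-masked."""
        params = AlignerParams()
        core = random_dna(rng, 400)
        ref = {"r": random_dna(rng, 5_000) + core + random_dna(rng, 5_000)}
        query = {"q": random_dna(rng, 2_000) + core + random_dna(rng, 2_000) + core + random_dna(rng, 2_000)}
        out = two_round_align(ref, query, params)
        r1 = [b for b in out if b.round == 1]
        r2 = [b for b in out if b.round == 2]
        masked_ref = hard_mask(ref, [b.ref for b in r1])
        masked_query = hard_mask(query, [b.query for b in r1])
        manual = seed_extend_align(masked_ref, masked_query, params)
        assert [(b.ref, b.query) for b in r2] == [(b.ref, b.query) for b in manual]

    def test_rounds_never_overlap_on_reference(self, rng):
        core = random_dna(rng, 400)
        ref = {"r": random_dna(rng, 3_000) + core + random_dna(rng, 3_000)}
        query = {"q": core + random_dna(rng, 1_000) + core}
        out = two_round_align(ref, query)
        r1 = [b.ref for b in out if b.round == 1]
        r2 = [b.ref for b in out if b.round == 2]
        for a in r1:
            for b in r2:
                assert not a.overlaps(b)


def _mk_block(ref_start, ref_end, q_start, q_end, score, chrom="r", qchrom="q", strand="+", rng=None):
    n = ref_end - ref_start
    seq = random_dna(rng, n) if rng is not None else "A" * n
    return AlignmentBlock(
        ref=Interval(chrom, ref_start, ref_end),
        query=Interval(qchrom, q_start, q_end, strand),
        strand=strand,
        ref_aln=seq,
        query_aln=seq,
        score=score,
    )


def brute_force_best_chain(blocks, gap_open, per_bp, max_gap):
    """Exhaustive maximum chain score over all valid ordered subsets."""
    n = len(blocks)
    best = 0.0

    def qs(b):
        return (b.query.start, b.query.end) if b.strand == "+" else (-b.query.end, -b.query.start)

    def rec(last, score, remaining):
        nonlocal best
        best = max(best, score)
        for i in list(remaining):
            b = blocks[i]
            if last is not None:
                rgap = b.ref.start - last.ref.end
                qgap = qs(b)[0] - qs(last)[1]
                if rgap < 0 or qgap < 0 or rgap > max_gap or qgap > max_gap:
                    continue
                cost = gap_open + per_bp * (rgap + qgap)
            else:
                cost = 0.0
            rec(b, score + b.score - cost, remaining - {i})

    rec(None, 0.0, frozenset(range(n)))
    return best


class TestChaining:
    def test_singleton(self):
        b = _mk_block(10, 60, 0, 50, 50)
        (chain,) = chain_blocks([b])
        assert chain.blocks == [b] and chain.ref_span == Interval("r", 10, 60)

    def test_three_collinear_blocks_one_chain(self):
        blocks = [
            _mk_block(0, 100, 0, 100, 100),
            _mk_block(200, 300, 200, 300, 100),
            _mk_block(400, 500, 400, 500, 100),
        ]
        chains = chain_blocks(blocks, gap_open=50, per_bp_gap_cost=0.1, max_gap=1_000)
        assert len(chains) == 1 and len(chains[0].blocks) == 3
        expected = brute_force_best_chain(blocks, 50, 0.1, 1_000)
        assert chains[0].total_score == pytest.approx(expected)

    def test_blocks_on_different_query_chroms_never_chained(self):
        b1 = _mk_block(0, 100, 0, 100, 100, qchrom="q1")
        b2 = _mk_block(200, 300, 200, 300, 100, qchrom="q2")
        chains = chain_blocks([b1, b2])
        assert len(chains) == 2

    def test_dp_equals_brute_force(self, rng):
        """Best chain score equals exhaustive chaining on <= 8 random blocks."""
        for case in range(200):
            n = int(rng.integers(1, 9))
            blocks = []
            pos = 0
            qpos = int(rng.integers(0, 50))
            for _ in range(n):
                pos += int(rng.integers(0, 400))
                qpos += int(rng.integers(0, 400))
                length = int(rng.integers(20, 120))
                blocks.append(_mk_block(pos, pos + length, qpos, qpos + length, float(rng.integers(10, 200))))
                pos += length
                qpos += length
            rng.shuffle(blocks)
            blocks = sorted(blocks, key=lambda b: b.ref.start)
            go, pb, mg = 30.0, 0.5, int(rng.integers(100, 900))
            chains = chain_blocks(blocks, go, pb, mg)
            expected = brute_force_best_chain(blocks, go, pb, mg)
            assert max(c.total_score for c in chains) == pytest.approx(expected), f"case {case}"

    def test_overlapping_inputs_trimmed_at_midpoint(self, rng):
        b1 = _mk_block(0, 100, 0, 100, 100, rng=rng)
        b2 = _mk_block(80, 180, 300, 400, 100, rng=rng)
        chains = chain_blocks([b1, b2], max_gap=50)
        spans = sorted((blk.ref.start, blk.ref.end) for c in chains for blk in c.blocks)
        assert spans == [(0, 90), (90, 180)]


class TestNetting:
    def test_disjoint_chains_kept_whole(self, rng):
        c1 = Chain([_mk_block(0, 100, 0, 100, 100, rng=rng)])
        c2 = Chain([_mk_block(200, 300, 0, 100, 80, rng=rng)])
        net = net_chains([c1, c2])
        assert len(net) == 2

    def test_full_overlap_keeps_higher_score(self, rng):
        hi = Chain([_mk_block(0, 100, 0, 100, 100, rng=rng)])
        lo = Chain([_mk_block(0, 100, 500, 600, 60, rng=rng)])
        net = net_chains([lo, hi])
        assert len(net) == 1 and net[0].total_score == 100

    def test_partial_overlap_trims_to_union(self, rng):
        hi = Chain([_mk_block(0, 150, 0, 150, 150, rng=rng)])
        lo = Chain([_mk_block(100, 300, 500, 700, 120, rng=rng)])
        net = net_chains([hi, lo], min_fragment=1)
        covered = sorted((b.ref.start, b.ref.end) for c in net for b in c.blocks)
        # total kept coverage equals the union of the inputs
        total = sum(e - s for s, e in covered)
        assert total == 300
        for (s1, e1), (s2, e2) in zip(covered, covered[1:]):
            assert e1 <= s2

    def test_net_reference_coverage_overlap_free(self, rng):
        chains = []
        for _ in range(30):
            s = int(rng.integers(0, 2_000))
            L = int(rng.integers(20, 300))
            chains.append(Chain([_mk_block(s, s + L, 0, L, float(rng.integers(10, 100)), rng=rng)]))
        net = net_chains(chains, min_fragment=1)
        ivs = sorted((b.ref.start, b.ref.end) for c in net for b in c.blocks)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2


class TestSliceBlock:
    def test_slice_preserves_invariants(self, rng):
        b = _mk_block(100, 200, 50, 150, 100, rng=rng)
        piece = slice_block(b, 120, 170)
        assert piece.ref == Interval("r", 120, 170)
        assert piece.query == Interval("q", 70, 120)
        assert len(piece.ref_aln) == len(piece.query_aln) == 50

    def test_slice_minus_strand(self, rng):
        n = 100
        seq = random_dna(rng, n)
        b = AlignmentBlock(Interval("r", 0, n), Interval("q", 300, 400, "-"), "-", seq, seq, 100)
        piece = slice_block(b, 10, 40)
        # oriented query consumed 10 bases from the high end
        assert piece.query == Interval("q", 360, 390, "-")
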
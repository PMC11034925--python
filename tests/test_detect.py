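import numpy as np
import pytest

from cnekit.align import AlignmentBlock
from cnekit.detect import (
    CNERecord,
    CNESet,
    DetectParams,
    filter_repetitive,
    mask_annotations,
    merge_candidates,
    scan_conserved,
)
from cnekit.model import Interval, SpeciesGenome

from conftest import random_dna


def mk_block(ref_aln, query_aln, ref_start=0, chrom="chr1"):
    n_ref = len(ref_aln.replace("-", ""))
    n_q = len(query_aln.replace("-", ""))
    return AlignmentBlock(
        ref=Interval(chrom, ref_start, ref_start + n_ref),
        query=Interval("q", 0, n_q),
        strand="+",
        ref_aln=ref_aln,
        query_aln=query_aln,
        score=1,
    )


def plain_params(**kw):
    base = dict(window=100, min_identity=0.70, min_length=100, edge_trim=False)
    base.update(kw)
    return DetectParams(**base)


class TestMaskAnnotations:
    def test_no_annotations_nothing_excluded(self, rng):
        seq = random_dna(rng, 200)
        out = mask_annotations([mk_block(seq, seq)], [], [])
        assert len(out) == 1 and not out[0][1].any()

    def test_exon_middle_third_excluded(self, rng):
        seq = random_dna(rng, 300)
        (block, excl), = mask_annotations([mk_block(seq, seq)], [Interval("chr1", 100, 200)], [])
        assert excl[100:200].all() and not excl[:100].any() and not excl[200:].any()

    def test_query_gap_columns_not_annotation_flagged(self, rng):
        # ref has a gap column inside an annotated window; only columns with
        # a reference base are flagged
        ref_aln = "AAAA-AAAA"
        q_aln = "AAAAAAAAA"
        (block, excl), = mask_annotations([mk_block(ref_aln, q_aln)], [Interval("chr1", 0, 8)], [])
        per_column = [excl[i] for i in range(9)]
        assert per_column == [True] * 4 + [False] + [True] * 4

    def test_fully_excluded_block_dropped(self, rng):
        seq = random_dna(rng, 50)
        assert mask_annotations([mk_block(seq, seq)], [Interval("chr1", 0, 50)], []) == []


class TestScanConserved:
    def test_perfect_identity_marks_everything(self, rng):
        seq = random_dna(rng, 150)
        marked = scan_conserved(mk_block(seq, seq), plain_params())
        assert len(marked) == 150 and marked[0] == 0 and marked[-1] == 149

    def test_alternating_half_identity_marks_nothing(self):
        ref = "AC" * 100
        query = "AG" * 100
        assert len(scan_conserved(mk_block(ref, query), plain_params())) == 0

    def test_short_block_empty(self, rng):
        seq = random_dna(rng, 50)
        assert len(scan_conserved(mk_block(seq, seq), plain_params())) == 0

    @staticmethod
    def brute_force_windows(match, window, min_identity, excluded):
        """O(L*W) explicit enumeration of qualifying windows."""
        L = len(match)
        marked = np.zeros(L, dtype=bool)
        for start in range(L - window + 1):
            cols = range(start, start + window)
            if any(excluded[c] for c in cols):
                continue
            ident = sum(match[c] for c in cols) / window
            if ident >= min_identity - 1e-12:
                marked[start : start + window] = True
        return marked

    def test_matches_brute_force_enumeration(self, rng):
        """Window scanner equals the explicit window loop on random gapped
        blocks up to 2 kb (with random exclusions)."""
        for case in range(200):
            L = int(rng.integers(30, 2_000))
            window = int(rng.integers(5, 120))
            p_match = rng.uniform(0.4, 0.95)
            ref = list(random_dna(rng, L))
            query = [c if rng.random() < p_match else "ACGT-"[rng.integers(0, 5)] for c in ref]
            # random reference gaps too
            for i in range(L):
                if rng.random() < 0.02:
                    ref[i] = "-"
            ref_s, query_s = "".join(ref), "".join(query)
            if not ref_s.replace("-", "") or not query_s.replace("-", ""):
                continue
            block = mk_block(ref_s, query_s)
            excluded = rng.random(L) < 0.05
            params = plain_params(window=window, min_length=window, min_identity=float(rng.uniform(0.5, 0.9)))
            got = scan_conserved(block, params, excluded.copy())
            match = block.match_columns()
            marked_cols = self.brute_force_windows(match, window, params.min_identity, excluded)
            pos = block.ref_positions()
            expected = pos[marked_cols & (pos >= 0)]
            assert np.array_equal(got, expected), f"case {case}"


class TestMergeCandidates:
    def test_single_run(self):
        marked = np.arange(1_000, 1_150)
        out = merge_candidates(marked, plain_params())
        assert out == [(1_000, 1_150, 1.0)]

    def test_short_run_discarded(self):
        assert merge_candidates(np.arange(90), plain_params()) == []

    def test_one_bp_gap_keeps_two_elements(self):
        """Two runs separated by a single unmarked bp stay separate
        (run-length-encoding oracle)."""
        marked = np.concatenate([np.arange(0, 120), np.arange(121, 241)])
        out = merge_candidates(marked, plain_params())
        assert [(s, e) for s, e, _ in out] == [(0, 120), (121, 241)]

    def test_mean_identity_recomputed(self):
        marked = np.arange(0, 120)
        ident = {p: p % 10 != 0 for p in range(120)}  # 90% identity
        out = merge_candidates(marked, plain_params(), ident)
        (s, e, mi), = out
        assert mi == pytest.approx(0.9)

    def test_edge_trim_removes_diverged_flanks(self):
        marked = np.arange(0, 160)
        ident = {p: (20 <= p < 140) for p in range(160)}  # diverged 20 bp edges
        out = merge_candidates(marked, DetectParams(edge_trim=True), ident)
        (s, e, mi), = out
        assert s == 20 and e == 140 and mi == 1.0


class TestFilterRepetitive:
    def _genome(self, rng, copies, element, spacer=3_000):
        parts = []
        for _ in range(copies):
            parts.append(random_dna(rng, spacer))
            parts.append(element)
        parts.append(random_dna(rng, spacer))
        return SpeciesGenome(sequences={"chr1": "".join(parts)})

    def _cnes(self, genome, start, length):
        rec = CNERecord("e1", "ref", Interval("chr1", start, start + length), ("ref", "q"), 1.0, length)
        return CNESet("ref", [rec])

    def test_single_copy_kept(self, rng):
        elem = random_dna(rng, 300)
        ref = self._genome(rng, 1, elem)
        pos = ref.sequences["chr1"].find(elem)
        kept = filter_repetitive(self._cnes(ref, pos, 300), ref, SpeciesGenome(sequences={"c": random_dna(rng, 5_000)}))
        assert len(kept) == 1

    def test_high_copy_element_removed(self, rng):
        elem = random_dna(rng, 300)
        ref = self._genome(rng, 10, elem)
        pos = ref.sequences["chr1"].find(elem)
        kept = filter_repetitive(self._cnes(ref, pos, 300), ref, SpeciesGenome(sequences={"c": random_dna(rng, 5_000)}))
        assert len(kept) == 0

    def test_exactly_max_hits_kept(self, rng):
        """The copy-number cutoff is inclusive: exactly four hits survive,
        five do not (hit counts verified by the search engine itself)."""
        elem = random_dna(rng, 300)
        query = SpeciesGenome(sequences={"c": random_dna(rng, 5_000)})
        ref4 = self._genome(rng, 4, elem)
        pos = ref4.sequences["chr1"].find(elem)
        assert len(filter_repetitive(self._cnes(ref4, pos, 300), ref4, query, max_hits=4)) == 1
        ref5 = self._genome(rng, 5, elem)
        pos = ref5.sequences["chr1"].find(elem)
        assert len(filter_repetitive(self._cnes(ref5, pos, 300), ref5, query, max_hits=4)) == 0
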
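"""Desk-scale seed-and-extend pairwise genome alignment.

The aligner is deliberately simple: exact k-mer seeds on both strands,
ungapped x-drop extension, per-diagonal seed coverage filtering. It is meant
for small (megabase-scale) genomes whose homologous regions differ mostly by
substitutions; for real whole-genome work users import AXT produced by an
external aligner (LASTZ-style settings can be recorded in
``AlignerParams.external_params`` untouched).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._seqtools import KmerIndex, decode, encode, kmer_codes, revcomp_arr
from .model import Interval, SpeciesGenome

log = logging.getLogger(__name__)


@dataclass
class AlignerParams:
    seed_length: int = 12
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    x_drop: int = 20
    min_block_score: int = 30
    #: opaque passthrough for recording external aligner settings (e.g. LASTZ
    #: "M=50, E=30, H=2000"); never interpreted by this package.
    external_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.seed_length < 4:
            raise ValueError("seed_length must be >= 4")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("penalties must be negative")


@dataclass
class AlignmentBlock:
    """One gapped local alignment between a reference and a query interval.

    ``query`` is always a forward-strand interval; ``query_aln`` is oriented
    along the reference (reverse-complemented text for minus-strand blocks).
    """

    ref: Interval
    query: Interval
    strand: str
    ref_aln: str
    query_aln: str
    score: float
    round: int = 1

    def __post_init__(self):
        if len(self.ref_aln) != len(self.query_aln):
            raise ValueError("gapped rows differ in length")
        if len(self.ref_aln.replace("-", "")) != len(self.ref):
            raise ValueError("ref_aln does not match ref interval length")
        if len(self.query_aln.replace("-", "")) != len(self.query):
            raise ValueError("query_aln does not match query interval length")

    @property
    def n_columns(self) -> int:
        return len(self.ref_aln)

    def match_columns(self) -> np.ndarray:
        """Boolean per-column match vector (gap or N counts as mismatch)."""
        r = np.frombuffer(self.ref_aln.upper().encode(), dtype=np.uint8)
        q = np.frombuffer(self.query_aln.upper().encode(), dtype=np.uint8)
        acgt = np.isin(r, np.frombuffer(b"ACGT", dtype=np.uint8))
        return (r == q) & acgt

    def identity(self) -> float:
        return float(self.match_columns().mean())

    def ref_positions(self) -> np.ndarray:
        """Reference position of each column (-1 for reference-gap columns)."""
        r = np.frombuffer(self.ref_aln.encode(), dtype=np.uint8)
        has_ref = r != ord("-")
        pos = np.full(len(r), -1, dtype=np.int64)
        pos[has_ref] = self.ref.start + np.arange(int(has_ref.sum()))
        return pos

    def sort_key(self):
        return (self.ref.chrom, self.ref.start, self.ref.end, self.query.chrom, self.query.start, self.strand)


def hard_mask(sequences: dict[str, str], repeats) -> dict[str, str]:
    """Replace repeat intervals with N (RepeatMasker-style hard masking)."""
    arrs = {name: bytearray(seq.encode()) for name, seq in sequences.items()}
    for iv in repeats:
        if iv.chrom in arrs:
            arrs[iv.chrom][iv.start : iv.end] = b"N" * (iv.end - iv.start)
    return {name: bytes(a).decode() for name, a in arrs.items()}


def _xdrop_extend(rarr, qarr, r0, r1, q0, match, mismatch, x_drop, chunk=512):
    """Ungapped x-drop extension of an exact seed ``rarr[r0:r1] == qarr[q0:...]``.

    Returns (ref_start, ref_end, score, n_match); the query coordinates
    follow from the seed diagonal.
    """
    seed_len = r1 - r0
    score = seed_len * match
    n_match = seed_len
    # extend right
    re_, qe = r1, q0 + seed_len
    while True:
        n = min(chunk, len(rarr) - re_, len(qarr) - qe)
        if n <= 0:
            break
        rs = rarr[re_ : re_ + n]
        qs = qarr[qe : qe + n]
        m = (rs == qs) & (rs < 4)
        inc = np.where(m, match, mismatch)
        cs = np.cumsum(inc)
        # cut where cs falls x_drop below its running max
        rmax = np.maximum.accumulate(cs)
        fail = np.nonzero(cs < rmax - x_drop)[0]
        if len(fail):
            cut = int(np.argmax(cs[: fail[0] + 1]))
            if cs[cut] > 0:
                score += int(cs[cut])
                n_match += int(m[: cut + 1].sum())
                re_ += cut + 1
                qe += cut + 1
            break
        best = int(np.argmax(cs)) if len(cs) else -1
        if n < chunk:
            if len(cs) and cs[best] > 0:
                score += int(cs[best])
                n_match += int(m[: best + 1].sum())
                re_ += best + 1
                qe += best + 1
            break
        # whole chunk survived: keep it all, continue
        score += int(cs[-1])
        n_match += int(m.sum())
        re_ += n
        qe += n
    # extend left
    rs_, qs_ = r0, q0
    while True:
        n = min(chunk, rs_, qs_)
        if n <= 0:
            break
        rs = rarr[rs_ - n : rs_][::-1]
        qs = qarr[qs_ - n : qs_][::-1]
        m = (rs == qs) & (rs < 4)
        inc = np.where(m, match, mismatch)
        cs = np.cumsum(inc)
        rmax = np.maximum.accumulate(cs)
        fail = np.nonzero(cs < rmax - x_drop)[0]
        if len(fail):
            cut = int(np.argmax(cs[: fail[0] + 1]))
            if cs[cut] > 0:
                score += int(cs[cut])
                n_match += int(m[: cut + 1].sum())
                rs_ -= cut + 1
                qs_ -= cut + 1
            break
        best = int(np.argmax(cs)) if len(cs) else -1
        if n < chunk:
            if len(cs) and cs[best] > 0:
                score += int(cs[best])
                n_match += int(m[: best + 1].sum())
                rs_ -= best + 1
                qs_ -= best + 1
            break
        score += int(cs[-1])
        n_match += int(m.sum())
        rs_ -= n
        qs_ -= n
    return rs_, re_, score, n_match


def _batch_xdrop(rarr, qarr, rp, qp, k, match, mismatch, x_drop, W=64, chunk=120_000):
    """Vectorized ungapped x-drop extension of many seeds at once.

    Extends each seed within a +-W column window; seeds still alive at the
    window edge are finished with the scalar extender. Returns
    (rs, re, score, alive) arrays.
    """
    n = len(rp)
    rs = np.empty(n, dtype=np.int64)
    re_ = np.empty(n, dtype=np.int64)
    score = np.empty(n, dtype=np.int64)
    alive = np.zeros(n, dtype=bool)
    offs = np.arange(W, dtype=np.int64)
    for lo in range(0, n, chunk):
        sl = slice(lo, min(n, lo + chunk))
        rp_c, qp_c = rp[sl], qp[sl]
        m_ = len(rp_c)
        idx = np.arange(m_)
        parts = {}
        for side in ("right", "left"):
            if side == "right":
                ridx = rp_c[:, None] + k + offs[None, :]
                qidx = qp_c[:, None] + k + offs[None, :]
                valid = (ridx < len(rarr)) & (qidx < len(qarr))
            else:
                ridx = rp_c[:, None] - 1 - offs[None, :]
                qidx = qp_c[:, None] - 1 - offs[None, :]
                valid = (ridx >= 0) & (qidx >= 0)
            R = rarr[np.clip(ridx, 0, len(rarr) - 1)]
            Q = qarr[np.clip(qidx, 0, len(qarr) - 1)]
            mm = (R == Q) & (R < 4) & valid
            inc = np.where(mm, match, mismatch).astype(np.int32)
            cs = np.cumsum(inc, axis=1)
            rmax = np.maximum.accumulate(cs, axis=1)
            fail = cs < rmax - x_drop
            has_fail = fail.any(axis=1)
            first_fail = np.where(has_fail, fail.argmax(axis=1), W - 1)
            allowed = offs[None, :] <= first_fail[:, None]
            csm = np.where(allowed, cs, -(10**9))
            best = csm.argmax(axis=1)
            best_score = csm[idx, best]
            ext = np.where(best_score > 0, best + 1, 0)
            gain = np.where(best_score > 0, best_score, 0)
            side_alive = (~has_fail) & valid[:, -1]
            parts[side] = (ext, gain, side_alive)
        ext_r, gain_r, alive_r = parts["right"]
        ext_l, gain_l, alive_l = parts["left"]
        rs[sl] = rp_c - ext_l
        re_[sl] = rp_c + k + ext_r
        score[sl] = k * match + gain_l + gain_r
        alive[sl] = alive_r | alive_l
    return rs, re_, score, alive


def _finish_alive(rarr, qarr, rp, qp, k, match, mismatch, x_drop, rs_a, re_a, sc_a, alive) -> None:
    """Scalar-finish seeds still alive at the batch window edge, in place.

    Alive seeds on one diagonal inside the same homologous run converge to
    the same extent, so only the first uncovered seed per diagonal is
    re-extended; the rest are marked as duplicates (score -1).
    """
    idx = np.nonzero(alive)[0]
    if not len(idx):
        return
    d = rp[idx] - qp[idx]
    order = np.lexsort((rp[idx], d))
    covered: dict[int, int] = {}
    for o in order:
        t = idx[o]
        dd = int(d[o])
        if int(rp[t]) < covered.get(dd, -1):
            sc_a[t] = -1
            continue
        rs_i, re_i, sc_i, _ = _xdrop_extend(rarr, qarr, int(rp[t]), int(rp[t]) + k, int(qp[t]), match, mismatch, x_drop)
        rs_a[t], re_a[t], sc_a[t] = rs_i, re_i, sc_i
        covered[dd] = int(re_i)


def _seed_hits(ref_index: KmerIndex, qarr: np.ndarray, k: int):
    codes, valid = kmer_codes(qarr, k)
    qpos = np.nonzero(valid)[0]
    if len(qpos) == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    qidx, gpos = ref_index.lookup_many(codes[qpos])
    return qpos[qidx], gpos


def seed_extend_align(
    ref_genome: SpeciesGenome | dict[str, str],
    query_genome: SpeciesGenome | dict[str, str],
    params: AlignerParams | None = None,
) -> list[AlignmentBlock]:
    """All-vs-all ungapped local alignment blocks between two genomes.

    Both strands are searched; N runs (hard-masked repeats) are never seeded
    and score as mismatches during extension. Blocks scoring below
    ``params.min_block_score`` are dropped.
    """
    params = params or AlignerParams()
    ref_seqs = ref_genome.sequences if isinstance(ref_genome, SpeciesGenome) else ref_genome
    query_seqs = query_genome.sequences if isinstance(query_genome, SpeciesGenome) else query_genome
    k = params.seed_length
    blocks: list[AlignmentBlock] = []
    ref_arrs = {name: encode(seq) for name, seq in ref_seqs.items()}
    for rname, rarr in ref_arrs.items():
        if len(rarr) < k:
            continue
        index = KmerIndex(rarr, k)
        for qname, qseq in query_seqs.items():
            qfwd = encode(qseq)
            if len(qfwd) < k:
                continue
            for strand in "+-":
                qarr = qfwd if strand == "+" else revcomp_arr(qfwd)
                qp, rp = _seed_hits(index, qarr, k)
                if len(qp) == 0:
                    continue
                rs_a, re_a, sc_a, alive = _batch_xdrop(
                    rarr, qarr, rp, qp, k, params.match, params.mismatch, params.x_drop
                )
                _finish_alive(
                    rarr, qarr, rp, qp, k, params.match, params.mismatch, params.x_drop, rs_a, re_a, sc_a, alive
                )
                keep = sc_a >= params.min_block_score
                if not keep.any():
                    continue
                diag = rp[keep] - qp[keep]
                cand = np.unique(np.stack([diag, rs_a[keep], re_a[keep], sc_a[keep]], axis=1), axis=0)
                # per-diagonal non-overlap sweep: keep the best extent
                order = np.lexsort((-cand[:, 3], cand[:, 1], cand[:, 0]))
                cand = cand[order]
                cur_diag, covered_end = None, -1
                for d, rs, re_, score in cand:
                    if d != cur_diag:
                        cur_diag, covered_end = d, -1
                    if rs < covered_end:
                        continue
                    covered_end = re_
                    qs, qe = rs - d, re_ - d
                    if strand == "+":
                        q_iv = Interval(qname, int(qs), int(qe), "+")
                    else:
                        L = len(qarr)
                        q_iv = Interval(qname, int(L - qe), int(L - qs), "-")
                    blocks.append(
                        AlignmentBlock(
                            ref=Interval(rname, int(rs), int(re_)),
                            query=q_iv,
                            strand=strand,
                            ref_aln=decode(rarr[rs:re_]),
                            query_aln=decode(qarr[qs:qe]),
                            score=float(score),
                        )
                    )
    blocks.sort(key=AlignmentBlock.sort_key)
    return blocks


def two_round_align(
    ref_genome: SpeciesGenome | dict[str, str],
    query_genome: SpeciesGenome | dict[str, str],
    params: AlignerParams | None = None,
) -> list[AlignmentBlock]:
    """Two-round alignment: align, mask aligned regions, align the rest.

    Round-2 blocks can only come from reference and query positions not
    already covered in round 1 (both sides are hard-masked with N), so the
    two rounds never overlap on the reference.
    """
    params = params or AlignerParams()
    ref_seqs = dict(ref_genome.sequences if isinstance(ref_genome, SpeciesGenome) else ref_genome)
    query_seqs = dict(query_genome.sequences if isinstance(query_genome, SpeciesGenome) else query_genome)
    round1 = seed_extend_align(ref_seqs, query_seqs, params)
    ref_cover = [b.ref for b in round1]
    query_cover = [b.query for b in round1]
    masked_ref = hard_mask(ref_seqs, ref_cover)
    masked_query = hard_mask(query_seqs, query_cover)
    round2 = seed_extend_align(masked_ref, masked_query, params)
    for b in round2:
        b.round = 2
    out = round1 + round2
    out.sort(key=AlignmentBlock.sort_key)
    return out


def slice_block(block: AlignmentBlock, ref_start: int, ref_end: int, params: AlignerParams | None = None) -> AlignmentBlock | None:
    """Trim a block to reference window [ref_start, ref_end); None if empty.

    Columns outside the window are removed; leading/trailing reference-gap
    columns are stripped; the score is recomputed column-wise with the
    (default) aligner scores.
    """
    params = params or AlignerParams()
    a, b = max(ref_start, block.ref.start), min(ref_end, block.ref.end)
    if a >= b:
        return None
    if a == block.ref.start and b == block.ref.end:
        return block
    pos = block.ref_positions()
    keep = (pos >= a) & (pos < b)
    idx = np.nonzero(keep)[0]
    lo, hi = int(idx[0]), int(idx[-1]) + 1
    ref_aln = block.ref_aln[lo:hi]
    query_aln = block.query_aln[lo:hi]
    # query bases consumed before lo / after hi (in oriented coordinates)
    q_before = len(block.query_aln[:lo].replace("-", ""))
    q_len = len(query_aln.replace("-", ""))
    if q_len == 0:
        return None
    if block.strand == "+":
        q_iv = Interval(block.query.chrom, block.query.start + q_before, block.query.start + q_before + q_len, "+")
    else:
        q_end = block.query.end - q_before
        q_iv = Interval(block.query.chrom, q_end - q_len, q_end, "-")
    r = np.frombuffer(ref_aln.upper().encode(), dtype=np.uint8)
    q = np.frombuffer(query_aln.upper().encode(), dtype=np.uint8)
    acgt = np.isin(r, np.frombuffer(b"ACGT", dtype=np.uint8))
    m = (r == q) & acgt
    gap = (r == ord("-")) | (q == ord("-"))
    score = float(np.where(m, params.match, np.where(gap, params.gap_extend, params.mismatch)).sum())
    return AlignmentBlock(
        ref=Interval(block.ref.chrom, a, b),
        query=q_iv,
        strand=block.strand,
        ref_aln=ref_aln,
        query_aln=query_aln,
        score=score,
        round=block.round,
    )
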
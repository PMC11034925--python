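"""Collinear chaining of alignment blocks and reference-side netting.

Chaining joins blocks that are collinear on both genomes (per reference
chromosome / query chromosome / strand group) by maximum-score dynamic
programming with an affine-ish gap cost
``gap_open + per_bp_gap_cost * (ref_gap + query_gap)``.  Netting greedily
keeps chains by descending score, trimming lower-scoring chains to reference
space not already covered, so the net tiles the reference without overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .align import AlignerParams, AlignmentBlock, slice_block
from .model import Interval

log = logging.getLogger(__name__)

DEFAULT_GAP_OPEN = 50.0
DEFAULT_PER_BP_GAP_COST = 0.5
DEFAULT_MAX_GAP = 10_000


@dataclass
class Chain:
    """An ordered run of collinear alignment blocks on one strand."""

    blocks: list[AlignmentBlock]
    total_score: float = 0.0

    def __post_init__(self):
        if not self.blocks:
            raise ValueError("empty chain")
        if self.total_score == 0.0:
            self.total_score = sum(b.score for b in self.blocks)
        strands = {b.strand for b in self.blocks}
        if len(strands) != 1:
            raise ValueError("chain mixes strands")

    @property
    def strand(self) -> str:
        return self.blocks[0].strand

    @property
    def ref_span(self) -> Interval:
        return Interval(
            self.blocks[0].ref.chrom,
            min(b.ref.start for b in self.blocks),
            max(b.ref.end for b in self.blocks),
        )

    @property
    def query_span(self) -> Interval:
        return Interval(
            self.blocks[0].query.chrom,
            min(b.query.start for b in self.blocks),
            max(b.query.end for b in self.blocks),
            self.strand,
        )


def _oriented_q(block: AlignmentBlock) -> tuple[int, int]:
    """Query coordinates increasing along the reference direction."""
    if block.strand == "+":
        return block.query.start, block.query.end
    return -block.query.end, -block.query.start


def _resolve_ref_overlaps(blocks: list[AlignmentBlock]) -> list[AlignmentBlock]:
    """Trim reference-overlapping input blocks at the overlap midpoint."""
    out: list[AlignmentBlock] = []
    for b in sorted(blocks, key=AlignmentBlock.sort_key):
        if out and out[-1].ref.chrom == b.ref.chrom and b.ref.start < out[-1].ref.end:
            prev = out[-1]
            mid = (b.ref.start + prev.ref.end) // 2
            log.warning("overlapping blocks on %s trimmed at %d", b.ref.chrom, mid)
            trimmed_prev = slice_block(prev, prev.ref.start, mid)
            trimmed_b = slice_block(b, mid, b.ref.end)
            out.pop()
            if trimmed_prev:
                out.append(trimmed_prev)
            if trimmed_b:
                out.append(trimmed_b)
            continue
        out.append(b)
    return out


def chain_blocks(
    blocks: list[AlignmentBlock],
    gap_open: float = DEFAULT_GAP_OPEN,
    per_bp_gap_cost: float = DEFAULT_PER_BP_GAP_COST,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[Chain]:
    """Partition blocks into maximum-score collinear chains.

    Blocks are grouped by (ref chrom, query chrom, strand); within a group a
    link is allowed only when both-side gaps are in [0, max_gap]. Every block
    ends up in exactly one chain. Chains are returned sorted by descending
    total score (ties: ref start, then query start).
    """
    groups: dict[tuple, list[AlignmentBlock]] = {}
    for b in blocks:
        groups.setdefault((b.ref.chrom, b.query.chrom, b.strand), []).append(b)
    chains: list[Chain] = []
    for key in sorted(groups):
        # overlap resolution happens per group: blocks overlapping on the
        # reference across different query chromosomes/strands are competing
        # homologies that netting arbitrates by score, not chaining
        grp = sorted(_resolve_ref_overlaps(groups[key]), key=lambda b: (b.ref.start, _oriented_q(b)[0]))
        n = len(grp)
        dp = [b.score for b in grp]
        parent = [-1] * n
        for i in range(n):
            bi = grp[i]
            qi0, _ = _oriented_q(bi)
            for j in range(i):
                bj = grp[j]
                rgap = bi.ref.start - bj.ref.end
                qgap = qi0 - _oriented_q(bj)[1]
                if rgap < 0 or qgap < 0 or rgap > max_gap or qgap > max_gap:
                    continue
                cand = dp[j] - gap_open - per_bp_gap_cost * (rgap + qgap) + bi.score
                if cand > dp[i] + 1e-9:
                    dp[i] = cand
                    parent[i] = j
        used = [False] * n
        order = sorted(range(n), key=lambda i: (-dp[i], grp[i].ref.start, _oriented_q(grp[i])[0]))
        for i in order:
            if used[i]:
                continue
            members = []
            k = i
            while k != -1 and not used[k]:
                members.append(k)
                used[k] = True
                k = parent[k]
            members.reverse()
            picked = [grp[k] for k in members]
            score = sum(b.score for b in picked)
            for prev, nxt in zip(picked, picked[1:]):
                rgap = nxt.ref.start - prev.ref.end
                qgap = _oriented_q(nxt)[0] - _oriented_q(prev)[1]
                score -= gap_open + per_bp_gap_cost * (rgap + qgap)
            chains.append(Chain(picked, total_score=score))
    chains.sort(key=lambda c: (-c.total_score, c.ref_span.chrom, c.ref_span.start, c.query_span.start))
    return chains


def net_chains(chains: list[Chain], params: AlignerParams | None = None, min_fragment: int = 20) -> list[Chain]:
    """Greedy reference-side net: keep chains by descending score on
    reference space not already covered; trimmed chains keep their surviving
    (possibly sliced) blocks. Slivers shorter than ``min_fragment`` bp are
    discarded rather than kept as uninformative shards. The output has zero
    reference overlap."""
    covered: dict[str, list[tuple[int, int]]] = {}
    out: list[Chain] = []
    ordered = sorted(chains, key=lambda c: (-c.total_score, c.ref_span.chrom, c.ref_span.start, c.query_span.start))
    for chain in ordered:
        kept_blocks: list[AlignmentBlock] = []
        for b in chain.blocks:
            for lo, hi in _uncovered(covered.get(b.ref.chrom, []), b.ref.start, b.ref.end):
                if hi - lo < min_fragment and (hi - lo) < len(b.ref):
                    continue
                piece = slice_block(b, lo, hi, params)
                if piece is not None:
                    kept_blocks.append(piece)
        if not kept_blocks:
            continue
        for b in kept_blocks:
            _add_cover(covered.setdefault(b.ref.chrom, []), b.ref.start, b.ref.end)
        out.append(Chain(kept_blocks))
    # sanity: overlap-free reference coverage
    for chrom, ivs in covered.items():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2, f"net overlap on {chrom}"
    out.sort(key=lambda c: (c.ref_span.chrom, c.ref_span.start, c.query_span.start))
    return out


def _uncovered(cover: list[tuple[int, int]], start: int, end: int):
    """Sub-intervals of [start, end) not covered by the sorted interval list."""
    pos = start
    for s, e in sorted(cover):
        if e <= pos:
            continue
        if s >= end:
            break
        if s > pos:
            yield pos, min(s, end)
        pos = max(pos, e)
        if pos >= end:
            return
    if pos < end:
        yield pos, end


def _add_cover(cover: list[tuple[int, int]], start: int, end: int) -> None:
    cover.append((start, end))
    cover.sort()
    merged = [cover[0]]
    for s, e in cover[1:]:
        ls, le = merged[-1]
        if s <= le:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    cover[:] = merged


def net_blocks(net: list[Chain]) -> list[AlignmentBlock]:
    """Flat list of all blocks in a net, sorted by reference position."""
    out = [b for c in net for b in c.blocks]
    out.sort(key=AlignmentBlock.sort_key)
    return out
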
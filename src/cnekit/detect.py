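"""De novo CNE detection from netted pairwise alignments.

The scan follows the classic conserved-element recipe: filter exonic and
repetitive reference positions out of the alignment, slide a 100-bp window
one alignment column at a time, mark windows with >= 70% identity, merge
marked columns into elements of >= 100 bp, and drop elements that look
repetitive (more than four hits in either genome of the pair).

Window identity counts gap columns as mismatches, and windows never span an
excluded (exon/repeat) column - the stricter, simpler choice, switchable via
``DetectParams``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .align import AlignmentBlock
from .model import Interval, SpeciesGenome

log = logging.getLogger(__name__)


@dataclass
class DetectParams:
    window: int = 100
    min_identity: float = 0.70
    max_hits: int = 4
    min_length: int = 100
    #: trim element edges whose local identity (over ``edge_window`` columns)
    #: falls below min_identity; qualifying windows straddling an element
    #: boundary otherwise drag a few tens of bp of diverged flank into the
    #: element. Disable to get the plain marked-run merge.
    edge_trim: bool = True
    edge_window: int = 20

    def __post_init__(self):
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.min_length < self.window:
            raise ValueError("min_length must be >= window")


@dataclass
class CNERecord:
    id: str
    ref_species: str
    location: Interval
    source_pair: tuple[str, str]
    mean_identity: float
    length: int

    def __post_init__(self):
        if self.length != len(self.location):
            raise ValueError("length field disagrees with location")
        if not (0 <= self.mean_identity <= 1):
            raise ValueError("mean_identity out of range")


class CNESet:
    """An ordered set of CNE records anchored on one reference species."""

    def __init__(self, ref_species: str, records: list[CNERecord] | None = None):
        self.ref_species = ref_species
        self.records: list[CNERecord] = list(records or [])
        self._by_id = {r.id: r for r in self.records}

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, cne_id: str) -> CNERecord:
        return self._by_id[cne_id]

    def __contains__(self, cne_id: str) -> bool:
        return cne_id in self._by_id

    def add(self, rec: CNERecord) -> None:
        self.records.append(rec)
        self._by_id[rec.id] = rec

    def sequences(self, genomes) -> dict[str, str]:
        """Extract element sequences from the reference genome."""
        g = genomes[self.ref_species] if not isinstance(genomes, SpeciesGenome) else genomes
        out = {}
        for r in self.records:
            out[r.id] = g.sequences[r.location.chrom][r.location.start : r.location.end]
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "cne_id": r.id,
                    "ref_species": r.ref_species,
                    "chrom": r.location.chrom,
                    "start": r.location.start,
                    "end": r.location.end,
                    "strand": r.location.strand,
                    "mean_identity": round(r.mean_identity, 4),
                    "length": r.length,
                    "source_pair": f"{r.source_pair[0]}|{r.source_pair[1]}",
                }
                for r in self.records
            ]
        )

    @classmethod
    def from_frame(cls, df) -> "CNESet":
        ref = df["ref_species"].iloc[0] if len(df) else ""
        out = cls(ref)
        for _, row in df.iterrows():
            pair = tuple(row["source_pair"].split("|"))
            out.add(
                CNERecord(
                    id=row["cne_id"],
                    ref_species=row["ref_species"],
                    location=Interval(str(row["chrom"]), int(row["start"]), int(row["end"])),
                    source_pair=pair,
                    mean_identity=float(row["mean_identity"]),
                    length=int(row["length"]),
                )
            )
        return out


# ------------------------------------------------------------ operations ---

def mask_annotations(
    blocks: list[AlignmentBlock], exons: list[Interval], repeats: list[Interval]
) -> list[tuple[AlignmentBlock, np.ndarray]]:
    """Flag alignment columns whose reference base overlaps an exon/repeat.

    Returns (block, excluded) pairs; fully excluded blocks are dropped.
    Columns without a reference base (reference-gap columns) are never
    flagged by annotations.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in list(exons) + list(repeats):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts, ends = [], []
        for s, e in ivs:
            if starts and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (np.asarray(starts), np.asarray(ends))
    out = []
    for b in blocks:
        excluded = np.zeros(b.n_columns, dtype=bool)
        if b.ref.chrom in merged:
            starts, ends = merged[b.ref.chrom]
            pos = b.ref_positions()
            has_ref = pos >= 0
            idx = np.searchsorted(starts, pos[has_ref], side="right") - 1
            inside = (idx >= 0) & (pos[has_ref] < ends[np.clip(idx, 0, None)])
            excluded[has_ref] = inside
        if excluded.all():
            continue
        out.append((b, excluded))
    return out


def scan_conserved(
    block: AlignmentBlock, params: DetectParams, excluded: np.ndarray | None = None
) -> np.ndarray:
    """Reference positions covered by any qualifying sliding window.

    Windows of ``params.window`` alignment columns slide one column at a
    time over maximal excluded-free stretches; window identity is
    matches / window (gaps and N count as mismatches). Returns the sorted
    array of reference positions of marked columns.
    """
    W = params.window
    if block.n_columns < W:
        return np.empty(0, dtype=np.int64)
    m = block.match_columns().astype(np.int64)
    if excluded is None:
        excluded = np.zeros(block.n_columns, dtype=bool)
    pos = block.ref_positions()
    marked = np.zeros(block.n_columns, dtype=bool)
    # maximal stretches without excluded columns
    if excluded.any():
        edges = np.flatnonzero(np.diff(np.concatenate(([1], excluded.astype(np.int8), [1]))))
        free = list(zip(edges[::2], edges[1::2]))
    else:
        free = [(0, block.n_columns)]
    need = int(np.ceil(params.min_identity * W - 1e-9))
    for lo, hi in free:
        L = hi - lo
        if L < W:
            continue
        cs = np.concatenate(([0], np.cumsum(m[lo:hi])))
        wsum = cs[W:] - cs[:-W]
        good = np.flatnonzero(wsum >= need)
        if not len(good):
            continue
        cover = np.zeros(L + 1, dtype=np.int64)
        cover[good] += 1
        cover[good + W] -= 1
        marked[lo:hi] |= np.cumsum(cover[:-1]) > 0
    sel = marked & (pos >= 0)
    return pos[sel]


def merge_candidates(
    marked_positions: np.ndarray,
    params: DetectParams,
    identity_by_pos: dict[int, bool] | None = None,
) -> list[tuple[int, int, float]]:
    """Merge marked reference positions into elements.

    Maximal runs of consecutive positions become elements; runs shorter than
    ``min_length`` are discarded. ``identity_by_pos`` (position -> column is
    a match) lets per-element mean identity be recomputed; with
    ``params.edge_trim`` the element is first trimmed inward until both
    terminal ``edge_window``-column stretches reach ``min_identity`` and the
    element starts/ends on a match column.

    Returns (start, end, mean_identity) tuples in reference coordinates.
    """
    if len(marked_positions) == 0:
        return []
    pos = np.unique(np.asarray(marked_positions, dtype=np.int64))
    breaks = np.flatnonzero(np.diff(pos) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks + 1, [len(pos)]))
    out = []
    for s_i, e_i in zip(starts, ends):
        start, end = int(pos[s_i]), int(pos[e_i - 1]) + 1
        if identity_by_pos is not None:
            match_vec = np.array([identity_by_pos.get(p, False) for p in range(start, end)], dtype=bool)
            if params.edge_trim:
                start_off, end_off = _trim_edges(match_vec, params)
                if start_off is None:
                    continue
                start, end = start + start_off, start + end_off
                match_vec = match_vec[start_off:end_off]
            ident = float(match_vec.mean()) if len(match_vec) else 0.0
        else:
            ident = 1.0
        if end - start < params.min_length:
            continue
        out.append((start, end, ident))
    return out


def _trim_edges(match_vec: np.ndarray, params: DetectParams):
    """Offsets (lo, hi) after trimming low-identity edges; (None, None) if gone."""
    W = min(params.edge_window, len(match_vec))
    if W == 0:
        return None, None
    cs = np.concatenate(([0], np.cumsum(match_vec.astype(np.int64))))
    wsum = (cs[W:] - cs[:-W]) / W
    ok = np.flatnonzero(wsum >= params.min_identity)
    if not len(ok):
        return None, None
    lo = int(ok[0])
    hi = int(ok[-1]) + W
    # snap to match columns
    matches = np.flatnonzero(match_vec[lo:hi])
    if not len(matches):
        return None, None
    return lo + int(matches[0]), lo + int(matches[-1]) + 1


def filter_repetitive(
    elements: CNESet,
    ref_genome: SpeciesGenome,
    query_genome: SpeciesGenome,
    search_params=None,
    max_hits: int = 4,
) -> CNESet:
    """Drop elements with more than ``max_hits`` hits in either genome of
    the pair (exactly ``max_hits`` survives). Genomes are searched with
    repeats hard-masked, mirroring the premasked search protocol."""
    from .search import GenomeIndex, SearchParams, search_all

    params = search_params or SearchParams()
    seqs = elements.sequences(ref_genome)
    kept = CNESet(elements.ref_species)
    ref_idx = GenomeIndex(ref_genome.sequences, params, repeats=ref_genome.repeats, species_id="ref")
    q_idx = GenomeIndex(query_genome.sequences, params, repeats=query_genome.repeats, species_id="query")
    ref_hits = search_all(seqs, ref_idx, params)
    q_hits = search_all(seqs, q_idx, params)
    for rec in elements:
        n_ref = len(ref_hits.get(rec.id, []))
        n_q = len(q_hits.get(rec.id, []))
        if n_ref > max_hits or n_q > max_hits:
            log.debug("element %s dropped as repetitive (%d/%d hits)", rec.id, n_ref, n_q)
            continue
        kept.add(rec)
    return kept


# ----------------------------------------------------------- orchestrator --

def detect_cnes(
    net_blocks: list[AlignmentBlock],
    ref_genome: SpeciesGenome,
    query_genome: SpeciesGenome,
    ref_species: str,
    query_species: str,
    params: DetectParams | None = None,
    search_params=None,
    id_prefix: str = "cne",
    apply_repeat_filter: bool = True,
) -> CNESet:
    """Full detection pass: mask -> scan -> merge -> repeat-copy filter."""
    params = params or DetectParams()
    masked = mask_annotations(net_blocks, ref_genome.exons, ref_genome.repeats)
    marked_by_chrom: dict[str, list[np.ndarray]] = {}
    match_by_chrom: dict[str, dict[int, bool]] = {}
    for block, excluded in masked:
        marked = scan_conserved(block, params, excluded)
        if not len(marked):
            continue
        marked_by_chrom.setdefault(block.ref.chrom, []).append(marked)
        mvec = block.match_columns()
        pos = block.ref_positions()
        d = match_by_chrom.setdefault(block.ref.chrom, {})
        has_ref = pos >= 0
        for p_, m_ in zip(pos[has_ref], mvec[has_ref]):
            d[int(p_)] = bool(m_)
    out = CNESet(ref_species)
    n = 0
    for chrom in sorted(marked_by_chrom):
        allpos = np.concatenate(marked_by_chrom[chrom])
        for start, end, ident in merge_candidates(allpos, params, match_by_chrom[chrom]):
            n += 1
            out.add(
                CNERecord(
                    id=f"{id_prefix}{n:05d}",
                    ref_species=ref_species,
                    location=Interval(chrom, start, end),
                    source_pair=(ref_species, query_species),
                    mean_identity=ident,
                    length=end - start,
                )
            )
    if apply_repeat_filter:
        out = filter_repetitive(out, ref_genome, query_genome, search_params, params.max_hits)
    return out
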
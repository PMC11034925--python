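"""Consensus-motif scanning and positional-centrality summary.

A fixed IUPAC consensus (default TAATTA, the homeodomain-binding core
typical of developmental enhancers) is scanned exactly on both strands of
each element; palindromic matches are counted once. The positional summary
reports a normalized histogram of relative occurrence positions and the
fraction falling in the central third of the element.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seqtools import revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class MotifOccurrence:
    cne_id: str
    motif: str
    offset: int  # bp from element start (forward strand of the element)
    strand: str
    relative_position: float  # occurrence midpoint / element length, in [0, 1]


def _matches_at(seq: str, motif: str, i: int) -> bool:
    for j, c in enumerate(motif):
        if seq[i + j] not in IUPAC[c]:
            return False
    return True


def scan_sequence(cne_id: str, seq: str, motif: str = "TAATTA") -> list[MotifOccurrence]:
    """Exact IUPAC-expanded occurrences on both strands; positions where the
    forward and reverse-complement patterns coincide (palindromes) count once."""
    motif = motif.upper()
    for c in motif:
        if c not in IUPAC:
            raise ValueError(f"invalid IUPAC code {c!r} in motif")
    seq = seq.upper()
    L, M = len(seq), len(motif)
    rc = revcomp(motif)
    out = []
    for i in range(L - M + 1):
        fwd = _matches_at(seq, motif, i)
        rev = _matches_at(seq, rc, i)
        if fwd or rev:
            rel = (i + M / 2.0) / L
            out.append(MotifOccurrence(cne_id, motif, i, "+" if fwd else "-", rel))
    return out


def scan_consensus(cnes, genomes, motif: str = "TAATTA") -> tuple[list[MotifOccurrence], float]:
    """Scan a CNE collection; returns (occurrences, fraction of elements
    with >= 1 occurrence). ``cnes`` is any iterable of objects with
    id/ref_species/location; sequences come from the reference genomes."""
    occs: list[MotifOccurrence] = []
    n_total = 0
    n_with = 0
    for rec in cnes:
        n_total += 1
        loc = rec.location
        seq = genomes[rec.ref_species].sequences[loc.chrom][loc.start : loc.end]
        found = scan_sequence(rec.id, seq, motif)
        occs.extend(found)
        if found:
            n_with += 1
    frac = n_with / n_total if n_total else float("nan")
    return occs, frac


@dataclass
class PositionalSummary:
    histogram: np.ndarray  # normalized over n_bins
    bin_edges: np.ndarray
    central_fraction: float  # occurrences with relative position in [1/3, 2/3)


def positional_distribution(occurrences: list[MotifOccurrence], n_bins: int = 20) -> PositionalSummary:
    """Histogram of relative positions plus the middle-tercile fraction."""
    if not occurrences:
        return PositionalSummary(np.zeros(n_bins), np.linspace(0, 1, n_bins + 1), float("nan"))
    rel = np.array([o.relative_position for o in occurrences])
    hist, edges = np.histogram(rel, bins=n_bins, range=(0.0, 1.0))
    hist = hist / hist.sum()
    central = float(((rel >= 1.0 / 3.0) & (rel < 2.0 / 3.0)).mean())
    return PositionalSummary(hist, edges, central)


def central_element_fraction(cnes, genomes, motif: str = "TAATTA") -> float:
    """Fraction of all elements carrying a centrally positioned occurrence
    (relative position in the middle tercile)."""
    n_total = 0
    n_central = 0
    for rec in cnes:
        n_total += 1
        loc = rec.location
        seq = genomes[rec.ref_species].sequences[loc.chrom][loc.start : loc.end]
        for occ in scan_sequence(rec.id, seq, motif):
            if 1.0 / 3.0 <= occ.relative_position < 2.0 / 3.0:
                n_central += 1
                break
    return n_central / n_total if n_total else float("nan")
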
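"""CNE-based phylogenomics at desk scale.

Universal single-copy elements (exactly one hit locus in every species of a
chosen subset) become markers; their hit sequences, extended by a flank and
anchored on the full query span, are concatenated into a supermatrix,
gap-heavy columns are trimmed, and a neighbor-joining tree on p-distances
serves as the built-in tree estimate (ML inference is deliberately left to
external tools).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
from dendropy.calculate import treecompare

from ._seqtools import revcomp
from .search import PresenceMatrix

log = logging.getLogger(__name__)


def universal_single_copy(presence: PresenceMatrix, species_subset: list[str]) -> list[str]:
    """Elements with exactly one hit locus in every species of the subset."""
    out = []
    for cid in presence.cne_ids:
        if all(presence.present(cid, sp) and presence.count(cid, sp) == 1 for sp in species_subset):
            out.append(cid)
    return out


def extract_marker_seqs(
    cne_ids: list[str], presence: PresenceMatrix, genomes, flank: int = 50
) -> dict[str, dict[str, str]]:
    """Per-marker, per-species sequences extended by ``flank`` bp.

    Hit coordinates are first extended to the full query span (using the
    hit's query footprint), then by the flank, clipped at chromosome ends
    (clipped bases padded with gaps so homologous columns stay aligned);
    minus-strand hits are reverse-complemented into marker orientation.
    """
    out: dict[str, dict[str, str]] = {}
    for cid in cne_ids:
        ref_sp = presence.ref_species[cid]
        qlen = len(presence.hit(cid, ref_sp).location)
        per_species: dict[str, str] = {}
        for sp in presence.species:
            hit = presence.hit(cid, sp)
            if hit is None:
                continue
            g = genomes[sp]
            chrom_seq = g.sequences[hit.location.chrom]
            qs, qe = hit.qstart, hit.qend
            if sp == ref_sp:
                qs, qe = 0, qlen
            if hit.strand == "+":
                gs = hit.location.start - qs - flank
                ge = hit.location.end + (qlen - qe) + flank
            else:
                gs = hit.location.start - (qlen - qe) - flank
                ge = hit.location.end + qs + flank
            lo, hi = max(0, gs), min(len(chrom_seq), ge)
            seq = chrom_seq[lo:hi]
            left_pad, right_pad = lo - gs, ge - hi
            seq = "-" * left_pad + seq + "-" * right_pad
            if hit.strand == "-":
                seq = revcomp(seq)  # '-' pads are strand-neutral and map to themselves
            per_species[sp] = seq
        out[cid] = per_species
    return out


@dataclass
class Supermatrix:
    species: list[str]
    rows: dict[str, str]
    partitions: dict[str, tuple[int, int]]  # marker -> [start, end) columns

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def __post_init__(self):
        widths = {len(s) for s in self.rows.values()}
        if len(widths) > 1:
            raise ValueError("unequal supermatrix row lengths")

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.species)} {self.width}\n")
            for sp in self.species:
                fh.write(f"{sp}  {self.rows[sp]}\n")


def build_supermatrix(
    marker_seq_sets: dict[str, dict[str, str]], gap_threshold: float = 0.5, msa_hook=None
) -> Supermatrix:
    """Concatenate per-marker alignments and trim gap-heavy columns.

    Markers whose sequences have unequal lengths need ``msa_hook`` (a
    callable mapping {species: seq} to an aligned {species: seq}); on
    substitution-only cohorts sequences are already positionally homologous
    and are concatenated directly. Species absent from a marker are padded
    with gaps before trimming. Columns with gap fraction > ``gap_threshold``
    are removed.
    """
    species = sorted({sp for seqs in marker_seq_sets.values() for sp in seqs})
    parts: dict[str, list[str]] = {sp: [] for sp in species}
    partitions: dict[str, tuple[int, int]] = {}
    col = 0
    for marker in sorted(marker_seq_sets):
        seqs = marker_seq_sets[marker]
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) > 1:
            if msa_hook is None:
                raise ValueError(f"marker {marker}: unequal sequence lengths and no MSA hook")
            seqs = msa_hook(seqs)
            lengths = {len(s) for s in seqs.values()}
            if len(lengths) > 1:
                raise ValueError(f"marker {marker}: MSA hook returned unequal lengths")
        L = lengths.pop() if lengths else 0
        mat = np.array([list(seqs.get(sp, "-" * L).upper()) for sp in species])
        gap_frac = (mat == "-").mean(axis=0)
        keep = gap_frac <= gap_threshold
        mat = mat[:, keep]
        for i, sp in enumerate(species):
            parts[sp].append("".join(mat[i]))
        partitions[marker] = (col, col + int(keep.sum()))
        col += int(keep.sum())
    rows = {sp: "".join(parts[sp]) for sp in species}
    return Supermatrix(species, rows, partitions)


def _p_distance_matrix(sm: Supermatrix, jc_correction: bool = False):
    arrs = {}
    valid_chars = np.frombuffer(b"ACGT", dtype=np.uint8)
    drop = []
    for sp in sm.species:
        a = np.frombuffer(sm.rows[sp].upper().encode(), dtype=np.uint8)
        ok = np.isin(a, valid_chars)
        if not ok.any():
            log.warning("species %s has an all-gap row; excluded from the tree", sp)
            drop.append(sp)
            continue
        arrs[sp] = (a, ok)
    species = [sp for sp in sm.species if sp not in drop]
    n = len(species)
    D = np.zeros((n, n))
    for i in range(n):
        ai, oki = arrs[species[i]]
        for j in range(i + 1, n):
            aj, okj = arrs[species[j]]
            both = oki & okj
            m = int(both.sum())
            p = float((ai[both] != aj[both]).mean()) if m else 0.0
            if jc_correction and p < 0.749:
                p = -0.75 * np.log(1.0 - (4.0 / 3.0) * p)
            D[i, j] = D[j, i] = p
    return species, D


def nj_tree(sm: Supermatrix, jc_correction: bool = False) -> str:
    """Neighbor-joining newick tree from supermatrix p-distances
    (pairwise deletion of gap/N sites)."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    species, D = _p_distance_matrix(sm, jc_correction)
    if len(species) < 4:
        raise ValueError("need >= 4 species for an unrooted tree")
    tree = nj(DistanceMatrix(D, ids=species))
    return str(tree).strip()


def rf_distance(newick_a: str, newick_b: str) -> int:
    """Unrooted Robinson-Foulds (symmetric difference) distance between two
    trees given as newick strings; both trees are first pruned to their
    common leaf set."""
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    la = {leaf.taxon.label for leaf in ta.leaf_node_iter()}
    lb = {leaf.taxon.label for leaf in tb.leaf_node_iter()}
    common = sorted(la & lb)
    if len(common) < 4:
        raise ValueError("need >= 4 shared leaves for an unrooted comparison")
    if common != sorted(la):
        ta.retain_taxa_with_labels(common)
    if common != sorted(lb):
        tb.retain_taxa_with_labels(common)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return int(treecompare.symmetric_difference(ta, tb))
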
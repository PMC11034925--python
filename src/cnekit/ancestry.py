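"""Ancestral teleost CNE inference, origin dating, loss rates and zones.

An element detected in one basal teleost clade that is also found in the
other basal clade must have been inherited from the teleost common ancestor
(an "atCNE"). Origin categories follow outgroup presence with vertebrate
precedence: a hit in any non-gar vertebrate outgroup makes an element
"vertebrate"-age, otherwise a gar hit makes it "neopterygian", otherwise it
is a teleost-specific "3R" gain.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seqtools import revcomp
from .detect import CNERecord, CNESet
from .model import Interval, SpeciesGenome
from .search import PresenceMatrix

log = logging.getLogger(__name__)

CATEGORIES = ("vertebrate", "neopterygian", "3R")


@dataclass
class AncestryParams:
    clade1: frozenset[str]
    clade2: frozenset[str]
    neopterygian_outgroup: frozenset[str]
    vertebrate_outgroup: frozenset[str]
    zone_size: int = 500_000
    #: zone assignment anchor: "start" or "midpoint"
    zone_anchor: str = "start"

    def __post_init__(self):
        self.clade1 = frozenset(self.clade1)
        self.clade2 = frozenset(self.clade2)
        self.neopterygian_outgroup = frozenset(self.neopterygian_outgroup)
        self.vertebrate_outgroup = frozenset(self.vertebrate_outgroup)
        if not self.clade1 or not self.clade2:
            raise ValueError("both clades must be non-empty")
        if self.zone_size <= 0:
            raise ValueError("zone_size must be positive")
        outgroups = self.neopterygian_outgroup | self.vertebrate_outgroup
        if outgroups & (self.clade1 | self.clade2):
            raise ValueError("outgroups must be disjoint from the basal clades")


@dataclass
class AtCNE:
    record: CNERecord
    origin_category: str | None = None
    clade_support: tuple[int, int] = (0, 0)

    @property
    def id(self) -> str:
        return self.record.id

    @property
    def ref_species(self) -> str:
        return self.record.ref_species

    @property
    def location(self) -> Interval:
        return self.record.location


class AtCNESet:
    """Ancestral element set with provenance helpers."""

    def __init__(self, members: list[AtCNE]):
        self.members = list(members)
        self._by_id = {m.id: m for m in self.members}

    def __len__(self):
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, cne_id):
        return self._by_id[cne_id]

    def __contains__(self, cne_id):
        return cne_id in self._by_id

    def of_category(self, category: str) -> list[AtCNE]:
        return [m for m in self.members if m.origin_category == category]

    def category_counts(self) -> dict[str, int]:
        return category_counts(self.members)

    def by_ref_species(self, species: str) -> list[AtCNE]:
        return [m for m in self.members if m.ref_species == species]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cne_id": m.id,
                    "ref_species": m.ref_species,
                    "chrom": m.location.chrom,
                    "start": m.location.start,
                    "end": m.location.end,
                    "origin_category": m.origin_category or "",
                    "clade1_present": m.clade_support[0],
                    "clade2_present": m.clade_support[1],
                }
                for m in self.members
            ]
        )


def category_counts(atcnes) -> dict[str, int]:
    """Partition counts by origin category (the partition is exhaustive and
    disjoint, so the counts always sum to the set size)."""
    counts = {c: 0 for c in CATEGORIES}
    for m in atcnes:
        if m.origin_category not in counts:
            raise ValueError(f"uncategorized element {m.id}")
        counts[m.origin_category] += 1
    return counts


def gained_shares(counts: dict[str, int]) -> dict[str, float]:
    """Shares of post-vertebrate gains among gained (neopterygian+3R) elements, in %."""
    gained = counts["neopterygian"] + counts["3R"]
    if gained == 0:
        return {"neopterygian": float("nan"), "3R": float("nan")}
    return {
        "neopterygian": 100.0 * counts["neopterygian"] / gained,
        "3R": 100.0 * counts["3R"] / gained,
    }


# ------------------------------------------------------------- inference ---

def infer_ancestral_set(
    zcne_set: CNESet, fcne_set: CNESet, presence: PresenceMatrix, params: AncestryParams
) -> AtCNESet:
    """Infer the ancestral set from cross-clade presence.

    zCNEs (clade-1 reference) present in >= 1 clade-2 species are kept;
    fCNEs present in >= 1 clade-1 species are added unless they overlap a
    kept zCNE - overlap is assessed in the zCNE reference species via the
    fCNE's hit there (>= 1 bp), falling back to hit overlap in any shared
    species; the zCNE record wins.
    """
    kept: list[AtCNE] = []
    z_ref = zcne_set.ref_species
    z_footprints: dict[str, list[tuple[int, int, str]]] = {}

    def support(cne_id) -> tuple[int, int]:
        present = presence.species_present(cne_id)
        return len(present & params.clade1), len(present & params.clade2)

    for rec in zcne_set:
        c1, c2 = support(rec.id)
        if c2 >= 1:
            kept.append(AtCNE(rec, clade_support=(c1, c2)))
            z_footprints.setdefault(rec.location.chrom, []).append((rec.location.start, rec.location.end, rec.id))
    for rec in fcne_set:
        c1, c2 = support(rec.id)
        if c1 < 1:
            continue
        if _overlaps_kept(rec, presence, z_ref, z_footprints, kept):
            continue
        kept.append(AtCNE(rec, clade_support=(c1, c2)))
    return AtCNESet(kept)


def _overlaps_kept(rec, presence: PresenceMatrix, z_ref: str, z_footprints, kept) -> bool:
    hit = presence.hit(rec.id, z_ref)
    if hit is not None:
        for s, e, _ in z_footprints.get(hit.location.chrom, []):
            if hit.location.start < e and s < hit.location.end:
                return True
        return False
    # fallback: compare hits in any species shared with a kept zCNE
    shared = presence.species_present(rec.id)
    for z in kept:
        for sp in shared & presence.species_present(z.id):
            ha, hb = presence.hit(rec.id, sp), presence.hit(z.id, sp)
            if ha is not None and hb is not None and ha.location.overlaps(hb.location):
                return True
    return False


def categorize_origin(atcnes: AtCNESet, presence: PresenceMatrix, params: AncestryParams) -> AtCNESet:
    """Assign origin categories from outgroup presence (vertebrate wins over
    neopterygian; no outgroup hit means a 3R teleost-specific gain)."""
    for m in atcnes:
        present = presence.species_present(m.id)
        if present & params.vertebrate_outgroup:
            m.origin_category = "vertebrate"
        elif present & params.neopterygian_outgroup:
            m.origin_category = "neopterygian"
        else:
            m.origin_category = "3R"
    return atcnes


def loss_rates(atcnes: AtCNESet, presence: PresenceMatrix, species: list[str]) -> pd.DataFrame:
    """Per-species atCNE absence, by category, as % of all atCNEs.

    Columns: species, absent_<category>, pct_<category>, absent_total,
    pct_total; category percentages sum to the total by construction.
    """
    total = len(atcnes)
    rows = []
    for sp in species:
        row = {"species": sp}
        absent_total = 0
        for cat in CATEGORIES:
            absent = sum(1 for m in atcnes.of_category(cat) if not presence.present(m.id, sp))
            row[f"absent_{cat}"] = absent
            row[f"pct_{cat}"] = 100.0 * absent / total if total else 0.0
            absent_total += absent
        row["absent_total"] = absent_total
        row["pct_total"] = 100.0 * absent_total / total if total else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- zones ---

ZONE_CLASSES = ("empty", "vertebrate-containing", "novel-neopterygian", "novel-3R")


class ZoneProfile:
    """Fixed-size window profile of atCNE content on a reference genome."""

    def __init__(self, table: pd.DataFrame, zone_size: int):
        self.table = table
        self.zone_size = zone_size

    @property
    def n_zones(self) -> int:
        return len(self.table)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in ZONE_CLASSES}
        counts.update(self.table["zone_class"].value_counts().to_dict())
        return counts

    def n_occupied(self) -> int:
        return int((self.table["zone_class"] != "empty").sum())

    def empty_fraction(self) -> float:
        return float((self.table["zone_class"] == "empty").mean())

    def category_totals(self) -> dict[str, int]:
        return {c: int(self.table[f"n_{c}"].sum()) for c in CATEGORIES}


def classify_zone(n_vertebrate: int, n_neopterygian: int, n_3r: int) -> str:
    """Zone class from per-category content: empty; novel-3R (3R only,
    no older elements); novel-neopterygian (neopterygian, no vertebrate);
    otherwise vertebrate-containing."""
    if n_vertebrate + n_neopterygian + n_3r == 0:
        return "empty"
    if n_3r > 0 and n_vertebrate == 0 and n_neopterygian == 0:
        return "novel-3R"
    if n_neopterygian > 0 and n_vertebrate == 0:
        return "novel-neopterygian"
    return "vertebrate-containing"


def zone_profile(atcnes: AtCNESet, ref_genome: SpeciesGenome, params: AncestryParams, ref_species: str | None = None) -> ZoneProfile:
    """Tile each chromosome into ``zone_size`` windows (the final partial
    window is a zone) and count per-category atCNE content per zone."""
    Z = params.zone_size
    rows = []
    zone_of: dict[tuple[str, int], dict] = {}
    for chrom in sorted(ref_genome.sequences):
        L = len(ref_genome.sequences[chrom])
        n = max(1, -(-L // Z))
        for i in range(n):
            row = {"chrom": chrom, "start": i * Z, "end": min((i + 1) * Z, L)}
            for c in CATEGORIES:
                row[f"n_{c}"] = 0
            rows.append(row)
            zone_of[(chrom, i)] = row
    for m in atcnes:
        if ref_species is not None and m.ref_species != ref_species:
            continue
        loc = m.location
        if loc.chrom not in ref_genome.sequences:
            raise ValueError(f"atCNE {m.id} on unknown chromosome {loc.chrom}")
        if loc.end > len(ref_genome.sequences[loc.chrom]):
            raise ValueError(f"atCNE {m.id} beyond chromosome end (corrupt input)")
        anchor = loc.start if params.zone_anchor == "start" else (loc.start + loc.end) // 2
        row = zone_of[(loc.chrom, anchor // Z)]
        row[f"n_{m.origin_category}"] += 1
    table = pd.DataFrame(rows)
    table["zone_class"] = [
        classify_zone(r["n_vertebrate"], r["n_neopterygian"], r["n_3R"]) for r in rows
    ]
    return ZoneProfile(table, Z)


# ---------------------------------------------------------- conservation ---

def _oriented_hit_seq(hit, genomes) -> str:
    g = genomes[hit.species_id]
    seq = g.sequences[hit.location.chrom][hit.location.start : hit.location.end]
    return revcomp(seq) if hit.strand == "-" else seq


def _pair_identity(a: str, b: str) -> float:
    if len(a) == len(b):
        same = sum(x == y and x in "ACGT" for x, y in zip(a.upper(), b.upper()))
        return same / len(a) if a else 0.0
    try:
        import edlib

        res = edlib.align(a, b, task="distance", mode="NW")
        return max(0.0, 1.0 - res["editDistance"] / max(len(a), len(b)))
    except Exception:  # pragma: no cover
        n = min(len(a), len(b))
        same = sum(x == y for x, y in zip(a[:n], b[:n]))
        return same / max(len(a), len(b))


def conservation_score(atcne: AtCNE, presence: PresenceMatrix, genomes) -> float | None:
    """Mean pairwise identity of the element across all species where it is
    present (a column-identity substitute for model-based conservation
    scores). None with fewer than two species."""
    hits = [presence.hit(atcne.id, sp) for sp in presence.species if presence.present(atcne.id, sp)]
    if len(hits) < 2:
        return None
    seqs = [_oriented_hit_seq(h, genomes) for h in hits]
    idents = [_pair_identity(a, b) for a, b in itertools.combinations(seqs, 2)]
    return float(np.mean(idents))


def conservation_by_category(atcnes: AtCNESet, presence: PresenceMatrix, genomes) -> dict[str, float]:
    """Mean conservation score per origin category."""
    out = {}
    for cat in CATEGORIES:
        scores = [conservation_score(m, presence, genomes) for m in atcnes.of_category(cat)]
        scores = [s for s in scores if s is not None]
        out[cat] = float(np.mean(scores)) if scores else float("nan")
    return out
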
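"""Core coordinate and cohort data model.

All coordinates in the package are 0-based half-open on the forward strand;
conversions to the 1-based conventions of GFF3 and AXT happen only in
:mod:`cnekit.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import pandas as pd


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("empty chrom name")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def distance(self, other: "Interval") -> int:
        """Gap in bp between two intervals on the same chrom (0 if they overlap)."""
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        if self.overlaps(other):
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


@dataclass
class SpeciesGenome:
    """Sequences plus annotation intervals for one species."""

    sequences: dict[str, str]
    exons: list[Interval] = field(default_factory=list)
    repeats: list[Interval] = field(default_factory=list)
    #: optional gene bodies, keyed by gene id (used by target association)
    genes: dict[str, Interval] = field(default_factory=dict)

    def validate(self) -> None:
        for name, ivs in (("exon", self.exons), ("repeat", self.repeats)):
            for iv in ivs:
                if iv.chrom not in self.sequences:
                    raise ValueError(f"{name} interval on unknown sequence {iv.chrom}")
                if iv.end > len(self.sequences[iv.chrom]):
                    raise ValueError(f"{name} interval {iv} beyond sequence end")
        for gid, iv in self.genes.items():
            if iv.chrom not in self.sequences or iv.end > len(self.sequences[iv.chrom]):
                raise ValueError(f"gene {gid} interval {iv} outside genome")

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


class GenomeSet(dict):
    """Mapping species_id -> :class:`SpeciesGenome`."""

    def validate(self) -> None:
        for genome in self.values():
            genome.validate()


def n_run_intervals(seq: str, chrom: str, min_len: int = 1) -> list[Interval]:
    """Intervals of N runs in a sequence (hard-masked repeat recovery)."""
    out = []
    start = None
    for i, c in enumerate(seq):
        if c in "Nn":
            if start is None:
                start = i
        elif start is not None:
            if i - start >= min_len:
                out.append(Interval(chrom, start, i))
            start = None
    if start is not None and len(seq) - start >= min_len:
        out.append(Interval(chrom, start, len(seq)))
    return out


@dataclass
class SpeciesTree:
    """Species phylogeny plus the clade designations the ancestry logic needs.

    ``clade1_members`` / ``clade2_members`` are the two basally splitting
    teleost clades (zebrafish/tetra-like and fugu/seabream-like);
    ``outgroup_ids`` is the neopterygian outgroup (gar analog) and
    ``vertebrate_ids`` the non-neopterygian vertebrate outgroups.
    """

    newick: str
    clade1_members: frozenset[str]
    clade2_members: frozenset[str]
    outgroup_ids: frozenset[str] = frozenset()
    vertebrate_ids: frozenset[str] = frozenset()

    def __post_init__(self):
        self.clade1_members = frozenset(self.clade1_members)
        self.clade2_members = frozenset(self.clade2_members)
        self.outgroup_ids = frozenset(self.outgroup_ids)
        self.vertebrate_ids = frozenset(self.vertebrate_ids)
        if not self.clade1_members or not self.clade2_members:
            raise ValueError("both basal clades must be non-empty")
        if self.clade1_members & self.clade2_members:
            raise ValueError("clade1 and clade2 overlap")
        leaves = set(self.leaf_names())
        for group in (self.clade1_members, self.clade2_members, self.outgroup_ids, self.vertebrate_ids):
            missing = group - leaves
            if missing:
                raise ValueError(f"species not in tree: {sorted(missing)}")

    def to_dendropy(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.newick, schema="newick")

    def leaf_names(self) -> list[str]:
        return [t.label for t in self.to_dendropy().taxon_namespace]

    @property
    def teleost_ids(self) -> frozenset[str]:
        return frozenset(set(self.leaf_names()) - self.outgroup_ids - self.vertebrate_ids)


class OrthologyTable:
    """Per-species gene -> orthogroup assignments with paralogy annotations.

    Wraps a DataFrame with columns ``species_id, gene_id, orthogroup_id,
    paralog_partner_ids, paralog_origin``; ``paralog_partner_ids`` is a
    comma-separated list of same-species paralog gene ids and
    ``paralog_origin`` one of ``pre-WGD``, ``post-WGD``, ``none``.
    """

    COLUMNS = ["species_id", "gene_id", "orthogroup_id", "paralog_partner_ids", "paralog_origin"]

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"orthology table missing columns {sorted(missing)}")
        df = df[self.COLUMNS].copy()
        df["paralog_partner_ids"] = df["paralog_partner_ids"].fillna("")
        if df.duplicated(["species_id", "gene_id"]).any():
            raise ValueError("duplicate (species_id, gene_id) rows")
        bad = ~df["paralog_origin"].isin(["pre-WGD", "post-WGD", "none"])
        if bad.any():
            raise ValueError("invalid paralog_origin values")
        self.df = df
        self._og = dict(zip(zip(df.species_id, df.gene_id), df.orthogroup_id))
        self._partners = {
            (s, g): frozenset(p for p in partners.split(",") if p)
            for s, g, partners in zip(df.species_id, df.gene_id, df.paralog_partner_ids)
        }
        self.validate_symmetry()

    def validate_symmetry(self) -> None:
        for (sp, gene), partners in self._partners.items():
            for p in partners:
                if gene not in self._partners.get((sp, p), frozenset()):
                    raise ValueError(f"asymmetric paralog relation {gene} -> {p} in {sp}")

    def orthogroup(self, species_id: str, gene_id: str) -> str | None:
        return self._og.get((species_id, gene_id))

    def partners(self, species_id: str, gene_id: str) -> frozenset[str]:
        return self._partners.get((species_id, gene_id), frozenset())

    def are_paralogs(self, species_id: str, a: str, b: str) -> bool:
        return a == b or b in self.partners(species_id, a)

    def genes_of(self, species_id: str) -> pd.DataFrame:
        return self.df[self.df.species_id == species_id]
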
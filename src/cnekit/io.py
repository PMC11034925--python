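"""Readers and writers for the standard formats the pipeline touches.

Conventions: internal coordinates are 0-based half-open everywhere. BED is
native; GFF3 (1-based inclusive) and AXT (1-based inclusive, minus-strand
query coordinates given on the reverse-complemented strand) are converted at
this boundary and nowhere else.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seqtools import NT_ORDER
from .align import AlignmentBlock
from .model import Interval

log = logging.getLogger(__name__)


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------- FASTA ----

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file to ``{name: sequence}``.

    Characters outside {A,C,G,T,N} (either case) are uppercased and mapped
    to N with a warning; empty records are rejected.
    """
    with open(path) as fh:
        first = fh.readline()
    if first and not first.startswith((">", ";")):
        raise FormatError(f"{path}: line 1: expected FASTA header starting with '>'")
    seqs: dict[str, str] = {}
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    for rec in records:
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"{path}: empty sequence record {rec.id!r}")
        cleaned = "".join(c if c.upper() in NT_ORDER else ("n" if c.islower() else "N") for c in seq)
        if cleaned != seq:
            log.warning("%s: non-ACGTN characters in %s mapped to N", path, rec.id)
        seqs[rec.id] = cleaned
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    records = []
    for name, seq in seqs.items():
        if not seq:
            raise FormatError(f"refusing to write empty sequence record {name!r}")
        records.append(SeqRecord(Seq(seq), id=name, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ------------------------------------------------------------------ BED ----

def read_bed(path) -> list[Interval]:
    """Read BED3/BED6 to intervals; rows with start >= end are dropped and logged."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: BED needs >=3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "+"
            if start >= end:
                log.warning("%s: line %d: start >= end, row skipped", path, lineno)
                continue
            out.append(Interval(chrom, start, end, strand))
    return out


def write_bed(intervals, path, names=None, scores=None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if names is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                score = 0 if scores is None else scores[i]
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{names[i]}\t{score}\t{iv.strand}\n")


# ----------------------------------------------------------------- GFF3 ----

def read_gff3_exons(path) -> list[Interval]:
    """Exon intervals from a GFF3 file (type == 'exon'), converted to 0-based."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise FormatError(f"{path}: line {lineno}: GFF3 needs 8+ columns")
            if fields[2] != "exon":
                continue
            start, end = int(fields[3]) - 1, int(fields[4])
            if start >= end:
                log.warning("%s: line %d: start >= end, row skipped", path, lineno)
                continue
            strand = fields[6] if fields[6] in "+-" else "+"
            out.append(Interval(fields[0], start, end, strand))
    return out


def read_gff3_genes(path) -> dict[str, Interval]:
    """Gene bodies from GFF3 rows with type == 'gene' (ID=... attribute)."""
    out: dict[str, Interval] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv)
            gid = attrs.get("ID", f"{fields[0]}:{fields[3]}")
            strand = fields[6] if fields[6] in "+-" else "+"
            out[gid] = Interval(fields[0], int(fields[3]) - 1, int(fields[4]), strand)
    return out


# ------------------------------------------------------------------ AXT ----

def read_axt(path, query_sizes: dict[str, int] | None = None) -> list[AlignmentBlock]:
    """Read AXT triplet records to alignment blocks.

    AXT coordinates are 1-based inclusive; minus-strand query coordinates are
    given on the reverse-complemented query strand and are normalized here to
    forward-strand intervals (this needs ``query_sizes`` for '-' blocks).
    """
    blocks = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    lineno = 0
    while i < len(lines):
        if not lines[i].strip() or lines[i].startswith("#"):
            i += 1
            continue
        header = lines[i].split()
        if len(header) != 9:
            raise FormatError(f"{path}: line {i + 1}: AXT header needs 9 fields")
        if i + 2 >= len(lines):
            raise FormatError(f"{path}: line {i + 1}: truncated AXT record")
        _, rchrom, rstart, rend, qchrom, qstart, qend, strand, score = header
        ref_aln, query_aln = lines[i + 1], lines[i + 2]
        if len(ref_aln) != len(query_aln):
            raise FormatError(f"{path}: line {i + 2}: aligned rows differ in length")
        rs, re_ = int(rstart) - 1, int(rend)
        qs, qe = int(qstart) - 1, int(qend)
        if strand == "-":
            if query_sizes is None or qchrom not in query_sizes:
                raise FormatError(f"{path}: need query size for minus-strand block on {qchrom}")
            L = query_sizes[qchrom]
            qs, qe = L - qe, L - (int(qstart) - 1)
        blocks.append(
            AlignmentBlock(
                ref=Interval(rchrom, rs, re_),
                query=Interval(qchrom, qs, qe, strand),
                strand=strand,
                ref_aln=ref_aln,
                query_aln=query_aln,
                score=float(score),
            )
        )
        i += 3
        lineno += 1
    return blocks


def write_axt(blocks, path, query_sizes: dict[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        for n, b in enumerate(blocks):
            if b.strand == "-":
                if query_sizes is None or b.query.chrom not in query_sizes:
                    raise FormatError(f"need query size for minus-strand block on {b.query.chrom}")
                L = query_sizes[b.query.chrom]
                qstart, qend = L - b.query.end + 1, L - b.query.start
            else:
                qstart, qend = b.query.start + 1, b.query.end
            fh.write(
                f"{n} {b.ref.chrom} {b.ref.start + 1} {b.ref.end} "
                f"{b.query.chrom} {qstart} {qend} {b.strand} {int(b.score)}\n"
            )
            fh.write(b.ref_aln + "\n")
            fh.write(b.query_aln + "\n\n")


# ------------------------------------------------------------------ TSV ----

def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------- validate ----

def validate_file(path) -> str:
    """One-line validation report for a file, dispatched on suffix."""
    p = Path(path)
    try:
        if p.suffix in (".fa", ".fasta", ".fna"):
            seqs = read_fasta(p)
            total = sum(len(s) for s in seqs.values())
            return f"{p}: FASTA ok, {len(seqs)} records, {total} bp"
        if p.suffix == ".bed":
            ivs = read_bed(p)
            return f"{p}: BED ok, {len(ivs)} intervals"
        if p.suffix in (".gff3", ".gff"):
            exons = read_gff3_exons(p)
            return f"{p}: GFF3 ok, {len(exons)} exons"
        if p.suffix == ".axt":
            blocks = read_axt(p, query_sizes=None) if _axt_all_plus(p) else None
            if blocks is None:
                return f"{p}: AXT ok (minus-strand blocks present; sizes needed to load)"
            return f"{p}: AXT ok, {len(blocks)} blocks"
        if p.suffix in (".nwk", ".newick", ".tree"):
            import dendropy

            t = dendropy.Tree.get(path=str(p), schema="newick")
            return f"{p}: newick ok, {len(t.leaf_nodes())} leaves"
        if p.suffix == ".tsv":
            df = read_tsv(p)
            return f"{p}: TSV ok, {len(df)} rows x {len(df.columns)} cols"
        return f"{p}: unknown format (skipped)"
    except Exception as exc:  # report, do not raise: this is a linting surface
        return f"{p}: INVALID - {exc}"


def _axt_all_plus(path) -> bool:
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) == 9 and parts[7] == "-":
                return False
    return True
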
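"""Shared genomic-interval type and strict readers/writers for external formats.

All coordinates are 0-based half-open in memory.  Text formats keep their
native conventions: GFF3 and BLAST tabular are 1-based inclusive, BED is
0-based half-open.  Conversions are lossless and involutive.

Masking convention: lowercase bases are soft-masked, ``N`` is hard-masked;
both are excluded from homology-search seeding.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BLAST_TAB_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


class FormatError(ValueError):
    """Raised on malformed input; message carries file and line context."""


@dataclasses.dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded interval on a scaffold, 0-based half-open."""

    scaffold: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strand-agnostic overlap of >= 1 shared base."""
        return (
            self.scaffold == other.scaffold
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Bases strictly between the two intervals (negative if they touch/overlap)."""
        if self.scaffold != other.scaffold:
            raise ValueError("gap undefined across scaffolds")
        if self.start <= other.start:
            return other.start - self.end
        return self.start - other.end

    def union_span(self, other: "GenomicInterval") -> "GenomicInterval":
        return GenomicInterval(
            self.scaffold, min(self.start, other.start),
            max(self.end, other.end), self.strand,
        )


# ---------------------------------------------------------------------------
# coordinate dialects

@dataclasses.dataclass(frozen=True)
class FormatDialect:
    name: str
    one_based: bool
    inclusive_end: bool


DIALECTS: dict[str, FormatDialect] = {
    "internal": FormatDialect("internal", one_based=False, inclusive_end=False),
    "bed": FormatDialect("bed", one_based=False, inclusive_end=False),
    "gff3": FormatDialect("gff3", one_based=True, inclusive_end=True),
    "blast-tab-12": FormatDialect("blast-tab-12", one_based=True, inclusive_end=True),
}


def convert_coordinates(
    start: int, end: int, from_dialect: str, to_dialect: str
) -> tuple[int, int]:
    """Convert a (start, end) pair between coordinate dialects.

    Round-trip identity and length preservation are guaranteed.
    """
    src = DIALECTS[from_dialect]
    dst = DIALECTS[to_dialect]
    # A 1-based inclusive end and a 0-based half-open end coincide numerically,
    # so only the start shifts between the supported conventions.
    s = start - 1 if src.one_based else start
    return (s + 1 if dst.one_based else s), end


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered {id: sequence} mapping; case preserved."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3

GFF3_HEADER = "##gff-version 3"


def write_gff3(features: Iterable[Sequence], path: str | Path) -> None:
    """Write rows of (scaffold, source, type, start0, end0, score, strand, phase, attrs).

    Coordinates are internal 0-based half-open and are converted to the
    1-based inclusive GFF3 convention on output.
    """
    with open(path, "w") as fh:
        fh.write(GFF3_HEADER + "\n")
        for scaffold, source, ftype, start, end, score, strand, phase, attrs in features:
            s1, e1 = convert_coordinates(start, end, "internal", "gff3")
            fh.write(
                f"{scaffold}\t{source}\t{ftype}\t{s1}\t{e1}\t{score}\t{strand}\t{phase}\t{attrs}\n"
            )


def iter_gff3(path: str | Path):
    """Yield (lineno, fields9) for each feature line; validates column count."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            yield lineno, fields


# ---------------------------------------------------------------------------
# BED

def write_bed(intervals: Iterable[tuple[GenomicInterval, str]], path: str | Path) -> None:
    """Write (interval, name) pairs as BED6 (0-based half-open natively)."""
    with open(path, "w") as fh:
        for iv, name in intervals:
            fh.write(f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            name = f[3] if len(f) > 3 else f"feature_{lineno}"
            strand = f[5] if len(f) > 5 else "+"
            out.append((GenomicInterval(f[0], int(f[1]), int(f[2]), strand), name))
    return out


# ---------------------------------------------------------------------------
# BLAST 12-column tabular

def read_blast_tab(path: str | Path) -> pd.DataFrame:
    """Read 12-column BLAST tabular output; raises with line number on bad rows."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(f)}"
                )
            try:
                rows.append(
                    (
                        f[0], f[1], float(f[2]), int(f[3]), int(f[4]), int(f[5]),
                        int(f[6]), int(f[7]), int(f[8]), int(f[9]),
                        float(f[10]), float(f[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return pd.DataFrame(rows, columns=BLAST_TAB_COLUMNS)


def write_blast_tab(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=BLAST_TAB_COLUMNS)


# ---------------------------------------------------------------------------
# TSV helpers

def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# validation

def validate_inputs(paths: Mapping[str, str | Path]) -> pd.DataFrame:
    """Validate a {format_name: path} mapping; returns a per-file pass/fail report.

    Supported format names: fasta, gff3, bed, blast-tab-12, tsv.
    """
    report = []
    for fmt, path in paths.items():
        status, detail = "pass", ""
        try:
            if fmt == "fasta":
                read_fasta(path)
            elif fmt == "gff3":
                _validate_gff3(path)
            elif fmt == "bed":
                read_bed(path)
            elif fmt == "blast-tab-12":
                read_blast_tab(path)
            elif fmt == "tsv":
                _validate_tsv(path)
            else:
                status, detail = "fail", f"unknown format {fmt!r}"
        except (FormatError, OSError, ValueError) as exc:
            status, detail = "fail", str(exc)
        report.append({"format": fmt, "path": str(path), "status": status, "detail": detail})
    return pd.DataFrame(report)


def _validate_gff3(path: str | Path) -> None:
    gene_spans: dict[str, tuple[str, int, int]] = {}
    pending_exons = []
    for lineno, f in iter_gff3(path):
        start, end = int(f[3]), int(f[4])
        if start > end or start < 1:
            raise FormatError(f"{path}:{lineno}: bad coordinates {start}..{end}")
        attrs = dict(
            kv.split("=", 1) for kv in f[8].split(";") if kv and "=" in kv
        )
        if f[2] == "gene":
            gene_spans[attrs.get("ID", "")] = (f[0], start, end)
        elif f[2] == "exon":
            pending_exons.append((lineno, f[0], start, end, attrs.get("Parent", "")))
    for lineno, scaf, start, end, parent in pending_exons:
        parent_gene = parent.split(".")[0]
        if parent_gene in gene_spans:
            g_scaf, g_start, g_end = gene_spans[parent_gene]
            if scaf != g_scaf or start < g_start or end > g_end:
                raise FormatError(
                    f"{path}:{lineno}: exon [{start},{end}] outside gene "
                    f"{parent_gene} span [{g_start},{g_end}]"
                )


def _validate_tsv(path: str | Path) -> None:
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            n = len(line.rstrip("\n").split("\t"))
            if ncols is None:
                ncols = n
            elif n != ncols:
                raise FormatError(
                    f"{path}:{lineno}: {n} columns, expected {ncols}"
                )
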
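"""Readers and writers for the standard formats the pipeline consumes.

FASTA/FASTQ go through Biopython.  The tabular dialects are the 12-column
blast tabular format (outfmt 6), the 3-column samtools-depth table, and the
project's own TSVs (header line starting with ``#``, ``.`` for undefined
values).  Only CHROM/POS/REF/ALT/QUAL are consulted in VCFs.
"""

from __future__ import annotations

import io as _io
import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence, TextIO

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .windows import Contig, Window

MISSING = "."


# ---------------------------------------------------------------- FASTA/FASTQ

def read_fasta(path: str | os.PathLike) -> list[Contig]:
    return [Contig(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(contigs: Iterable[Contig], path: str | os.PathLike) -> None:
    records = (SeqRecord(Seq(c.sequence), id=c.contig_id, description="") for c in contigs)
    SeqIO.write(records, str(path), "fasta")


def read_fastq_sequences(path: str | os.PathLike) -> list[str]:
    """Read sequences only (ids/qualities are not used downstream)."""
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]


# ------------------------------------------------------------- depth records

@dataclass(frozen=True)
class DepthRecord:
    name: str
    pos: int  # 1-based
    depth: int


def parse_depth_table(source: str | os.PathLike | TextIO) -> Iterator[DepthRecord]:
    """Stream a 3-column samtools-depth table (name, 1-based pos, depth)."""
    close, handle = _open(source)
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(
                    f"depth table line {lineno}: expected 3 columns, got {len(fields)}"
                )
            name, pos_s, depth_s = fields
            try:
                pos = int(pos_s)
                depth = int(depth_s)
            except ValueError as exc:
                raise ValueError(f"depth table line {lineno}: non-integer field") from exc
            if pos < 1:
                raise ValueError(f"depth table line {lineno}: positions are 1-based, got {pos}")
            if depth < 0:
                raise ValueError(f"depth table line {lineno}: negative depth {depth}")
            yield DepthRecord(name, pos, depth)
    finally:
        if close:
            handle.close()


def write_depth_table(records: Iterable[tuple[str, int, int]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, pos, depth in records:
            fh.write(f"{name}\t{pos}\t{depth}\n")


# --------------------------------------------------------------- VCF records

@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    qual: float | None


def parse_vcf(source: str | os.PathLike | TextIO) -> Iterator[VariantRecord]:
    """Minimal VCF v4.x reader consulting CHROM/POS/REF/ALT/QUAL only."""
    close, handle = _open(source)
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(
                    f"VCF line {lineno}: expected >= 8 columns, got {len(fields)}"
                )
            chrom, pos_s, _id, ref, alt, qual_s = fields[:6]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise ValueError(f"VCF line {lineno}: non-integer POS {pos_s!r}") from exc
            if pos < 1:
                raise ValueError(f"VCF line {lineno}: POS is 1-based, got {pos}")
            if not ref:
                raise ValueError(f"VCF line {lineno}: empty REF")
            qual = None if qual_s in (MISSING, "") else float(qual_s)
            alts = tuple(a for a in alt.split(",") if a and a != MISSING)
            yield VariantRecord(chrom, pos, ref.upper(), tuple(a.upper() for a in alts), qual)
    finally:
        if close:
            handle.close()


def write_vcf(
    records: Iterable[tuple[str, int, str, str, float | None, str]],
    path: str | os.PathLike,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write (chrom, pos, ref, alt, qual, info) tuples as a minimal VCF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        for name, length in (contig_lengths or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt, qual, info in records:
            qual_s = MISSING if qual is None else f"{qual:g}"
            fh.write(f"{chrom}\t{pos}\t{MISSING}\t{ref}\t{alt}\t{qual_s}\t{MISSING}\t{info}\n")


# ----------------------------------------------------------- SAM/BAM access

def depth_records_from_alignments(path: str | os.PathLike) -> Iterator[DepthRecord]:
    """Per-base depth from a SAM/BAM file, all records counted (secondary
    and supplementary included, mirroring all-alignments mapping modes).

    Yields (reference name, 1-based position, depth) for covered positions.
    """
    import numpy as np
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        lengths = dict(zip(af.references, af.lengths))
        cover: dict[str, "np.ndarray"] = {}
        for aln in af:
            if aln.is_unmapped or aln.reference_name is None:
                continue
            ref = aln.reference_name
            if ref not in cover:
                cover[ref] = np.zeros(lengths[ref] + 1, dtype=np.int64)
            cover[ref][aln.reference_start] += 1
            cover[ref][aln.reference_end] -= 1
    for ref in sorted(cover):
        depth = np.cumsum(cover[ref][:-1])
        for pos0 in np.flatnonzero(depth):
            yield DepthRecord(ref, int(pos0) + 1, int(depth[pos0]))


def reads_overlapping_from_alignments(
    path: str | os.PathLike, contig_id: str, start: int, end: int
) -> list[str]:
    """Sequences of reads whose alignment overlaps [start, end) on a contig.

    Used to collect the read set underlying one window from a SAM/BAM file;
    secondary records without stored sequence are skipped.
    """
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for aln in af:
            if aln.is_unmapped or aln.reference_name != contig_id:
                continue
            if aln.reference_end is None or aln.query_sequence is None:
                continue
            if aln.reference_start < end and aln.reference_end > start:
                out.append(aln.query_sequence.upper())
    return out


# -------------------------------------------------- blast tabular (outfmt 6)

#: column order of the standard 12-column tabular alignment format
TABULAR_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore"
).split()


def parse_alignment_table(source: str | os.PathLike | TextIO) -> pd.DataFrame:
    """Parse 12-column tabular alignments; '#' comment lines are skipped."""
    close, handle = _open(source)
    rows = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"alignment table line {lineno}: expected 12 columns, got {len(fields)}"
                )
            rows.append(fields)
    finally:
        if close:
            handle.close()
    df = pd.DataFrame(rows, columns=TABULAR_COLUMNS)
    if len(df):
        df = df.astype(
            {
                "pident": float,
                "length": int,
                "mismatch": int,
                "gapopen": int,
                "qstart": int,
                "qend": int,
                "sstart": int,
                "send": int,
                "evalue": float,
                "bitscore": float,
            }
        )
    return df


# ------------------------------------------------------------- project TSVs

def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a DataFrame with a '#'-prefixed header and '.' for NA."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False, na_rep=MISSING)


def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise ValueError(f"{path}: expected '#'-prefixed header line")
        columns = header[1:].split("\t")
        df = pd.read_csv(fh, sep="\t", names=columns, na_values=[MISSING], **kwargs)
    return df


def write_window_index(windows: Sequence[Window], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        {
            "window_id": [w.window_id for w in windows],
            "contig_id": [w.contig_id for w in windows],
            "start0": [w.start for w in windows],
            "end0": [w.end for w in windows],
        }
    )
    write_tsv(df, path)


def read_window_index(path: str | os.PathLike) -> pd.DataFrame:
    df = read_tsv(path)
    expected = ["window_id", "contig_id", "start0", "end0"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return df


def read_bins_table(path: str | os.PathLike) -> dict[str, str]:
    """contig_id -> bin_id mapping from a 2-column TSV (header optional)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"bins table line {lineno}: expected 2 columns")
            contig_id, bin_id = fields
            if contig_id == "contig_id" and lineno == 1:
                continue
            if contig_id in mapping and mapping[contig_id] != bin_id:
                raise ValueError(f"bins table line {lineno}: contig {contig_id} in two bins")
            mapping[contig_id] = bin_id
    return mapping


def _open(source) -> tuple[bool, TextIO]:
    if isinstance(source, (str, os.PathLike)):
        return True, open(source)
    if isinstance(source, str):  # pragma: no cover - defensive
        return True, _io.StringIO(source)
    return False, source
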
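"""Readers and writers for the plain-text formats the toolkit consumes.

BED is the plain 3-6 column tab-delimited dialect, 0-based half-open.
Gene tables are refFlat-like: gene_id, gene_name, chrom, strand, txStart,
txEnd. Write->read round-trips are identity.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import GeneModel, GenomeLayout, GenomicInterval, Peak

__all__ = [
    "read_bed",
    "write_bed",
    "read_gene_table",
    "write_gene_table",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_fasta",
    "write_fasta",
]


class FormatError(ValueError):
    """Malformed input line; message carries the file and line number."""


def _fail(path: str | os.PathLike, lineno: int, msg: str) -> None:
    raise FormatError(f"{path}:{lineno}: {msg}")


def read_bed(path: str | os.PathLike) -> list[Peak]:
    """Read a BED3+ file into :class:`Peak` records.

    Column 4 becomes the peak name, column 5 the score; extra columns are
    ignored. Strand (column 6) is carried on the interval when present.
    """
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                _fail(path, lineno, f"expected >=3 tab-separated columns, got {len(fields)}")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError:
                _fail(path, lineno, f"non-integer coordinates in {fields[1:3]}")
            name = fields[3] if len(fields) > 3 else ""
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError:
                _fail(path, lineno, f"non-numeric score {fields[4]!r}")
            strand = fields[5] if len(fields) > 5 else "."
            try:
                peaks.append(Peak(GenomicInterval(chrom, start, end, strand), score, name))
            except ValueError as e:
                _fail(path, lineno, str(e))
    return peaks


def write_bed(
    records: Iterable[Peak | GenomicInterval], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, Peak):
                iv, name, score = rec.interval, rec.name, rec.score
            else:
                iv, name, score = rec, "", 0.0
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )


def read_gene_table(path: str | os.PathLike) -> list[GeneModel]:
    """Read a refFlat-like gene table (gene_id, name, chrom, strand, txStart,
    txEnd). The TSS is txStart for + genes and txEnd-1 for - genes."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                _fail(path, lineno, f"expected >=6 columns, got {len(fields)}")
            gene_id, gene_name, chrom, strand = fields[:4]
            try:
                tx_start, tx_end = int(fields[4]), int(fields[5])
            except ValueError:
                _fail(path, lineno, f"non-integer txStart/txEnd in {fields[4:6]}")
            try:
                genes.append(
                    GeneModel(
                        gene_id, gene_name, chrom, strand,
                        GenomicInterval(chrom, tx_start, tx_end, strand),
                    )
                )
            except ValueError as e:
                _fail(path, lineno, str(e))
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.gene_name}\t{g.chrom}\t{g.strand}"
                f"\t{g.span.start}\t{g.span.end}\n"
            )


def read_chrom_sizes(path: str | os.PathLike) -> GenomeLayout:
    """Read a two-column chrom<TAB>length file into a :class:`GenomeLayout`."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                _fail(path, lineno, "expected chrom<TAB>length")
            try:
                length = int(fields[1])
            except ValueError:
                _fail(path, lineno, f"non-integer length {fields[1]!r}")
            if fields[0] in lengths:
                _fail(path, lineno, f"duplicate chromosome {fields[0]!r}")
            lengths[fields[0]] = length
    return GenomeLayout(lengths)


def write_chrom_sizes(genome: GenomeLayout, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")
    }


def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, os.fspath(path), "fasta")
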
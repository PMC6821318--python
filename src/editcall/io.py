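"""Readers and writers for the standard formats at the package boundary."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTQ file (Phred+33) into ``(read_id, sequence)`` pairs."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, quality_char: str = "I") -> None:
    """Write reads as FASTQ with a constant per-base quality."""
    q = ord(quality_char) - 33
    records = (
        SeqRecord(Seq(seq), id=rid, description="", letter_annotations={"phred_quality": [q] * len(seq)})
        for rid, seq in reads
    )
    SeqIO.write(records, str(path), "fastq")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = (SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items())
    SeqIO.write(records, str(path), "fasta")


def write_bed(regions: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    """Write 0-based half-open regions as 3-column BED."""
    with open(path, "w") as fh:
        for chrom, start, end in regions:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_clone_manifest(path: str | Path) -> list[dict[str, str]]:
    """Read a colony manifest TSV with columns: colony, target, fastq."""
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = {"colony", "target", "fastq"}
        if not required.issubset(header):
            raise ValueError(f"{path}: manifest needs columns {sorted(required)}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            values = dict(zip(header, line.split("\t")))
            if len(values) < len(required):
                raise ValueError(f"{path}:{lineno}: short row")
            rows.append(values)
    return rows
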
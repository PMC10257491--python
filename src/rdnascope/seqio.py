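"""FASTA/FASTQ/BED6/GFF3 input and output.

Thin wrappers around Biopython's SeqIO that speak the pipeline's own
:class:`~rdnascope.core.SequenceRecord` / :class:`~rdnascope.core.AnnotationBlock`
types. All readers and writers are gzip-transparent (by ``.gz`` suffix).
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .core import AnnotationBlock, Interval, SequenceRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_bed",
    "write_bed",
    "write_gff3",
]


def _open(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def _to_record(rec: BioSeqRecord, with_qual: bool) -> SequenceRecord:
    quals = None
    if with_qual:
        quals = list(rec.letter_annotations.get("phred_quality", []))
        if not quals:
            quals = None
    return SequenceRecord(rec.id, str(rec.seq).upper(), quals)


def read_fasta(path: str | Path) -> Iterator[SequenceRecord]:
    with _open(path, "r") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            yield _to_record(rec, with_qual=False)


def read_fastq(path: str | Path) -> Iterator[SequenceRecord]:
    with _open(path, "r") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield _to_record(rec, with_qual=True)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with _open(path, "w") as fh:
        for rec in records:
            bio = BioSeqRecord(Seq(rec.residues), id=rec.id, description="")
            SeqIO.write(bio, fh, "fasta")


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with _open(path, "w") as fh:
        for rec in records:
            if rec.qualities is None:
                raise ValueError(f"{rec.id}: FASTQ output requires qualities")
            bio = BioSeqRecord(Seq(rec.residues), id=rec.id, description="")
            bio.letter_annotations["phred_quality"] = list(rec.qualities)
            SeqIO.write(bio, fh, "fastq")


def write_bed(blocks: Iterable[AnnotationBlock], path: str | Path) -> None:
    """BED6: 0-based half-open coordinates, label as name, source as score 0."""
    with _open(path, "w") as fh:
        for b in blocks:
            iv = b.interval
            fh.write(
                f"{iv.ref_id}\t{iv.start}\t{iv.end}\t{b.label}\t0\t{iv.strand}\n"
            )


def read_bed(path: str | Path, source: str = "truth") -> list[AnnotationBlock]:
    blocks = []
    with _open(path, "r") as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            iv = Interval(f[0], int(f[1]), int(f[2]), f[5] if len(f) > 5 else "+")
            blocks.append(AnnotationBlock(f[3] if len(f) > 3 else ".", iv, source))
    return blocks


def write_gff3(blocks: Iterable[AnnotationBlock], path: str | Path) -> None:
    """GFF3: converts to 1-based inclusive coordinates."""
    with _open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for b in blocks:
            iv = b.interval
            fh.write(
                f"{iv.ref_id}\trdnascope\tregion\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tName={b.label};source={b.source}\n"
            )
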
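"""Genome assembly container and FASTA/FASTQ plumbing."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID = frozenset("ACGTN")


@dataclass
class GenomeAssembly:
    """Named contigs of uppercase nucleotide sequence over {A,C,G,T,N}.

    The substrate for translated search and element insertion.
    """

    contigs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {cid!r} is empty")
            extra = set(seq) - _VALID
            if extra:
                raise ValueError(
                    f"contig {cid!r} contains characters outside ACGTN: {sorted(extra)}"
                )

    def __len__(self) -> int:
        return len(self.contigs)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def items(self) -> Iterator[tuple[str, str]]:
        return iter(self.contigs.items())

    def __getitem__(self, contig_id: str) -> str:
        return self.contigs[contig_id]

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self.contigs

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeAssembly":
        contigs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in contigs:
                raise ValueError(f"duplicate contig id {rec.id!r} in {path}")
            contigs[rec.id] = str(rec.seq).upper()
        return cls(contigs)

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        records = [
            SeqRecord(Seq(seq), id=cid, description="") for cid, seq in self.contigs.items()
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
            writer.write_file(records)


@dataclass(frozen=True)
class Read:
    """A single-end sequencing read."""

    read_id: str
    sequence: str
    quality: str


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path: str | Path) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(Read(rec.id, str(rec.seq).upper(), qual))
    return reads


def write_protein_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
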
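"""Thin FASTA/FASTQ helpers built on Biopython."""

from __future__ import annotations

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str) -> dict[str, str]:
    """Load a FASTA file into an ordered {name: uppercase sequence} dict."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, path, "fasta")


def read_fastq_seqs(path: str):
    """Yield read sequences (uppercase strings) from a FASTQ file."""
    for rec in SeqIO.parse(path, "fastq"):
        yield str(rec.seq).upper()


def write_fastq(reads: list[tuple[str, str]], path: str) -> None:
    """Write (name, sequence) pairs as FASTQ with uniform quality."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
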
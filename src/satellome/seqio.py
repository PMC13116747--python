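"""Thin FASTA/FASTQ readers over Biopython."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_fasta_list(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.description, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    with open(path) as fh:
        return [(title, seq) for title, seq, _q in FastqGeneralIterator(fh)]
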
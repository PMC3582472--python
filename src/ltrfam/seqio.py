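"""FASTA reading and strand-aware sequence extraction."""

from __future__ import annotations

import re
from typing import TextIO

from Bio import SeqIO
from Bio.Seq import Seq

from .model import FeatureNode, LtrfamError, SequenceCollection

_NON_NUC = re.compile(r"[^ACGTN]")


def read_fasta(stream: TextIO) -> tuple[SequenceCollection, list[str]]:
    """Read FASTA records in order; returns (collection, warnings).

    Sequences are uppercased; symbols outside {A,C,G,T,N} are mapped to N
    with a warning.  Record order defines the ``seqX`` numbering (0-based).
    """
    warnings: list[str] = []
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(stream, "fasta"):
        name = rec.id
        if name in seen:
            warnings.append(f"duplicate FASTA header {name!r}")
        seen.add(name)
        seq = str(rec.seq).upper()
        if _NON_NUC.search(seq):
            warnings.append(f"non-nucleotide symbols in {name!r} mapped to N")
            seq = _NON_NUC.sub("N", seq)
        records.append((name, seq))
    return SequenceCollection(records), warnings


def write_fasta(records: list[tuple[str, str]], stream: TextIO, width: int = 80) -> None:
    for name, seq in records:
        stream.write(f">{name}\n")
        for i in range(0, len(seq), width):
            stream.write(seq[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_sequence(node: FeatureNode, seqs: SequenceCollection) -> str:
    """Genomic substring [start..end] of the node, reverse-complemented on '-'.

    Strands '.' and '?' are treated as '+'.
    """
    genome = seqs.get(node.seqid)
    if node.end > len(genome):
        raise LtrfamError(
            f"feature {node.so_type} [{node.start},{node.end}] exceeds "
            f"sequence {node.seqid!r} of length {len(genome)}"
        )
    sub = genome[node.start - 1 : node.end]
    if node.strand == "-":
        return reverse_complement(sub)
    return sub
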
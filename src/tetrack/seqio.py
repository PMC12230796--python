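"""FASTA/FASTQ input and output.

An *assembly* is represented as a plain ``dict`` mapping contig id to an
upper-case nucleotide string; a *read set* is a list of :class:`Read`.
Sequences are case-folded to upper on input and restricted to the alphabet
``ACGTN``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Read:
    id: str
    sequence: str


def _validate(name: str, seq: str) -> str:
    if not seq:
        raise ValueError(f"empty record {name!r}")
    seq = seq.upper()
    bad = set(seq) - ALPHABET
    if bad:
        raise ValueError(f"illegal characters {sorted(bad)} in record {name!r}")
    return seq


def read_fasta(path: Union[str, Path, io.TextIOBase]) -> Dict[str, str]:
    """Read a FASTA file into an ``{id: sequence}`` dict.

    Duplicate ids, empty records and characters outside ``ACGTN`` raise
    :class:`ValueError`.  Sequences are upper-cased.
    """
    assembly: Dict[str, str] = {}
    for rec in SeqIO.parse(path if isinstance(path, io.TextIOBase) else str(path), "fasta"):
        if rec.id in assembly:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        assembly[rec.id] = _validate(rec.id, str(rec.seq))
    if not assembly:
        raise ValueError("no FASTA records found")
    return assembly


def write_fasta(assembly: Dict[str, str], path: Union[str, Path]) -> Path:
    path = Path(path)
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in assembly.items()]
    SeqIO.write(records, str(path), "fasta")
    return path


def read_fastq(path: Union[str, Path]) -> List[Read]:
    reads = [Read(rec.id, _validate(rec.id, str(rec.seq))) for rec in SeqIO.parse(str(path), "fastq")]
    if not reads:
        raise ValueError("no FASTQ records found")
    return reads


def write_fastq(reads: Iterable[Read], path: Union[str, Path]) -> Path:
    """Write reads as FASTQ with uniform placeholder qualities (Q40)."""
    path = Path(path)
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")
    return path
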
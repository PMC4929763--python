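"""FASTA I/O and nucleotide primitives shared by the whole pipeline.

Sequences are plain uppercase strings over ``{A, C, G, T, N}``.  Soft-masked
(lowercase) input is uppercased on load; any other character is rejected with
a :class:`FastaFormatError` naming the offending record and position.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, List

from Bio import SeqIO

__all__ = [
    "NucleotideSequence",
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "iupac_matches",
    "IUPAC_CODES",
]

VALID_RESIDUES = frozenset("ACGTN")

#: IUPAC nucleotide codes mapped to the set of *unambiguous* residues they
#: accept.  A residue ``N`` in a sequence is an unknown base: it matches no
#: pattern letter except pattern ``N`` (conservative — unknown bases never
#: create spurious matches).
IUPAC_CODES = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGTN"),
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA content (empty file, duplicate ids,
    illegal residues)."""


@dataclass(frozen=True)
class NucleotideSequence:
    """One named DNA sequence.

    ``id`` is the FASTA header token up to the first whitespace; ``residues``
    is uppercase over ``{A, C, G, T, N}``.
    """

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


def _validate_residues(seq_id: str, residues: str) -> str:
    upper = residues.upper()
    for pos, ch in enumerate(upper, start=1):
        if ch not in VALID_RESIDUES:
            raise FastaFormatError(
                f"record {seq_id!r}: illegal residue {ch!r} at position {pos}"
            )
    return upper


def read_fasta(path: os.PathLike | str) -> List[NucleotideSequence]:
    """Read a (possibly multi-record, line-wrapped) FASTA file.

    Residues are uppercased; ids are truncated at the first whitespace.
    Raises ``FileNotFoundError`` for a missing file and
    :class:`FastaFormatError` for an empty file, duplicate ids or residues
    outside ``{A, C, G, T, N}`` (case-insensitive).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: List[NucleotideSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq_id = rec.id
        if not seq_id:
            raise FastaFormatError(f"{path}: record with empty id")
        if seq_id in seen:
            raise FastaFormatError(f"{path}: duplicate record id {seq_id!r}")
        seen.add(seq_id)
        residues = _validate_residues(seq_id, str(rec.seq))
        if not residues:
            raise FastaFormatError(f"{path}: record {seq_id!r} has no residues")
        records.append(NucleotideSequence(id=seq_id, residues=residues))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    records: Iterable[NucleotideSequence],
    path: os.PathLike | str,
    line_width: int = 70,
) -> None:
    """Write records as wrapped FASTA with LF line endings."""
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), line_width):
                fh.write(rec.residues[i : i + line_width] + "\n")


def reverse_complement(s: str) -> str:
    """Watson-Crick reverse complement; ``N`` maps to ``N``."""
    for ch in s:
        if ch not in VALID_RESIDUES:
            raise ValueError(f"illegal residue {ch!r} in sequence")
    return s.translate(_COMPLEMENT)[::-1]


def iupac_matches(pattern: str, s: str) -> bool:
    """True iff each residue of ``s`` is accepted by the IUPAC code at the
    same position of ``pattern``.

    Lengths must agree.  A residue ``N`` matches only pattern ``N``.
    """
    if len(pattern) != len(s):
        raise ValueError(
            f"pattern length {len(pattern)} != sequence length {len(s)}"
        )
    for p, ch in zip(pattern, s):
        try:
            allowed = IUPAC_CODES[p]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {p!r} in pattern") from None
        if ch not in allowed:
            return False
    return True
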
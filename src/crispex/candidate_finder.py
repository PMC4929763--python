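"""Enumeration of 23-nt Cas9 target candidates on both strands of a query.

A candidate is a 20-nt protospacer followed by a 3-nt PAM.  Coordinates are
1-based inclusive on the query's forward strand regardless of the candidate's
strand, so reports are directly comparable across strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

from .sequence_io import NucleotideSequence, iupac_matches, reverse_complement

__all__ = ["RunConfig", "GuideCandidate", "enumerate_candidates"]

SITE_LEN = 23
PROTO_LEN = 20

#: PAM rule -> required residues at PAM positions 2 and 3 (position 1 is N).
PAM_TAILS = {"NGG": "GG", "NAG": "AG"}


@dataclass(frozen=True)
class RunConfig:
    """Run-wide parameters.

    ``pam_rule``: ``NGG`` or ``NAG`` (one rule per run).
    ``start_rule``: ``G`` restricts candidates to protospacers starting with
    G; ``N`` allows any start base.
    ``max_mismatch``: protospacer Hamming ceiling for the level-1 off-target
    check.
    ``seed_length``: length of the PAM-proximal seed window (fixed at 15:
    12 protospacer bases + 3-nt PAM).
    """

    pam_rule: str = "NGG"
    start_rule: str = "N"
    max_mismatch: int = 2
    seed_length: int = 15

    def __post_init__(self) -> None:
        if self.pam_rule not in PAM_TAILS:
            raise ValueError(f"pam_rule must be NGG or NAG, got {self.pam_rule!r}")
        if self.start_rule not in ("G", "N"):
            raise ValueError(f"start_rule must be G or N, got {self.start_rule!r}")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        if self.seed_length != 15:
            raise ValueError("seed_length is fixed at 15")


@dataclass(frozen=True)
class GuideCandidate:
    """One 23-nt candidate target located on a query sequence.

    ``protospacer`` and ``pam`` are given in candidate-strand orientation;
    for strand ``-`` the 23-mer is the reverse complement of the query slice
    ``[start, stop]``.
    """

    query_id: str
    start: int  # 1-based inclusive, forward coordinates
    stop: int  # start + 22
    strand: str  # '+' or '-'
    protospacer: str
    pam: str
    site23: str = field(default="")

    def __post_init__(self) -> None:
        if not self.site23:
            object.__setattr__(self, "site23", self.protospacer + self.pam)
        if len(self.protospacer) != PROTO_LEN or len(self.pam) != 3:
            raise ValueError("protospacer must be 20 nt and PAM 3 nt")
        if self.site23 != self.protospacer + self.pam:
            raise ValueError("site23 must equal protospacer + pam")
        if self.stop - self.start != SITE_LEN - 1:
            raise ValueError("stop - start must be 22")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


def _window_candidate(
    query_id: str, offset: int, window: str, strand: str, config: RunConfig
) -> GuideCandidate | None:
    """Validate one oriented 23-mer; returns None if it fails the rules."""
    if "N" in window:
        return None  # ambiguous guides cannot be synthesized
    if not iupac_matches(config.pam_rule, window[20:]):
        return None
    if config.start_rule == "G" and window[0] != "G":
        return None
    return GuideCandidate(
        query_id=query_id,
        start=offset + 1,
        stop=offset + SITE_LEN,
        strand=strand,
        protospacer=window[:20],
        pam=window[20:],
    )


def enumerate_candidates(
    query: NucleotideSequence, config: RunConfig
) -> List[GuideCandidate]:
    """Return every rule-satisfying 23-nt window on both strands of the query.

    Overlapping windows are all examined; output is sorted by
    ``(start, strand)`` with ``+`` before ``-``.  A query shorter than 23 nt
    yields an empty list.
    """
    seq = query.residues
    out: List[GuideCandidate] = []
    for i in range(len(seq) - SITE_LEN + 1):
        window = seq[i : i + SITE_LEN]
        fwd = _window_candidate(query.id, i, window, "+", config)
        if fwd is not None:
            out.append(fwd)
        rev = _window_candidate(
            query.id, i, reverse_complement(window), "-", config
        )
        if rev is not None:
            out.append(rev)
    return out
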
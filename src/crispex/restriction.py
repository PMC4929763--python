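"""Restriction-site annotation of candidate 23-mers for RFLP mutant screens.

Cas9 cuts bluntly 3–4 bases upstream of the PAM, i.e. at the 17|18 boundary
of the 23-mer with the adjacent 16|17 boundary also honoured.  A recognition
site "overlaps the cleavage position" iff it covers both flanking bases of
either boundary.  Both strands of the 23-mer are scanned because recognition
sites need not be palindromic; palindromic double matches at one interval
collapse to a single ``+`` record.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import List, Sequence

from .candidate_finder import SITE_LEN, GuideCandidate
from .sequence_io import IUPAC_CODES, iupac_matches, reverse_complement

__all__ = [
    "RestrictionEnzyme",
    "RestrictionMatch",
    "RestrictionAnnotation",
    "EnzymeTableError",
    "DEFAULT_ENZYMES",
    "load_enzymes",
    "find_sites",
    "annotate",
    "overlaps_cleavage",
]


class EnzymeTableError(ValueError):
    """Malformed enzyme table (bad row, duplicate name, illegal IUPAC code)."""


@dataclass(frozen=True)
class RestrictionEnzyme:
    name: str
    site: str  # IUPAC recognition sequence, length 4-15

    def __post_init__(self) -> None:
        if not self.site or not all(c in IUPAC_CODES for c in self.site):
            raise EnzymeTableError(
                f"enzyme {self.name!r}: invalid IUPAC site {self.site!r}"
            )


@dataclass(frozen=True)
class RestrictionMatch:
    enzyme_name: str
    start: int  # 1-based inclusive within the 23-mer
    end: int  # inclusive
    strand: str  # strand of the 23-mer on which the pattern reads 5'->3'
    overlaps_cleavage: bool


@dataclass(frozen=True)
class RestrictionAnnotation:
    matches: List[RestrictionMatch]
    cleavage_matches: List[RestrictionMatch]
    any_site: bool
    any_cleavage_site: bool


# Stand-in table of common commercial 6-cutters; replaceable via
# load_enzymes()/--enzymes.
DEFAULT_ENZYMES = [
    RestrictionEnzyme("EcoRI", "GAATTC"),
    RestrictionEnzyme("BamHI", "GGATCC"),
    RestrictionEnzyme("HindIII", "AAGCTT"),
    RestrictionEnzyme("XhoI", "CTCGAG"),
    RestrictionEnzyme("NdeI", "CATATG"),
    RestrictionEnzyme("SpeI", "ACTAGT"),
    RestrictionEnzyme("PstI", "CTGCAG"),
    RestrictionEnzyme("SalI", "GTCGAC"),
    RestrictionEnzyme("NcoI", "CCATGG"),
    RestrictionEnzyme("KpnI", "GGTACC"),
    RestrictionEnzyme("SacI", "GAGCTC"),
    RestrictionEnzyme("XbaI", "TCTAGA"),
]


def overlaps_cleavage(start: int, end: int) -> bool:
    """Interval predicate for covering the 17|18 or 16|17 cut boundary."""
    return (start <= 17 and end >= 18) or (start <= 16 and end >= 17)


def load_enzymes(path: os.PathLike | str) -> List[RestrictionEnzyme]:
    """Parse a two-column ``name,site`` CSV; ``#`` comment lines skipped."""
    enzymes: List[RestrictionEnzyme] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise EnzymeTableError(
                    f"{path}:{lineno}: expected 'name,site', got {line!r}"
                )
            name, site = parts[0], parts[1].upper()
            if name in seen:
                raise EnzymeTableError(f"{path}:{lineno}: duplicate enzyme {name!r}")
            if not all(c in IUPAC_CODES for c in site):
                raise EnzymeTableError(
                    f"{path}:{lineno}: illegal IUPAC character in site {site!r}"
                )
            seen.add(name)
            enzymes.append(RestrictionEnzyme(name, site))
    if not enzymes:
        raise EnzymeTableError(f"{path}: no enzymes loaded")
    return enzymes


def find_sites(
    site23: str, enzymes: Sequence[RestrictionEnzyme]
) -> List[RestrictionMatch]:
    """Every IUPAC match of every enzyme on either strand of the 23-mer.

    Reverse-strand matches are reported in forward 23-mer coordinates with
    strand ``-``; a palindromic double match at the same interval collapses
    to one ``+`` record.  Sorted by (start, enzyme_name, strand).
    """
    if len(site23) != SITE_LEN:
        raise ValueError(f"expected a 23-nt sequence, got length {len(site23)}")
    rc = reverse_complement(site23)
    found: dict[tuple, RestrictionMatch] = {}
    for enz in enzymes:
        m = len(enz.site)
        if m > SITE_LEN:
            continue
        for i in range(SITE_LEN - m + 1):
            if iupac_matches(enz.site, site23[i : i + m]):
                start, end = i + 1, i + m
                found[(enz.name, start, end, "+")] = RestrictionMatch(
                    enz.name, start, end, "+", overlaps_cleavage(start, end)
                )
        for j in range(SITE_LEN - m + 1):
            if iupac_matches(enz.site, rc[j : j + m]):
                start, end = SITE_LEN - m + 1 - j, SITE_LEN - j
                if (enz.name, start, end, "+") in found:
                    continue  # palindromic double match
                found[(enz.name, start, end, "-")] = RestrictionMatch(
                    enz.name, start, end, "-", overlaps_cleavage(start, end)
                )
    return sorted(
        found.values(), key=lambda r: (r.start, r.enzyme_name, r.strand)
    )


def annotate(
    candidate: GuideCandidate, enzymes: Sequence[RestrictionEnzyme]
) -> RestrictionAnnotation:
    """All enzyme matches on the candidate 23-mer plus cleavage-overlap flags."""
    matches = find_sites(candidate.site23, enzymes)
    cleavage = [m for m in matches if m.overlaps_cleavage]
    return RestrictionAnnotation(
        matches=matches,
        cleavage_matches=cleavage,
        any_site=bool(matches),
        any_cleavage_site=bool(cleavage),
    )
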
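"""Two-level specificity check designating potential Cas9 targets.

Level 1 passes a candidate when no *second* genomic site lies within the
protospacer-mismatch ceiling; level 2 passes when no second site reproduces
the 15-base seed (12 PAM-proximal protospacer bases + PAM) exactly.  The
candidate's own locus — present whenever the query derives from the genome —
is the one permitted hit, hence both thresholds are "at most one site".
Queries absent from the background (e.g. plasmids) simply have zero
self-hits and the same thresholds apply.  A candidate passing both levels is
a potential target; multi-copy genes legitimately fail both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

from .candidate_finder import GuideCandidate, RunConfig
from .genome_search import GenomeIndex, OffTargetHit, find_hits

__all__ = [
    "SpecificityResult",
    "check_level1",
    "check_level2",
    "classify",
    "classify_hits",
]


@dataclass(frozen=True)
class SpecificityResult:
    n_hits_within_ceiling: int
    n_seed_exact: int
    level1_pass: bool
    level2_pass: bool
    potential: bool

    def __post_init__(self) -> None:
        assert self.potential == (self.level1_pass and self.level2_pass)


def check_level1(hits: List[OffTargetHit], config: RunConfig) -> bool:
    """True iff at most one genomic site is within ``max_mismatch``
    protospacer mismatches (i.e. no off-target neighbour exists)."""
    n = sum(h.protospacer_mismatches <= config.max_mismatch for h in hits)
    return n <= 1


def check_level2(hits: List[OffTargetHit]) -> bool:
    """True iff at most one genomic site reproduces the seed exactly."""
    return sum(h.seed_exact for h in hits) <= 1


def classify_hits(hits: List[OffTargetHit], config: RunConfig) -> SpecificityResult:
    """Build the full result from a precomputed hit list (any hit backend)."""
    n_within = sum(h.protospacer_mismatches <= config.max_mismatch for h in hits)
    n_seed = sum(h.seed_exact for h in hits)
    l1 = n_within <= 1
    l2 = n_seed <= 1
    return SpecificityResult(
        n_hits_within_ceiling=n_within,
        n_seed_exact=n_seed,
        level1_pass=l1,
        level2_pass=l2,
        potential=l1 and l2,
    )


def classify(
    candidate: GuideCandidate, index: GenomeIndex, config: RunConfig
) -> SpecificityResult:
    """Run the indexed off-target search and both check levels."""
    return classify_hits(find_hits(index, candidate, config), config)
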
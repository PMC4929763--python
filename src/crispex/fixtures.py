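"""Deterministic synthetic genomes with planted target structures.

Every plant's expected specificity outcome is *verified* against the
brute-force oracle during generation (rejection sampling with bounded
retries), so test expectations are guaranteed rather than merely probable:
a random background can in principle collide with a 15-mer seed, and such a
draw is regenerated, never shipped.

Plant kinds:

``unique_target``
    a 23-mer present exactly once → passes both filters.
``duplicated_target``
    the same 23-mer spliced verbatim at one or more extra loci → both fail.
``near_miss``
    an extra copy carrying ``k`` protospacer substitutions at given 1-based
    positions; with ``k <= max_mismatch`` level 1 fails, and level 2 fails
    iff every substitution sits in positions 1-8 (outside the seed).
``seed_exact_decoy``
    a copy with 3 substitutions confined to positions 1-8: level 1 passes
    (3 > ceiling) while the intact seed makes level 2 fail.
``restriction_overlap``
    a unique target whose 23-mer carries an enzyme site spanning the
    cleavage boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .candidate_finder import GuideCandidate, RunConfig
from .genome_search import brute_force_hits
from .restriction import DEFAULT_ENZYMES, annotate
from .sequence_io import NucleotideSequence, write_fasta
from .specificity_filter import SpecificityResult, classify_hits

__all__ = ["PlantSpec", "FixtureExpectation", "Fixture", "make_genome", "standard_fixture", "save_fixture"]

FLANK = 30  # background context kept on each side of a planted 23-mer
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

KINDS = (
    "unique_target",
    "duplicated_target",
    "near_miss",
    "seed_exact_decoy",
    "restriction_overlap",
)


@dataclass(frozen=True)
class PlantSpec:
    """One planted structure.

    ``locations`` holds ``(contig_index, 1-based position)`` pairs: the first
    is the primary locus (spliced together with its gene flanks), the rest
    receive the exact/mutated 23-mer copy depending on ``kind``.
    """

    kind: str
    gene_id: str
    locations: Tuple[Tuple[int, int], ...]
    mismatch_positions: Tuple[int, ...] = ()  # 1-based protospacer positions
    enzyme_site: str = "GAATTC"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown plant kind {self.kind!r}")
        if not self.locations:
            raise ValueError(f"{self.gene_id}: at least one location required")
        if self.kind == "seed_exact_decoy" and not self.mismatch_positions:
            object.__setattr__(self, "mismatch_positions", (2, 4, 6))
        if self.kind in ("duplicated_target", "near_miss", "seed_exact_decoy"):
            if len(self.locations) < 2:
                raise ValueError(f"{self.gene_id}: {self.kind} needs a second locus")
        if self.kind == "near_miss":
            if not self.mismatch_positions:
                raise ValueError(f"{self.gene_id}: near_miss needs mismatch positions")
        if any(not (1 <= p <= 20) for p in self.mismatch_positions):
            raise ValueError(f"{self.gene_id}: mismatch positions must be in 1-20")


@dataclass(frozen=True)
class FixtureExpectation:
    """Closed-form ground truth for the planted candidate of one gene."""

    gene_id: str
    candidate: GuideCandidate
    specificity: SpecificityResult
    any_cleavage_site: bool


@dataclass
class Fixture:
    genome: List[NucleotideSequence]
    queries: List[NucleotideSequence]
    expected: Dict[str, FixtureExpectation]
    config: RunConfig = field(default_factory=RunConfig)


def _expected_counts(plant: PlantSpec, config: RunConfig) -> Tuple[int, int]:
    """(sites within mismatch ceiling, seed-exact sites) implied by the plant."""
    n_extra = len(plant.locations) - 1
    if plant.kind in ("unique_target", "restriction_overlap"):
        return 1, 1
    if plant.kind == "duplicated_target":
        return 1 + n_extra, 1 + n_extra
    k = len(plant.mismatch_positions)
    within = 1 + (n_extra if k <= config.max_mismatch else 0)
    seed_intact = all(p <= 8 for p in plant.mismatch_positions)
    seed = 1 + (n_extra if seed_intact else 0)
    return within, seed


def _mutate(base: str) -> str:
    return {"A": "C", "C": "A", "G": "T", "T": "G"}[base]


def _build_site23(rng: np.random.Generator, plant: PlantSpec, config: RunConfig) -> str:
    """Random rule-satisfying 23-mer; start base fixed to G so the plant is
    enumerable under either start rule."""
    proto = "G" + "".join(
        chr(b) for b in _BASES[rng.integers(0, 4, size=19)]
    )
    if plant.kind == "restriction_overlap":
        site = plant.enzyme_site
        if len(site) != 6:
            raise ValueError("restriction_overlap plants expect a 6-base site")
        # occupy 23-mer positions 14-19: spans both cut boundaries
        proto = proto[:13] + site + proto[19:]
    pam_mid = {"NGG": "G", "NAG": "A"}[config.pam_rule]
    pam = chr(_BASES[rng.integers(0, 4)]) + pam_mid + "G"
    return proto + pam


def _variant_site(site23: str, plant: PlantSpec) -> str:
    """The 23-mer spliced at secondary loci (verbatim or mutated copy)."""
    if plant.kind == "duplicated_target":
        return site23
    chars = list(site23)
    for p in plant.mismatch_positions:
        chars[p - 1] = _mutate(chars[p - 1])
    return "".join(chars)


def _check_layout(plants: Sequence[PlantSpec], n_contigs: int, contig_length: int) -> None:
    occupied: List[Tuple[int, int, int]] = []
    for plant in plants:
        for li, (ci, pos) in enumerate(plant.locations):
            if not (0 <= ci < n_contigs):
                raise ValueError(f"{plant.gene_id}: contig index {ci} out of range")
            pad = FLANK if li == 0 else 0
            lo, hi = pos - pad, pos + 22 + pad
            if lo < 1 or hi > contig_length:
                raise ValueError(
                    f"{plant.gene_id}: plant at ({ci}, {pos}) does not fit"
                )
            for oc, olo, ohi in occupied:
                if oc == ci and not (hi < olo or lo > ohi):
                    raise ValueError(
                        f"{plant.gene_id}: plant at ({ci}, {pos}) overlaps another"
                    )
            occupied.append((ci, lo, hi))


def make_genome(
    n_contigs: int,
    contig_length: int,
    plants: Sequence[PlantSpec],
    rng_seed: int,
    config: RunConfig | None = None,
    max_retries: int = 30,
) -> Fixture:
    """Generate a synthetic genome + query genes with verified ground truth.

    The background is uniform over ACGT from a seeded generator.  After
    planting, every plant's expected hit counts are recomputed with
    :func:`brute_force_hits`; if the random background accidentally creates
    extra hits the whole draw is regenerated (up to ``max_retries``).
    Identical arguments always produce identical bytes.
    """
    config = config or RunConfig()
    _check_layout(plants, n_contigs, contig_length)
    rng = np.random.default_rng(rng_seed)

    for _attempt in range(max_retries):
        contigs = [
            _BASES[rng.integers(0, 4, size=contig_length)].copy()
            for _ in range(n_contigs)
        ]
        genes: List[NucleotideSequence] = []
        planted: List[Tuple[PlantSpec, str]] = []
        for plant in plants:
            site23 = _build_site23(rng, plant, config)
            variant = _variant_site(site23, plant)
            for li, (ci, pos) in enumerate(plant.locations):
                chunk = site23 if li == 0 else variant
                contigs[ci][pos - 1 : pos + 22] = np.frombuffer(
                    chunk.encode("ascii"), dtype=np.uint8
                )
            planted.append((plant, site23))
        genome = [
            NucleotideSequence(id=f"contig{ci + 1}", residues=arr.tobytes().decode("ascii"))
            for ci, arr in enumerate(contigs)
        ]
        expected: Dict[str, FixtureExpectation] = {}
        ok = True
        for plant, site23 in planted:
            ci, pos = plant.locations[0]
            gene_seq = genome[ci].residues[pos - 1 - FLANK : pos + 22 + FLANK]
            genes.append(NucleotideSequence(id=plant.gene_id, residues=gene_seq))
            candidate = GuideCandidate(
                query_id=plant.gene_id,
                start=FLANK + 1,
                stop=FLANK + 23,
                strand="+",
                protospacer=site23[:20],
                pam=site23[20:],
            )
            want_within, want_seed = _expected_counts(plant, config)
            result = classify_hits(
                brute_force_hits(genome, candidate, config), config
            )
            if (result.n_hits_within_ceiling, result.n_seed_exact) != (
                want_within,
                want_seed,
            ):
                ok = False
                break
            expected[plant.gene_id] = FixtureExpectation(
                gene_id=plant.gene_id,
                candidate=candidate,
                specificity=result,
                any_cleavage_site=annotate(candidate, DEFAULT_ENZYMES).any_cleavage_site,
            )
        if ok:
            return Fixture(genome=genome, queries=genes, expected=expected, config=config)
    raise RuntimeError(
        f"fixture verification failed after {max_retries} attempts (seed {rng_seed})"
    )


_STANDARD_KINDS = [
    ("unique_target", ()),
    ("duplicated_target", ()),
    ("near_miss", (16,)),
    ("near_miss", (5, 18)),
    ("seed_exact_decoy", (2, 4, 6)),
    ("restriction_overlap", ()),
]


def standard_fixture(
    rng_seed: int,
    n_genes: int = 20,
    config: RunConfig | None = None,
) -> Fixture:
    """The canonical 3-contig x 5-kb suite used across the test modules.

    Gene kinds cycle through unique / duplicated / 1-mismatch near miss /
    2-mismatch near miss / seed-exact decoy / restriction overlap.
    """
    n_contigs, contig_length = 3, 5000
    plants: List[PlantSpec] = []
    for g in range(n_genes):
        kind, positions = _STANDARD_KINDS[g % len(_STANDARD_KINDS)]
        ci = g % n_contigs
        slot = g // n_contigs
        pos = 100 + slot * 600
        locations = [(ci, pos)]
        if kind in ("duplicated_target", "near_miss", "seed_exact_decoy"):
            locations.append((ci, pos + 300))
        plants.append(
            PlantSpec(
                kind=kind,
                gene_id=f"gene{g + 1:02d}",
                locations=tuple(locations),
                mismatch_positions=tuple(positions),
            )
        )
    return make_genome(n_contigs, contig_length, plants, rng_seed, config=config)


def save_fixture(fixture: Fixture, outdir: os.PathLike | str) -> Tuple[str, str]:
    """Write genome and query FASTA files; returns their paths."""
    os.makedirs(outdir, exist_ok=True)
    genome_path = os.path.join(outdir, "genome.fasta")
    query_path = os.path.join(outdir, "queries.fasta")
    write_fasta(fixture.genome, genome_path)
    write_fasta(fixture.queries, query_path)
    return genome_path, query_path
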
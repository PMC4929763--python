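"""Genome-wide off-target search.

Two independent routes are provided:

* :func:`build_index` / :func:`find_hits` — a PAM-anchored index over every
  valid 23-mer site on both strands of every contig.  Protospacers are packed
  2 bits/base into ``uint64`` and bucketed under (a) the 12-base PAM-proximal
  seed and (b) ``max_mismatch + 1`` contiguous partitions of the 20-mer, so
  by pigeonhole any site within the mismatch ceiling shares at least one
  exact partition with the candidate and is guaranteed to be retrieved.
* :func:`brute_force_hits` — a naive both-strand window scan sharing no
  matching code with the index, kept as the reference oracle.

Mismatches are counted over the 20-nt protospacer only.  The PAM gates site
validity (positions 2–3 must equal the rule's letters; position 1 is a
wildcard) and never contributes to the mismatch count.  Windows containing
``N`` are excluded on the genome side exactly as on the query side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .candidate_finder import PAM_TAILS, PROTO_LEN, SITE_LEN, GuideCandidate, RunConfig
from .sequence_io import NucleotideSequence, reverse_complement

__all__ = ["GenomeIndex", "OffTargetHit", "build_index", "find_hits", "brute_force_hits"]

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_CODE[ord("N")] = 4

_PAIR_MASK = np.uint64(0x5555555555555555)
_SEED_MASK = np.uint64((1 << 24) - 1)  # protospacer positions 9..20


@dataclass(frozen=True)
class OffTargetHit:
    """One genomic occurrence of a candidate.

    ``start`` is the 1-based forward-strand start of the 23-mer on ``contig``.
    ``protospacer_mismatches`` is the Hamming distance over the 20 protospacer
    positions with both sequences in candidate orientation.  ``seed_exact`` is
    true iff the last 15 bases of the 23-mer (12 proximal protospacer bases +
    PAM, PAM position 1 wildcarded) match with zero mismatches.
    """

    contig: str
    start: int
    strand: str
    protospacer_mismatches: int
    seed_exact: bool


class GenomeIndex:
    """PAM-anchored catalog of every valid 23-mer site in a genome.

    Built once per (genome, config); queried per candidate by
    :func:`find_hits`.  ``max_mismatch`` at query time must not exceed the
    value the index was built with, or partition completeness is lost.
    """

    def __init__(
        self,
        contigs: Sequence[NucleotideSequence],
        config: RunConfig,
    ) -> None:
        if not contigs:
            raise ValueError("empty genome: at least one contig required")
        self.contigs = list(contigs)
        self.pam_rule = config.pam_rule
        self.max_mismatch = config.max_mismatch
        self._contig_names = [c.id for c in self.contigs]

        tail = PAM_TAILS[config.pam_rule]
        p2, p3 = int(_CODE[ord(tail[0])]), int(_CODE[ord(tail[1])])

        contig_ids: List[np.ndarray] = []
        starts: List[np.ndarray] = []
        strands: List[np.ndarray] = []
        packed: List[np.ndarray] = []
        for ci, contig in enumerate(self.contigs):
            f_idx, f_pack, r_idx, r_pack = _scan_contig(contig.residues, p2, p3)
            for idx, pk, strand_code in ((f_idx, f_pack, 0), (r_idx, r_pack, 1)):
                if idx.size:
                    contig_ids.append(np.full(idx.size, ci, dtype=np.int32))
                    starts.append((idx + 1).astype(np.int32))
                    strands.append(np.full(idx.size, strand_code, dtype=np.int8))
                    packed.append(pk)

        if contig_ids:
            cid = np.concatenate(contig_ids)
            st = np.concatenate(starts)
            sd = np.concatenate(strands)
            pk = np.concatenate(packed)
            order = np.lexsort((sd, st, cid))
            self._contig_id = cid[order]
            self._start = st[order]
            self._strand = sd[order]
            self._packed = pk[order]
        else:
            self._contig_id = np.empty(0, dtype=np.int32)
            self._start = np.empty(0, dtype=np.int32)
            self._strand = np.empty(0, dtype=np.int8)
            self._packed = np.empty(0, dtype=np.uint64)

        # Bucket keys: seed (12 proximal bases) + max_mismatch+1 partitions.
        self._partitions = _partition_bounds(config.max_mismatch + 1)
        self._buckets = []
        keys = [self._packed & _SEED_MASK]
        for a, b in self._partitions:
            shift = np.uint64(2 * (PROTO_LEN - b))
            mask = np.uint64((1 << (2 * (b - a))) - 1)
            keys.append((self._packed >> shift) & mask)
        for key in keys:
            order = np.argsort(key, kind="stable")
            self._buckets.append((key[order], order.astype(np.int64)))

    # -- introspection -------------------------------------------------

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)

    @property
    def n_sites(self) -> int:
        return int(self._packed.size)

    def site_counts(self) -> Dict[str, int]:
        """Number of cataloged PAM sites per contig."""
        counts = {name: 0 for name in self._contig_names}
        uniq, n = np.unique(self._contig_id, return_counts=True)
        for ci, c in zip(uniq, n):
            counts[self._contig_names[int(ci)]] = int(c)
        return counts

    # -- query ---------------------------------------------------------

    def candidate_site_ids(self, cand_code: np.uint64) -> np.ndarray:
        """Site ids sharing the candidate's seed or any partition key."""
        chunks = []
        queries = [cand_code & _SEED_MASK]
        for a, b in self._partitions:
            shift = np.uint64(2 * (PROTO_LEN - b))
            mask = np.uint64((1 << (2 * (b - a))) - 1)
            queries.append((cand_code >> shift) & mask)
        for (sorted_keys, ids), q in zip(self._buckets, queries):
            lo = np.searchsorted(sorted_keys, q, side="left")
            hi = np.searchsorted(sorted_keys, q, side="right")
            if hi > lo:
                chunks.append(ids[lo:hi])
        if not chunks:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(chunks))


def _partition_bounds(n_parts: int) -> List[tuple]:
    edges = np.linspace(0, PROTO_LEN, n_parts + 1).astype(int)
    return [(int(edges[i]), int(edges[i + 1])) for i in range(n_parts)]


def _scan_contig(residues: str, p2: int, p3: int):
    """Locate PAM-valid, N-free 23-mer windows on both strands of one contig.

    Returns forward window offsets + packed protospacers, then the same for
    reverse-strand sites (offsets are forward-strand, 0-based).
    """
    c = _CODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    L = c.size
    n = L - SITE_LEN + 1
    empty = (np.empty(0, np.int64), np.empty(0, np.uint64))
    if n <= 0:
        return empty[0], empty[1], empty[0], empty[1]

    is_n = (c == 4).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(is_n)))
    clean = (cs[SITE_LEN:] - cs[:n]) == 0

    fwd = clean & (c[21 : 21 + n] == p2) & (c[22 : 22 + n] == p3)
    # reverse-strand PAM on forward coordinates: complement(tail) reversed
    rev = clean & (c[0:n] == 3 - p3) & (c[1 : 1 + n] == 3 - p2)

    cc = c.astype(np.uint64)
    pf = np.zeros(n, dtype=np.uint64)
    pr = np.zeros(n, dtype=np.uint64)
    three = np.uint64(3)
    for j in range(PROTO_LEN):
        pf = (pf << np.uint64(2)) | cc[j : j + n]
        pr = (pr << np.uint64(2)) | (three - cc[22 - j : 22 - j + n])

    f_idx = np.nonzero(fwd)[0]
    r_idx = np.nonzero(rev)[0]
    return f_idx, pf[f_idx], r_idx, pr[r_idx]


def pack_protospacer(protospacer: str) -> np.uint64:
    """2-bit big-endian packing of a 20-nt N-free protospacer."""
    if len(protospacer) != PROTO_LEN:
        raise ValueError("protospacer must be 20 nt")
    code = np.uint64(0)
    for ch in protospacer:
        v = int(_CODE[ord(ch)])
        if v > 3:
            raise ValueError(f"cannot pack ambiguous base {ch!r}")
        code = (code << np.uint64(2)) | np.uint64(v)
    return code


def build_index(
    genome: Sequence[NucleotideSequence], config: RunConfig
) -> GenomeIndex:
    """Index every PAM-anchored site on both strands of every contig."""
    return GenomeIndex(genome, config)


def find_hits(
    index: GenomeIndex, candidate: GuideCandidate, config: RunConfig
) -> List[OffTargetHit]:
    """All genomic sites within the mismatch ceiling, plus every seed-exact
    site regardless of mismatch count; sorted by (contig, start, strand)."""
    if config.pam_rule != index.pam_rule:
        raise ValueError(
            f"index built for PAM {index.pam_rule}, queried with {config.pam_rule}"
        )
    if config.max_mismatch > index.max_mismatch:
        raise ValueError(
            f"index guarantees completeness up to {index.max_mismatch} "
            f"mismatches; got max_mismatch={config.max_mismatch}"
        )
    cand_code = pack_protospacer(candidate.protospacer)
    ids = index.candidate_site_ids(cand_code)
    if ids.size == 0:
        return []
    z = index._packed[ids] ^ cand_code
    pairs = (z | (z >> np.uint64(1))) & _PAIR_MASK
    mm = np.bitwise_count(pairs)
    seed_ok = (z & _SEED_MASK) == 0
    keep = (mm <= config.max_mismatch) | seed_ok
    ids = ids[keep]
    mm = mm[keep]
    seed_ok = seed_ok[keep]
    names = index._contig_names
    return [
        OffTargetHit(
            contig=names[int(index._contig_id[i])],
            start=int(index._start[i]),
            strand="+" if index._strand[i] == 0 else "-",
            protospacer_mismatches=int(m),
            seed_exact=bool(s),
        )
        for i, m, s in zip(ids, mm, seed_ok)
    ]


def brute_force_hits(
    genome: Sequence[NucleotideSequence],
    candidate: GuideCandidate,
    config: RunConfig,
) -> List[OffTargetHit]:
    """Reference oracle: slide a 23-nt window over both strands of every
    contig and apply the hit contract literally.  Shares no matching code
    with the index path."""
    tail = PAM_TAILS[config.pam_rule]
    proto = candidate.protospacer
    seed12 = candidate.site23[8:20]
    max_mm = config.max_mismatch
    hits: List[OffTargetHit] = []
    for contig in genome:
        s = contig.residues
        for i in range(len(s) - SITE_LEN + 1):
            window = s[i : i + SITE_LEN]
            for strand, oriented in (("+", window), ("-", None)):
                if oriented is None:
                    oriented = reverse_complement(window)
                if oriented[21:23] != tail or "N" in oriented:
                    continue
                mm = sum(a != b for a, b in zip(proto, oriented[:20]))
                seed_exact = oriented[8:20] == seed12
                if mm <= max_mm or seed_exact:
                    hits.append(
                        OffTargetHit(
                            contig=contig.id,
                            start=i + 1,
                            strand=strand,
                            protospacer_mismatches=mm,
                            seed_exact=seed_exact,
                        )
                    )
    return hits
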
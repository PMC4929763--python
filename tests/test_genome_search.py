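import numpy as np
import pytest

from conftest import get_random_genome, random_residues
from crispex.candidate_finder import GuideCandidate, RunConfig
from crispex.genome_search import brute_force_hits, build_index, find_hits
from crispex.sequence_io import NucleotideSequence, reverse_complement

# Frozen naive count of PAM-anchored NGG sites (both strands, N-free) on the
# seed-7 fixture genome: 3 contigs x 5 kb from np.random.default_rng(7).
SEED7_SITE_COUNT = 1816


def seed7_genome():
    rng = np.random.default_rng(7)
    return [NucleotideSequence(f"c{i + 1}", random_residues(rng, 5000)) for i in range(3)]


def make_candidate(site23, query_id="q"):
    return GuideCandidate(query_id, 1, 23, "+", site23[:20], site23[20:])


def sample_candidates(genome, rng, n, max_mut=3, pam_tail="GG"):
    """Candidates drawn from genomic windows with 0..max_mut substitutions,
    plus some fully random ones."""
    cands = []
    while len(cands) < n:
        if rng.random() < 0.25:
            site = random_residues(rng, 20) + random_residues(rng, 1) + pam_tail
        else:
            contig = genome[int(rng.integers(0, len(genome)))]
            i = int(rng.integers(0, len(contig.residues) - 23))
            w = contig.residues[i : i + 23]
            if rng.integers(0, 2):
                w = reverse_complement(w)
            chars = list(w[:20])
            for p in rng.choice(20, size=int(rng.integers(0, max_mut + 1)), replace=False):
                chars[p] = "ACGT"[int(rng.integers(0, 4))]
            site = "".join(chars) + w[20] + pam_tail
        if "N" not in site:
            cands.append(make_candidate(site))
    return cands


class TestBuildIndex:
    def test_single_forced_site(self):
        g = [NucleotideSequence("g1", "GTTTTTTTTTTTTTTTTTTTTGG")]
        idx = build_index(g, RunConfig())
        assert idx.n_sites == 1
        assert idx.site_counts() == {"g1": 1}

    def test_all_a_contig_no_sites(self):
        g = [NucleotideSequence("g1", "A" * 100)]
        idx = build_index(g, RunConfig())
        assert idx.n_sites == 0

    def test_empty_genome_error(self):
        with pytest.raises(ValueError, match="empty genome"):
            build_index([], RunConfig())

    def test_n_windows_excluded(self):
        g = [NucleotideSequence("g1", "GTTTTTTTTTNTTTTTTTTTTGG")]
        assert build_index(g, RunConfig()).n_sites == 0

    def test_seed7_site_count_matches_frozen_oracle(self):
        genome = seed7_genome()
        idx = build_index(genome, RunConfig())
        assert idx.n_sites == SEED7_SITE_COUNT
        # re-derive with an in-test naive scan
        naive = 0
        for contig in genome:
            s = contig.residues
            for i in range(len(s) - 22):
                w = s[i : i + 23]
                naive += (w[21:23] == "GG") + (reverse_complement(w)[21:23] == "GG")
        assert naive == SEED7_SITE_COUNT

    def test_nag_reverse_pattern(self):
        # forward CTN start = reverse-strand NAG site
        g = [NucleotideSequence("g1", "CT" + "A" * 21)]
        idx = build_index(g, RunConfig(pam_rule="NAG"))
        assert idx.n_sites == 1


class TestFindHits:
    def test_self_hit_on_planted_candidate(self):
        rng = np.random.default_rng(0)
        site = "G" + random_residues(rng, 16) + "TTT" + "AGG"
        genome = [NucleotideSequence("g1", random_residues(rng, 500) + site + random_residues(rng, 500))]
        cand = make_candidate(site)
        hits = find_hits(build_index(genome, RunConfig()), cand, RunConfig())
        assert [h for h in hits if h.protospacer_mismatches == 0] == [hits[0]]
        assert hits[0].start == 501 and hits[0].strand == "+" and hits[0].seed_exact

    def test_seed_exact_site_beyond_ceiling_returned(self):
        rng = np.random.default_rng(1)
        site = "G" + random_residues(rng, 19) + "TGG"
        chars = list(site)
        for p in (2, 4, 6):  # protospacer positions 2,4,6 -> outside the seed
            chars[p - 1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[chars[p - 1]]
        mutated = "".join(chars)
        genome = [NucleotideSequence("g1", site + "T" * 50 + mutated)]
        cfg = RunConfig(max_mismatch=2)
        hits = find_hits(build_index(genome, cfg), make_candidate(site), cfg)
        assert len(hits) == 2
        assert (hits[0].protospacer_mismatches, hits[0].seed_exact) == (0, True)
        assert (hits[1].protospacer_mismatches, hits[1].seed_exact) == (3, True)

    def test_pam_rule_mismatch_rejected(self):
        genome = [NucleotideSequence("g1", "A" * 100)]
        idx = build_index(genome, RunConfig(pam_rule="NGG"))
        with pytest.raises(ValueError, match="PAM"):
            find_hits(idx, make_candidate("G" * 20 + "TGG"), RunConfig(pam_rule="NAG"))

    def test_max_mismatch_beyond_index_capacity_rejected(self):
        genome = [NucleotideSequence("g1", "A" * 100)]
        idx = build_index(genome, RunConfig(max_mismatch=2))
        with pytest.raises(ValueError, match="completeness"):
            find_hits(idx, make_candidate("G" * 20 + "TGG"), RunConfig(max_mismatch=3))

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_oracle_equivalence(self, seed):
        genome = list(get_random_genome(seed, n_contigs=2, length=4000))
        rng = np.random.default_rng(seed + 1000)
        cfg = RunConfig(max_mismatch=2)
        idx = build_index(genome, cfg)
        for cand in sample_candidates(genome, rng, 12):
            assert find_hits(idx, cand, cfg) == brute_force_hits(genome, cand, cfg)

    def test_monotone_in_max_mismatch(self):
        genome = list(get_random_genome(5, n_contigs=1, length=5000))
        rng = np.random.default_rng(50)
        idx = build_index(genome, RunConfig(max_mismatch=3))
        for cand in sample_candidates(genome, rng, 5):
            counts = [
                len(find_hits(idx, cand, RunConfig(max_mismatch=k)))
                for k in (0, 1, 2, 3)
            ]
            assert counts == sorted(counts)

    def test_self_consistency_query_substring(self):
        genome = list(get_random_genome(8, n_contigs=1, length=3000))
        cfg = RunConfig()
        idx = build_index(genome, cfg)
        s = genome[0].residues
        found = 0
        for i in range(len(s) - 22):
            w = s[i : i + 23]
            if w[21:23] == "GG":
                hits = find_hits(idx, make_candidate(w), cfg)
                assert any(
                    h.start == i + 1 and h.strand == "+" and h.protospacer_mismatches == 0
                    for h in hits
                )
                found += 1
                if found >= 25:
                    break
        assert found >= 25


class TestBruteForce:
    def test_absent_seed_empty(self):
        genome = [NucleotideSequence("g1", "A" * 200)]
        cand = make_candidate("G" * 20 + "TGG")
        assert brute_force_hits(genome, cand, RunConfig()) == []

    def test_identity_genome(self):
        site = "GACGTACGTACGTACGTACG" + "TGG"
        genome = [NucleotideSequence("g1", site)]
        hits = brute_force_hits(genome, make_candidate(site), RunConfig())
        assert len(hits) == 1
        assert hits[0].protospacer_mismatches == 0 and hits[0].seed_exact
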
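# crispex

Library + CLI for designing CRISPR/Cas9 target sites with genome-wide
specificity filtering and restriction-site annotation for PCR–digest (RFLP)
mutant screening.

Given query gene/exon sequences (FASTA) and a background genome or
transcriptome (FASTA, assembled or not), crispex:

1. enumerates every 23-nt candidate (20-nt protospacer + 3-nt PAM) on both
   strands, under a configurable PAM rule (`NGG` or `NAG`) and start-base
   rule (`G` or any base `N`);
2. searches the whole background for off-target occurrences of each
   candidate using a PAM-anchored, bit-packed index (with an independent
   brute-force oracle used to verify it in the test suite);
3. applies two specificity filters — level 1: no second genomic site within
   the protospacer mismatch ceiling (default 2); level 2: no second genomic
   site reproducing the 15-base seed (12 PAM-proximal protospacer bases +
   PAM) exactly. Candidates passing both are *potential* Cas9 targets.
   The candidate's own locus is the one permitted hit, so the same
   thresholds work for queries absent from the background (e.g. plasmids);
4. scans each candidate 23-mer against a restriction-enzyme table
   (user-editable CSV; a default table of common commercial 6-cutters is
   built in) and flags recognition sites overlapping the predicted blunt
   cleavage position 3–4 bases upstream of the PAM — losing such a site is a
   convenient screen for induced mutations;
5. writes a per-target CSV report and per-gene summary statistics
   (candidates, potential targets, percent efficiency, corpus-level
   percentages of genes with ≥1 potential target and with a cleavage-site
   enzyme).

## CLI

```sh
crispex --query genes.fasta --genome genome.fasta \
        --pam NGG --start N --max-mm 2 \
        [--enzymes enzymes.csv] [--out report.csv] [--summary summary.csv] \
        [--potential-only] [--log-level INFO]
```

Exit code 0 on success; any validation problem produces a one-line
diagnostic and a non-zero exit. Logging goes to standard error.

The report columns are
`target_label,sequence,strand,check1,check2,potential,restriction_sites,cleavage_site_enzymes`
with `target_label = <query_id>_<start>_<stop>` (1-based inclusive
coordinates on the query's forward strand). Restriction matches are encoded
`name@start-end(strand)` and joined with `;` (`NA` when empty). Output is
deterministic and byte-stable across runs.

The enzyme table is a two-column CSV (`name,site`, `#` comments allowed)
with IUPAC-degenerate recognition sites.

## Library

```python
from crispex import (
    read_fasta, RunConfig, enumerate_candidates,
    build_index, find_hits, brute_force_hits,
    classify, annotate, run_pipeline,
)
```

`crispex.fixtures` generates deterministic synthetic genomes with planted
structures (unique targets, duplicates, near-miss off-targets, seed-exact
decoys, cleavage-site enzymes) whose expected outcomes are verified against
the brute-force oracle during generation — these power the test suite and
double as CLI example inputs via `crispex.fixtures.save_fixture`.

## Notes & limitations

- The filter reading is the *specificity* one: a candidate fails when a
  second site exists within the mismatch ceiling (level 1) or with an exact
  seed (level 2). Multi-copy genes therefore legitimately fail both filters.
- Mismatches are counted over the 20-nt protospacer only; the PAM gates
  validity (positions 2–3 must match the rule; position 1 is a wildcard) and
  off-target sites must carry the same PAM rule as the run.
- Windows containing `N` are excluded on both the query and genome side;
  contigs are scanned independently, so sites spanning contig boundaries do
  not exist.
- No on-target activity scoring and no bulge/indel off-targets — filtering
  is pure Hamming counting by design.
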
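# guidefinder

CRISPR/Cas9 sgRNA target-site prediction and off-target evaluation as a
library and CLI. From a query DNA sequence, `guidefinder`:

1. **discovers** candidate sgRNA target sites on both strands (pattern such
   as `N20NGG`, optional 5'/3' dinucleotide constraints),
2. **enumerates** genome-wide off-target sites under a core/total mismatch
   model (defaults: PAM-proximal 12-bp core with at most 2 mismatches, at
   most 4 mismatches overall, valid NGG or NRG PAM) using an exact
   pigeonhole seed index, with an independent brute-force oracle engine,
3. **annotates** each off-target with its closest exon (within 100 kb;
   exonic / intronic / intergenic),
4. **scores and ranks** candidates — per-off-target positional mismatch
   score `sum(1.2**pos)` and a per-site aggregate combining exon distance,
   mismatch distribution and off-target count,
5. **designs** cloning oligo pairs for the DR274 sgRNA vector, fixing the
   5' end to GG for T7 transcription (lowercase `g` marks added or
   substituted bases).

A deterministic synthetic-genome simulator (`guidefinder.simulate`) plants
on-/off-target sites with chosen mismatch configurations plus exon
annotations and a truth table, so the whole pipeline is testable without
reference-genome downloads.

## CLI

```sh
# candidate sites in a query (FASTA file or raw sequence)
guidefinder discover --query query.fa --pattern N20NGG

# off-targets of one protospacer against a multi-FASTA genome
guidefinder search --protospacer GGCGAGGGCGATGCCACCTA --genome genome.fa --ot-pam NRG

# full pipeline: discovery -> search -> exon annotation -> ranking -> oligos
guidefinder run --query query.fa --genome genome.fa --exon-bed exons.bed \
    --core-length 12 --core-mm 2 --total-mm 4 --out-dir out
# writes out/candidates.fasta, out/results.tsv, out/track.bed

# cloning oligo pair for one protospacer
guidefinder oligos --protospacer GCATTTGTCAATGGATACCC --gg-mode extension

# synthetic genome with planted sites + truth table + exon BED
guidefinder simulate --seed 2 --chrom-length 5000 --plants-json plants.json --out-dir sim
```

Options mirror the `PatternConfig` fields and may also come from a flat
YAML file (`--config run.yaml`); command-line flags override file values.

Formats: query and genome are FASTA (or a raw sequence string for the
query); exons are BED with >= 4 columns, the name field carrying
`gene_name|gene_id`; `results.tsv` uses 1-based inclusive coordinates and
lowercases mismatched bases in off-target sequences; `track.bed` is a
standard BED6 custom track (0-based half-open) with rank scores rescaled
to 0–1000.

## Library

```python
from guidefinder import (PatternConfig, find_candidate_sites,
                         search_off_targets, brute_force_search,
                         load_exons, closest_exon, design_oligos,
                         run_pipeline)

cfg = PatternConfig(offtarget_pam="NRG")
sites = find_candidate_sites("...ACGT...", cfg)
hits = search_off_targets(sites[0], genome_dict, cfg)
```

## Tests and acceptance report

```sh
python -m pytest -q tests/          # unit + property + acceptance suites
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(published oligo pairs byte-exact, formula worked examples, seed-vs-brute
oracle equivalence over 100 random 50-kb genomes, planted-site recovery,
score monotonicity, end-to-end determinism). `scripts/acceptance.py`
re-runs the pipeline end to end on a seeded synthetic instance and writes
the (empty — no offline-reproducible numeric targets exist) JSON report.
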
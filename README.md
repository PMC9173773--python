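# phagescreen

Analysis pipeline for phage-display screens of small scaffold-protein
libraries, plus the supporting numerics for characterizing selected binders:

- **library_design** — scaffold templates with randomized positions (built-in
  `loop`: 7 positions, `side`: 6 positions, both over 19 amino acids with
  cysteine excluded), exact theoretical diversity, full variant-protein
  reconstruction, codon designs with the amber codon (TAG) reassigned to Gln,
  and PCR amplicon location.
- **read_qc** — FASTQ filter cascade: undetermined (N) bases, per-base Phred
  threshold (default ≥ 21), in-frame stop codons (TAA/TGA; TAG translates to
  Q), sense-strand orientation via DNA flank markers, flank / constant-region
  checks, and variable-region translation.
- **enrichment** — deterministic ranked variant tables, per-selection summary
  (top frequency, number of sequences above a read-count threshold), top-N
  extraction, Venn region counts across 2–4 selections, and naive-library QC
  (unique-read fraction, per-position amino-acid frequencies).
- **alignment** — ungapped position-wise peptide scoring with a configurable
  integer similarity matrix (0–9, identity 9; a group-structured default is
  shipped as TSV), all-vs-all scoring, seed-centric cutoff clustering, and
  frequency / information-content (bits) logo matrices.
- **synthetic_data** — a panning simulator: uniform naive libraries,
  affinity-weighted multi-round selection (softmax over motif scores with
  multinomial resampling), sequencing errors with degraded qualities, mixed
  read orientation; fully seeded and reproducible.
- **kinetics** — two-moment aggregation rate equations (primary nucleation,
  secondary nucleation, elongation) integrated numerically; global fits with
  a selective per-concentration reduction factor on one rate constant;
  model selection across the three inhibition modes; seeded-assay simulation.
- **spectroscopy** — FRET transfer efficiency `E = (I0 − I)/I0` and cubic
  hydrodynamic-radius → molecular-weight scaling.

## CLI

All functionality is exposed through one `phagescreen` entry point:

```sh
phagescreen design diversity -t loop            # 893871739
phagescreen design build -t loop -v YLTIRLM     # FASTA of the full protein
phagescreen simulate -t loop --rounds 3 --seed 17 --out-dir sim/
phagescreen qc sim/round_3.fastq -t loop --out-peptides peps.tsv --out-report qc.json
phagescreen count peps.tsv -o counts.tsv
phagescreen summary counts.tsv --min-reads 100
phagescreen venn counts_a.tsv counts_b.tsv
phagescreen cluster counts.tsv -s YLTIRLM -c 30 -o cluster.tsv
phagescreen logo cluster.tsv --out-prefix logo
phagescreen matrix-export -o matrix.tsv         # default similarity matrix
phagescreen kinfit -i traces.csv --mode all     # rank inhibition modes
phagescreen fret fret.csv
phagescreen mds-mw --rh-ratio 3
```

Trace CSVs for `kinfit` have columns
`time_h, signal, monomer_uM, inhibitor_uM, seed_fraction`; a zero-inhibitor
trace is required and rate constants are shared globally across traces.

## Notes

- The default similarity matrix is a documented stand-in (identity 9, same
  physicochemical group 6, related groups 3, otherwise 0); replace it with
  `--matrix your.tsv` anywhere a matrix is used. Cluster outputs record the
  matrix checksum.
- Default codon design uses one common E. coli codon per amino acid plus TAG
  as an extra Gln codon; no cysteine codon, no TAA/TGA. Override via
  `CodonDesign`.
- Scaffold templates are JSON-configurable (`name`, `constant_sequence`
  with `X` placeholders, `alphabet`, optional DNA flanks).
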
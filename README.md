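# surfmut

Mutation-guided surface-protein target selection: from somatic missense
variant tables to residue-level surface localization, mutated-surface-protein
(MSP) calls, immunogenic mutant/wild-type peptide-pair design, oligoclonal
panel selection, and cohort-level prevalence and sharing statistics. A
synthetic proteome+cohort generator with recorded ground truth makes every
stage testable offline.

## Pipeline stages

| Module | What it does |
|---|---|
| `surfmut.variant_io` | Read MAF-dialect TSVs, parse HGVS p. protein changes, filter to missense with a machine-readable rejection log |
| `surfmut.annotation_store` | JSON store of annotated proteins (sequence, topology features, subcellular-location labels), one canonical record per gene |
| `surfmut.msp_classifier` | Residue-level location lookup with overlap precedence, MSP calling (extracellular residue OR secreted protein, signal peptides excluded), compartment tallies |
| `surfmut.peptide_design` | Mutant/wild-type 14-mer windows with a C-terminal cysteine conjugation tag, single-substitution validation, deterministic n-target panel selection, FASTA export |
| `surfmut.cohort_stats` | Per-patient burden summaries (linear-interpolation quartiles), threshold prevalence, inter-patient sharing spectrum, caliper tumor-volume utility |
| `surfmut.synthetic_data` | Deterministic toy proteomes and somatic cohorts with injected (not sampled) sharing plans and complete ground truth |
| `surfmut.cli` | `surfmut` command wiring it all together |

## CLI

Each stage is independently exercisable:

```sh
surfmut simulate-proteome --n-proteins 60 --seed 7 --out-store store.json
surfmut simulate-cohort --store store.json --n-patients 100 --seed 7 --out-maf cohort.maf
surfmut classify --maf cohort.maf --store store.json --outdir out/
surfmut tally --maf cohort.maf --store store.json --mode overlapping
surfmut select --maf cohort.maf --store store.json --n 10 --outdir out/
surfmut cohort-stats --maf cohort.maf --store store.json --outdir out/
surfmut validate-pairs            # checks the bundled golden peptide pairs
surfmut run --maf cohort.maf --store store.json --outdir out/ --seed 7
```

`surfmut run` executes read → classify → tally → select → cohort-stats and
writes a `manifest.json` with stage counts, the seed, and a config echo
sufficient to rerun identically. Configuration can also come from a YAML
file (`--config`); explicit flags win. Exit codes: 0 success, 2 panel
shortfall, 1 hard error.

## Notes on conventions

- All residue coordinates are 1-based inclusive.
- Classification labels accepted as missense (case-insensitive):
  `Missense_Mutation`, `missense_variant`, `missense`.
- Percentages are rounded half-up (one decimal in tallies, three in
  sharing reports).
- Sharing keys are protein-level: (gene, position, ref, alt).
- The default peptide window length is 14 residues; window length and
  placement policy are parameters of `design_window`.
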
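# mrnadecay

A tested pipeline for massively parallel mRNA decay measurements in
bacteria: simulate a barcoded transcription-shutoff (rifampicin-chase style)
experiment, count barcoded reads, estimate per-variant decay constants with
spike-in normalization, compute isoform-aware biophysical features of
5' UTRs, train staged gradient-boosted models of mRNA levels and decay
rates, and extract design rules by systematic model queries.

## Layout

| module | what it does |
| --- | --- |
| `mrnadecay.synthetic_data` | design libraries (full-factorial 4-nt 5'-end site x RBS groups, structure series, G-quadruplex / i-motif, motif insertions, RBS sweeps), Hamming-separated barcodes, ground-truth decay constants, multinomial read sampling with a constant-mass spike-in, FASTQ emission |
| `mrnadecay.barcodes` | hash-based barcode index (exact + all Hamming-1 mutants), FASTQ counting with single-mismatch tolerance |
| `mrnadecay.kinetics` | spike-in normalization `R_i = (N_i/N_0)/(C_i/C_0)`, single-parameter exponential fits `M(t)=e^{-kt}`, half-lives, Pearson-R² fit quality, read-depth/fit QC, ln(RNA/DNA) level outcomes |
| `mrnadecay.features` | quadruplex/i-motif pattern detection, IUPAC motif counting, a self-contained DP secondary-structure folder, hairpin/loop/bulge/ssRNA anatomy, surrogate + designed transcription/translation providers, a versioned 496-column feature schema |
| `mrnadecay.model` | group-stratified train/test splitting (largest remainder), five per-timepoint level models + a decay model on level-augmented features, evaluation, importance pruning, isoform ablation |
| `mrnadecay.rules` | 4-mer/TIR/ssRNA/dsRNA sweeps (feature-space and sequence-built), plateau detection, multi-factor stratified correlations, tertiary-vs-secondary comparisons |
| `mrnadecay.pipeline` | YAML config, per-stage seed derivation, end-to-end orchestration with a manifest, external count-table loading |

## CLI

```bash
mrnadecay simulate --seed 1 --outdir run --scale 0.3     # library + truth + counts
mrnadecay count run/fastq --library run/library.tsv      # FASTQ -> counts TSV
mrnadecay fit run/counts.tsv --outdir run                # normalize + fit + QC
mrnadecay train --seed 1 --outdir run                    # simulate->fit->featurize->train
mrnadecay sweep --seed 1 --outdir run                    # + design-rule sweeps
mrnadecay run-all --config config.yaml                   # everything, from one config
```

Each run directory contains TSV/JSON artifacts per stage plus
`manifest.json` (config hash, derived seeds, row counts). Reruns with the
same config are bit-identical; model training is pinned to a single thread
so results reproduce across machines.

## Notes on scope

- The built-in folding provider is a weighted base-pair-maximization DP
  (lone pairs removed, minimum hairpin loop 3); a thermodynamic MFE folder
  can be plugged in through the same `fold(seq, blocked=...)` interface.
- Transcription/translation rate calculators are provider interfaces: the
  surrogate scorers are documented simplifications, and synthetic runs use
  design-time lookup providers.
- The boosted-tree backend is scikit-learn's histogram gradient booster
  behind a thin deterministic regressor interface; any gradient-boosted
  tree implementation can be substituted.
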
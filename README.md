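# appm

Antigen-presentation prediction for HLA class I peptides (8–11mers), built
around a mass-spectrometry elution view of presentation rather than in-vitro
binding affinity. The package provides:

- **`appm.codec`** — fixed-shape one-hot encoding: every peptide becomes an
  11×21 binary matrix (20 residues `ACDEFGHIKLMNPQRSTVWY` + pad `Z`,
  suffix-padded; column order fixed and bit-stable).
- **`appm.sampling`** — class rebalancing (random under-sampling of decoys,
  duplication over-sampling of hits) and stratified train/validation/test
  splitting; ships a packaged per-allele training-summary fixture
  (`appm.sampling.load_table1`).
- **`appm.cnn`** — an inception-style convolutional classifier implemented in
  pure NumPy: three parallel conv branches (8 kernels each, heights 2/3/4
  spanning all 21 columns, Leaky ReLU α=0.2), a 100-unit dense layer with
  dropout, a 2-node softmax; Adam training with early stopping on validation
  loss; percentile-rank scoring against a background population.
- **`appm.benchmark`** — hit/decoy benchmark construction (99 decoys per hit
  from the hit's source protein, balanced 25/25/25/24 across lengths 8–11,
  training-overlap and duplicate filtering), sensitivity/specificity/PPV,
  top-2%-rank binder calls, and the two-predictor intersection ensemble.
- **`appm.motif`** — position frequency matrices, information-content anchor
  detection, amino-acid property-class profiles, motif similarity.
- **`appm.neoantigen`** — sliding-window extraction of mutation-spanning 8–11mer
  candidates from driver missense mutations (per-length mutant-centered
  contexts, clipped at protein termini), allele-panel scoring, and cohort
  frequency annotation.
- **`appm.synthetic`** — seeded generators for motif-governed labeled peptide
  sets, toy proteomes with designated hits, mutation tables and external rank
  tables, so the whole pipeline is testable offline.

## CLI

```bash
appm synth --out data/ --n-positives 500 --imbalance 39 --seed 1
appm train --data data/dataset.csv --allele 'A*02:01' \
     --under 0.7 --over 5 --test-count 2000 --seed 1 --out model/
appm predict --model model/ --in peptides.csv --out scores.csv
appm benchmark --hits data/hits.csv --proteome data/proteome.fasta \
     --train-exclude train.csv --out bench.csv
appm evaluate --bench bench.csv --calls-a a.csv --calls-b b.csv --combine \
     --out report.json
appm motif --in positives.csv --length 9 --out pfm.csv
appm neoantigen --mutations data/mutations.csv --proteome data/proteome.fasta \
     --model model/ --out candidates.csv
```

Other subcommands: `encode`, `rebalance`, `split`, `combine`. Every run writes
a `run_manifest.json` (inputs, seed, config hash, versions) next to its
outputs; logs go to stderr.

## Conventions

- Peptide sequences are upper-cased on input; lengths outside 8–11 or letters
  outside the 20-residue alphabet are validation errors.
- Protein coordinates and window offsets are 1-based; decoy/benchmark offsets
  into proteins are 0-based (documented per field).
- External predictor scores are consumed as CSV
  (`peptide,allele,score,percentile_rank`); the external tool is never invoked.
- All randomness flows through explicit integer seeds; rerunning with the same
  seed reproduces outputs byte-for-byte.
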
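# rna5hmc

Sequence-based prediction of RNA 5-hydroxymethylcytosine (5hmC) sites from
41-nt windows with a centered candidate cytosine.

The pipeline:

1. **Encoding** — each window becomes 244 named features: a per-position
   one-hot binary code (41 × 4 = 164; A=0001, U=0010, C=0100, G=1000),
   the 2-mer spectrum (16), and the 3-mer spectrum (64).
2. **Feature optimization** — one-way ANOVA F-values rank the features;
   a sequential forward search over nested ranking prefixes (default
   step 10, optional step-1 refinement) keeps the prefix with the best
   cross-validated accuracy.
3. **Classification** — an RBF-kernel SVM with (C, γ) grid-searched over
   integer powers of two (log2 C ∈ −2..5, log2 γ ∈ −5..2), producing
   probability-like scores thresholded at 0.5 (strictly greater ⇒ positive).
4. **Evaluation** — stratified five-fold cross-validation reporting Sn, Sp,
   ACC, MCC per fold and averaged, plus pooled ROC/PR curves and AUC, and a
   per-position nucleotide-enrichment table.

A seeded synthetic-data module generates labeled datasets with controllable
compositional (G/GGG) and positional signal, so the whole pipeline is
exercisable and testable without any external dataset.

## CLI

```bash
# generate a synthetic dataset (presets: null_small, strong_kmer,
# positional_only, mixed)
rna5hmc simulate --preset strong_kmer --seed 7 -o out/sim

# train: encode -> ANOVA rank -> SFS -> grid search -> final fit
rna5hmc train --pos out/sim/positives.fasta --neg out/sim/negatives.fasta \
    --seed 7 -o out/model

# score unlabeled windows (strict > threshold rule, default 0.5)
rna5hmc predict --model out/model/model.joblib --fasta query.fasta -o out/pred

# five-fold cross-validated report; --nested reruns feature selection inside
# each training fold (statistically sound; the default replicates the
# original protocol, which selects features on the full dataset first)
rna5hmc evaluate --pos out/sim/positives.fasta --neg out/sim/negatives.fasta \
    --seed 7 -o out/eval --plots
```

Every command writes `run_config.json` next to its outputs; all randomness
flows from `--seed`. Options can also be supplied via `--config file.yaml`
(same names as the flags).

Inputs are FASTA (T is silently mapped to U; ambiguity codes are rejected).
Labels come either from a positives/negatives file pair or from a two-column
TSV (`id<TAB>0|1`, see `rna5hmc.sequence_io.load_with_label_table`).

## Layout

```
src/rna5hmc/
  sequence_io.py        FASTA I/O, window validation, labeled datasets
  feature_encoding.py   binary + k-mer spectrum encoding, feature matrices
  feature_selection.py  ANOVA F-values, ranking, sequential forward search
  model.py              RBF-SVM, grid search, calibration, persistence
  evaluation.py         metrics, stratified CV, ROC/PR/AUC, enrichment
  synthetic_data.py     seeded dataset generators and presets
  cli.py                command-line interface
```
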
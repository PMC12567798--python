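# seqtox

Machine-learning toolkit for predicting whether a protein is a toxin from
its amino-acid sequence alone.

Protein toxins — snake three-finger toxins, conotoxins, scorpion
neurotoxins, bacterial pore-formers — are annotated for only a small
fraction of known sequences, and experimental toxicity assays are slow and
expensive. A sequence-based classifier lets venom researchers,
protein-engineering groups and sequencing projects triage candidate
proteins before committing bench time. `seqtox` implements the full
workflow such a predictor needs, as a library of composable stages with a
thin command-line front end:

1. **Sequence cleaning** — FASTA I/O with dataset validity rules: minimum
   length 35 residues, the 20-letter standard alphabet only (records with
   B/J/O/U/X/Z are rejected and logged).
2. **Feature extraction** — 1920 classical descriptors in eight families
   (amino-acid and dipeptide composition; Moreau–Broto, Moran and Geary
   autocorrelation; composition/transition/distribution; conjoint triads;
   sequence-order coupling numbers and quasi-sequence-order; pseudo and
   amphiphilic pseudo amino-acid composition), plus PSSM evolutionary
   profiles compressed by global average pooling
   (GAP_j = (1/L) Σᵢ P_{ij}), six functional residue-group counts with
   sequence length, AAindex physicochemical profiles, and 50 one-hot
   discriminative minimotifs mined from training data.
3. **Negative sampling** — toxin datasets are hugely imbalanced; the
   negative pool is clustered by k-means, the cluster count picked from the
   elbow of the SSE(k) curve (maximum second difference), and a balanced
   negative set drawn with per-cluster quotas proportional to cluster size,
   so rare sequence families stay represented.
4. **Feature selection** — a four-stage cascade: zero-variance removal →
   pairwise Pearson filter (|r| ≥ 0.8 drops the later column) → graphical
   ensemble feature selection (bootstrap gradient-boosted learners vote;
   features are ranked by weighted degree in the co-selection graph) →
   recursive feature elimination with cross-validation, keeping the
   smallest subset within one standard error of the best CV score.
5. **Classification** — XGBoost (default), LightGBM, random forest and SVM
   behind one interface; stratified 20-fold cross-validation (95% / 5%
   splits) with every label-using step (motif mining, ensemble selection,
   RFECV) refit inside each training fold, and an audit log proving no
   validation labels leak; Bayesian (GP + expected improvement)
   hyperparameter search maximizing cross-validated MCC.
6. **Evaluation** — ten balanced measures from confusion counts and
   scores: NPV, PPV, specificity, sensitivity, accuracy, MCC,
   nMCC = (1+MCC)/2, F1, AUC, and the overall performance measure

   ```
   OPM = (NPV+PPV) · (specificity+sensitivity) · (accuracy+nMCC) / 8
   ```

   a single [0, 1] summary that penalizes predictors whose headline
   accuracy hides strong class bias.

A seeded synthetic-data generator (short cysteine-rich toxin-like
positives with planted minimotifs versus diverse background negatives)
makes every stage testable without downloading reference databases.

## Worked example

Evaluating predictors from their blind-test confusion counts
(`examples/06_published_comparison_table.py`):

```python
from seqtox.evaluation import ConfusionCounts, compare_table, format_table

table = compare_table([
    ("final-predictor",      ConfusionCounts(225, 457, 17, 54)),
    ("transformer-baseline", ConfusionCounts(203, 469,  5, 76)),
], n_inputs=753)
print(format_table(table))
```

prints

```
                       NPV   PPV  specificity  sensitivity  accuracy   MCC  nMCC   OPM    F1  coverage
method
final-predictor      0.894 0.930        0.964        0.806     0.906 0.797 0.898 0.728 0.864     1.000
transformer-baseline 0.861 0.976        0.989        0.728     0.892 0.774 0.887 0.701 0.834     1.000
```

The transformer baseline's near-perfect PPV and specificity come with much
weaker NPV and sensitivity — a biased predictor. MCC and OPM rank the
balanced final predictor higher (0.797/0.728 vs 0.774/0.701) even though
raw accuracies are close.

Training end to end on the synthetic benchmark
(`examples/05_train_and_evaluate.py`: 400/400 training, 100/100 held-out)
featurizes with mined motifs and fallback PSSMs, trains XGBoost and prints

```
held-out confusion counts: TP=99 TN=100 FP=0 FN=1
      accuracy = 0.995
           MCC = 0.990
           OPM = 0.985
```

The other `examples/` scripts walk through cleaning/featurization, motif
mining, clustering-based negative sampling and the selection cascade, each
printing what its numbers mean.

## Command line

Each pipeline stage is a subcommand operating on plain files (FASTA in,
TSV/JSON out), entered anywhere in the DAG:

```bash
seqtox simulate --preset tiny --out sim/
seqtox featurize sim/train_pos.fasta --out feat/
seqtox evaluate counts.tsv --out metrics/
```

Every output directory receives a `run_config.json` echo of the arguments,
seed and config hash for provenance.

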
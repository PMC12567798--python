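# Methods

This note records the models, conventions and design choices behind
`seqtox`, in the order the pipeline runs them.

## Sequence validity rules

Records are uppercased and a single terminal `*` stop character is
stripped before validation (UniProt-style FASTA is uppercase, but user
input varies, and the stop character is a common dialect). A record is
rejected — never repaired — if it is shorter than 35 residues or contains
any character outside the 20-letter standard alphabet; ambiguous codes
(B, J, O, U, X, Z) are the usual offenders. Duplicate ids within one file
are an error rather than a silent rename, because downstream label
bookkeeping is keyed by id. Duplicate *sequences* under distinct ids are
kept: redundancy handling is a dataset-curation decision, not an I/O
decision.

## Descriptor families

The eight classical families total 1920 columns at defaults:

| family | dim | parameters |
|---|---|---|
| amino-acid composition | 20 | — |
| dipeptide composition | 400 | overlapping pairs |
| autocorrelation (Moreau–Broto, Moran, Geary) | 3 × 240 | 8 physicochemical indices × 30 lags |
| CTD | 147 | 7 three-class encodings; 21 + 21 + 105 |
| conjoint triad | 343 | 7 residue classes |
| sequence order (SOCN + QSO) | 60 + 100 | 2 distance matrices × 30 lags, weight w = 0.1 |
| PAAC | 50 | λ = 30, w = 0.05 |
| APAAC | 80 | λ = 30, w = 0.05 |

Conventions that needed a decision:

- **Autocorrelation.** Property scales are standardized over the alphabet
  before the lagged sums. The three methods share per-index names, so
  matrix columns carry `mb.`/`moran.`/`geary.` prefixes; the packaged
  selected-feature manifest stores (family, name) pairs and resolves
  through these prefixes. Moran and Geary are defined as 0 when the
  profile along the sequence is constant (denominator below 1e-12): the
  alternative, NaN, would poison every downstream matrix, and constant
  columns are removed by selection anyway.
- **CTD distribution** reports the percent position (1-based, ×100/L) of
  the 1st, 25%, 50%, 75% and last occurrence of each class, with
  `round()` for the interior quantile indices and all five values 0 for an
  absent class.
- **Conjoint triads** are relative frequencies, count/(L−2). Some
  descriptor libraries instead rescale by (f−min)/max per sequence; the
  frequency convention is simpler, exactly linear in window counts, and is
  recorded in `DescriptorConfig.ctriad_convention` for auditability.
- **Sequence-order distance matrices.** The Grantham matrix is rebuilt
  from the 1974 formula and property table (α = 1.833, β = 0.1018,
  γ = 0.000399, mean off-diagonal distance normalized to 100); eight
  published cell values were checked against the reconstruction and match
  to rounding. The Schneider–Wrede-style matrix follows that
  construction's recipe — Euclidean distance over standardized
  hydrophobicity, hydrophilicity and side-chain volume, rescaled to
  max 1 — rather than a transcription of the original table.
- **AAindex profiles** pool each index as the mean value over the
  sequence's residues. The family's size is data-driven: whatever usable
  records the supplied AAindex1 flat file contains (records with `NA`
  residues are skipped). The bundled
  `data/aaindex1_synthetic_subset.txt` is a labelled synthetic stand-in —
  real accession ids with representative, reconstructed values — shipped
  so the default configuration and the packaged feature manifest resolve
  offline; analyses that depend on faithful physicochemical values should
  point `DescriptorConfig.aaindex_path` at a genuine AAindex1 file.
- **Sequence length** enters raw, not normalized; any scaling belongs to
  the model pipeline, and gradient-boosted trees are scale-invariant.

## PSSM features

A PSSM is the L×20 log-odds block of `psiblast -out_ascii_pssm` output
(the first 20 numeric columns; the second block of weighted percentages is
ignored). Global average pooling compresses it to 20 features named
`PSSM_A` … `PSSM_Y` in alphabetical residue order, mapped from
PSI-BLAST's native column order. Three providers exist: a live `psiblast`
wrapper (E-value 0.001, 3 iterations by default), a directory of
precomputed ASCII matrices keyed by sequence id, and a deterministic
fallback that stacks BLOSUM62 substitution rows per residue. The fallback
is homology-free — it encodes residue identity smoothed by substitution
preferences, not evolutionary conservation — and is flagged
`source="fallback"` so results can state their provenance. Synthetic
benchmarks use it throughout.

## Minimotifs

Motifs are literal substrings, length 3–6 by default, present in ≥ 1
positive and 0 negatives of the *training* data, ranked by positive
coverage (ties: shorter first, then lexicographic), top 50 kept, encoded
as binary presence flags. Degenerate physicochemical-class motifs and
gapped patterns are out of scope: the downstream contract is just 50
binary columns, and literal mining keeps that contract exactly testable
(the all-zero-on-training-negatives invariant is asserted in tests).
Because mining reads labels, it runs inside each cross-validation
training fold.

## Negative sampling

Features are z-scored before clustering so heterogeneous descriptor
scales do not dominate the Euclidean SSE. k-means runs best-of-10
restarts per k; the elbow of SSE(k) is automated as the interior k
maximizing the second difference SSE(k−1) − 2·SSE(k) + SSE(k+1) (ties →
smallest k), with the curve exported for manual inspection. Per-cluster
quotas are proportional to cluster size with largest-remainder rounding
and a minimum of one per non-empty cluster — the point of
clustering-based sampling is that rare clusters contribute at all —
and draws within a cluster are uniform without replacement, seeded.

## Feature-selection cascade

Stage order: zero-variance removal; greedy Pearson filter; graphical
ensemble feature selection (GEFS); RFECV.

- The Pearson filter scans columns in fixed order and drops the later
  member of any pair with **|r|** ≥ 0.8 (absolute value: an inverted copy
  of a feature carries the same information). Keeping the earlier column
  makes the outcome deterministic; the report records the partner and the
  correlation for every dropped column.
- GEFS trains 20 LightGBM members on bootstrap row-resamples; each
  nominates its top 50 features by gain importance; co-selection edge
  weights count members nominating both endpoints; features are ranked by
  weighted degree (ties: nomination count, then name) and the top 100
  survive. Member count and nomination size are stability/runtime
  trade-offs and are configurable.
- RFECV eliminates one feature per step (refitting importances each
  step), scores every subset size by stratified k-fold accuracy
  (default 5 folds), and returns the *smallest* subset within one
  standard error of the best mean score. The 1-SE rule is a reproducible
  parsimony criterion; its known consequence is that **mutually redundant
  informative features are legitimately pruned** — if three of five
  informative columns give statistically indistinguishable accuracy, the
  rule keeps three. Recovery experiments that require all informative
  features retained must plant complementary (non-redundant) signal; the
  test suite's generator labels samples by a majority vote of five latent
  bits with one feature per bit.
- Every stage appends to a `SelectionReport`; the identity
  in − dropped = out is enforced at stage boundaries, and the final list
  chains from the original columns.

The packaged 88-feature manifest (`data/selected_features_manifest.tsv`)
lets users bypass selection and reproduce a published feature space by
name; `resolve_manifest` maps its (family, name) pairs onto matrix
columns.

## Classifier and cross-validation

Four algorithms sit behind string ids: `xgboost` (default), `lightgbm`,
`random-forest`, `svm` (the SVM is wrapped with a standard scaler —
kernels need comparable feature scales; trees do not). All run
single-threaded with explicit seeds for determinism. The decision
threshold is 0.5 with ≥ on the boundary, configurable for screening uses
that prefer recall.

`cross_validate` uses stratified k-fold (default 20 folds ⇒ 95%/5%
splits). Because fold-averaged metrics and metrics of fold-averaged
counts differ in the third decimal, both are reported (`metrics` —
means of per-fold metrics, the convention of fold-averaged result
tables — and `metrics_of_mean_counts`). `run_nested_cv` refits motif
mining, the correlation stages, GEFS and RFECV inside every training
fold and logs, per fold and stage, exactly the sample ids whose labels
the stage received; the leakage test asserts these sets are disjoint
from every validation fold.

Hyperparameter search is sequential model-based optimization: random
initial design, Matern-5/2 Gaussian-process surrogate on the unit-scaled
space (log scaling where declared), expected-improvement acquisition over
256 random candidates, objective = mean CV MCC. Default space: trees
100–2000, depth 3–10, learning rate 1e-3–0.3 (log), subsample and column
subsample 0.5–1, min child weight 1–10, budget 50. The full evaluation
trace is returned and archived.

Persistence covers the gradient-boosting families only, as
`meta.json` + the library's own text model dump — no pickled Python
objects. The kernel/forest models are comparison baselines, not
deployment targets.

## Evaluation conventions

All ratios with a 0/0 form (PPV with no positive predictions, etc.)
return 0 and are listed in the report's `undefined` field; MCC with a
zero denominator is 0. This keeps OPM defined for degenerate predictors
while flagging the degeneracy. Confusion counts are accepted as reals so
fold-averaged tables evaluate exactly like integer ones. AUC is computed
as the normalized Mann–Whitney rank statistic (ties count ½), which is
the exact area under the ROC curve. Display rounding is half-up to three
decimals, matching the convention of printed comparison tables.

## Synthetic data

The generator emulates the *shape* of real toxin data: positives are
shorter (lognormal length, median ≈ 74 vs ≈ 164 residues, minimum 35),
cysteine-enriched (3× background frequency by default — disulfide-rich
toxin scaffolds), carry each of six planted minimotifs with probability
0.6, and have a mild CC-dipeptide bias; negatives follow background
proteome frequencies and are post-scanned so no planted motif survives in
them. Signal is multi-channel (composition, motifs, dipeptides) so
recovery tests can attribute information to descriptor families.

What it does **not** emulate: homology structure, real evolutionary
profiles (the PSSM fallback is substitution-based), domain architecture,
or the long tail of real negative diversity. Passing the end-to-end
benchmark therefore demonstrates that the pipeline machinery is sound
and leak-free at desk scale — not that the measured accuracy transfers
to UniProt-scale training, which requires the real datasets and a
psiblast database. Benchmark presets: `tiny` (20/20), `default`
(400/400 train, 100/100 test), `imbalanced` (200/6000).

## Problem sizes used by the test suite

Chosen as the package's own desk-scale defaults: the end-to-end check
uses the `default` preset (800 training, 200 held-out sequences, ~2000
features, GEFS with 10 members); selection-recovery experiments use
n = 300 samples with 5 complementary informative features among 50–100
noise columns, 20 seeded repetitions; the exhaustive descriptor oracle
covers all 2046 sequences of length ≤ 10 over {A, C} plus 100 random
full-alphabet sequences of length 35–200.

## Known limitations

- The bundled AAindex excerpt is a stand-in (see above); the 88-feature
  manifest resolves against it by accession id, but AAindex *values* in
  default runs are representative, not authoritative.
- Re-deriving a published 88-feature set end-to-end requires the original
  UniProtKB-scale datasets and PSSM database; the cascade here reproduces
  the procedure and its bookkeeping, not those exact features.
- Literal motif mining scales as total substring mass of the corpus;
  for millions of negatives a suffix-automaton implementation would be
  preferable.
- The SVM baseline uses Platt-scaled probabilities, which are poorly
  calibrated on very small training sets.
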
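# Methods

## Classification model

Degradability prediction is a binary classification over fixed-length
per-protein feature vectors. Tree ensembles (random forest, gradient-boosted
trees) are used because the typical regime is a few hundred labeled proteins
against hundreds-to-thousands of features, where bagging/boosting over
shallow trees resists overfitting better than high-capacity alternatives.

Four hyperparameters are tuned — `n_estimators`, `max_depth`,
`min_samples_split`, `min_samples_leaf` — by exhaustive grid search scored
with stratified 5-fold CV mean ROC-AUC. Default candidate grids
(`modeling.DEFAULT_GRID`): n_estimators {100, 200, 500}, max_depth {None, 5,
10, 20}, min_samples_split {2, 5, 10}, min_samples_leaf {1, 2, 4}. Ties are
broken by deterministic enumeration order of the grid so results are
reproducible.

The final model is built by repeated stratified K-fold CV (`n_splits=5`,
`n_repeats=2`), which yields ten fold models, each trained on 80% of the
data and validated on its held-out fifth. The deployment model is a
soft-voting ensemble: the unweighted mean of the ten members' positive-class
probabilities. A consensus mode (positive only when every member clears its
threshold) is provided for combining heterogeneous models, e.g. an RF and a
GBT; its default usage is the two-member agreement rule.

**Prediction convention.** Everywhere (FPR, consensus votes, screening),
a sample is called positive iff its score is ≥ the threshold. This makes
"threshold 0.90, zero false positives" a well-defined, reproducible
statement.

**Threshold calibration.** Each fold's false-positive-rate-vs-threshold
curve is evaluated on a shared lattice {0.00, 0.01, …, 1.00} (folds have
different score supports, so a fixed lattice makes the average
well-defined), the ten curves are averaged, and the calibrated threshold is
the smallest lattice point whose mean FPR is ≤ the target. The curve is
treated as piecewise constant; an unreachable target is an error rather
than an extrapolation.

## Feature spaces

- **Embeddings.** The `Embedder` contract is any deterministic map
  sequence → fixed-length vector. Three implementations: an adapter for an
  external transformer protein language model (optional dependency; mean
  pooling over residue positions by default, cls-token available;
  over-length sequences are split into non-overlapping windows whose
  vectors are averaged — deterministic, no truncation bias); a loader for
  precomputed embedding tables; and the fixture embedder (seeded hashed
  k-mer counts, L1-normalized, BLAKE2b-keyed so bucket assignment is stable
  across processes). The fixture embedder is composition-sensitive — a
  planted motif shifts a handful of buckets — which is exactly what the
  offline tests need, but it carries none of a language model's learned
  structural information.
- **Descriptors.** Six classical families: TPC (8000-dim tripeptide
  frequencies), GTPC (125-dim over 5 physicochemical groups), Geary
  autocorrelation (default `nlag=8` over 8 z-standardized property scales:
  hydropathy, hydrophilicity, polarity, volume, side-chain mass,
  isoelectric point, net charge, accessible surface area), CTDD (the
  distribution component: 7 attributes × 3 classes × 5 quantile positions,
  as % of length), CTriad (343-dim conjoint-triad class frequencies), and
  QSOrder (`lag=10`, `w=0.1`). All composition-style outputs are raw
  frequencies summing to 1, chosen over min-max variants for scale
  stability across sequence lengths. Geary returns 0.0 with a log message
  when a property profile is constant (zero variance), keeping feature
  matrices finite.
- **QSOrder distance matrix.** The bundled
  `data/qso_distance_synthetic.tsv` is a synthetic physicochemical distance
  matrix: Euclidean distance over five z-standardized scales (hydropathy,
  hydrophilicity, polarity, volume, side-chain mass), rescaled to max 1.
  Users reproducing a specific published quasi-sequence-order variant
  should supply their own 20×20 matrix; the loader accepts any file in the
  documented header+rows TSV format.
- **Contact features.** An n×m ligase×target contact-probability matrix is
  reduced by max pooling over the target axis to an n-vector (one value per
  ligase residue), so targets of any length produce stackable vectors.
  Producing the matrix itself requires an externally trained
  interaction model and is deliberately out of scope behind the file
  interface.

## eSHAP

The classifier operates on embedding coordinates with no direct biological
meaning. eSHAP grounds the decision onto residues:

1. **Feature selection.** Exact Shapley attributions are computed for every
   training sample with a native path-dependent TreeSHAP implementation
   (`preprotac.treeshap`): coalitions are weighted by the training-cover
   fractions at each split, evaluated in O(leaves × depth²) per sample per
   tree via the extend/unwind path-polynomial recursion. Global importance
   is the mean |attribution| over samples (signed means cancel); the top
   k = 20 features are kept. For the soft-voting ensemble, attributions are
   the member mean — consistent with the ensemble being the mean of its
   members. Feature selection requires embedding-provenance features, since
   the difference score is defined on the embedding space.
2. **Mutagenesis.** Every position is mutated once to its opposite-property
   residue: K→E, R→E, H→D (positive→negative); D→K, E→K
   (negative→positive); S/T/N/Q→L, Y→F, C→A (polar→hydrophobic);
   A/V/L/I/M→S, F→Y, W→Y (hydrophobic/aromatic→polar); P↔G. The table is
   total, never the identity, and deterministic; it lives in
   `properties.OPPOSITE_RESIDUE` and can be overridden. A single fixed
   substitute per residue (rather than sampling among candidates) keeps the
   scan deterministic.
3. **Scoring.** Position x gets the Euclidean norm of the parent−mutant
   embedding difference restricted to the selected features. Ranking is by
   score descending, ties broken by lower position. The attribution model
   for selection defaults to the ensemble; a single fold model or bare
   sklearn tree model is also accepted.

Attributions satisfy local accuracy exactly (checked to 1e-6 in the
acceptance suite, observed at ~1e-16): per sample, the attributions plus the
cover-weighted expectation reproduce the forest's predicted probability (or
the boosting margin). The TreeSHAP implementation is validated against
brute-force Shapley coalition enumeration on small trees.

## Synthetic benchmark

`synthetic.default_benchmark` generates 200 positive / 234 negative
sequences (the class balance of a published kinase degradation panel),
lengths 80–300 drawn uniformly, residues i.i.d. uniform over the 20
canonical amino acids, with the 6-mer motif `WCKDHE` planted at a random
interior site in every positive and in 2% of negatives. The planted motif
is the stand-in for whatever sequence property separates degradable from
non-degradable proteins.

Why these insertion probabilities: the benchmark is designed so that a
correct pipeline can demonstrate near-ceiling recovery. With class-
conditional insertion probabilities (p⁺, p⁻), no classifier can exceed a
ROC-AUC of p⁺(1−p⁻) + (1−p⁺(1−p⁻))/2 — motif-free positives are
statistically identical to motif-free negatives — so e.g. (0.9, 0.05) caps
ROC-AUC at ≈0.93 regardless of model quality. (1.0, 0.02) puts the ceiling
at 0.99 while keeping the task non-degenerate; the observed CV mean ROC-AUC
is ≈0.97. The generator itself accepts arbitrary probabilities, and a
property test verifies that pipeline ROC-AUC increases monotonically with
the insertion-probability gap.

What passing these tests shows: the mechanics — featurization, CV
bookkeeping, ensemble voting, calibration, Shapley selection, per-residue
scoring — behave correctly and deterministically on a signal of known
location and strength. What they do not show: performance on real
degradation data, which depends on label quality and on an embedder that
captures structure; benchmark metrics here say nothing about kinome-scale
generalization.

## Numerical and policy choices

- Non-canonical residues (X, U, B, Z, `*`): training reads drop the record
  with a warning; screening reads replace with alanine (configurable) so a
  proteome scan never aborts on one odd letter. Stop codons (`*`) are
  always stripped.
- Position indexing is 1-based in every user-visible report.
- Fold-model seeds are derived as `seed + 1000·fold_index + 1` (mod 2³¹−1);
  the whole pipeline is a deterministic function of (data, config, seed).
- Reports carry the seed and a 12-hex-digit SHA-256 config hash; wall-clock
  timestamps go to the log stream only, so identical reruns are
  byte-identical.
- Grid-search and ranking ties always resolve to the first element in
  deterministic enumeration order (grids) or the lower index/position
  (features, residues).
- Test and acceptance problem sizes (434-sequence benchmark with 100-tree
  forests; 80-sequence cohorts with 50-tree forests for the 20-seed eSHAP
  recovery study) were chosen as the smallest cohorts at which the planted
  signal is comfortably above sampling noise.

## Known limitations

- The native TreeSHAP is pure Python: exact but not optimized for
  proteome-scale attribution (a 434×256 training matrix against a
  1000-tree ensemble takes on the order of a minute). Selection is computed
  once per model, not per mutant, so eSHAP scans themselves stay cheap.
- GBT attributions explain the decision margin (log-odds), not the
  probability; RF attributions explain the probability directly.
- The fixture embedder treats sequences as bags of k-mers; it cannot
  represent order effects beyond k, and eSHAP resolution under it is
  limited to motif-composition changes. Because k-mers are hashed into a
  fixed number of buckets, benchmark difficulty varies slightly with the
  hashing seed (motif k-mers occasionally collide with high-traffic
  buckets): across seeds 0-5 the benchmark CV mean ROC-AUC ranges from
  about 0.94 to 0.98.
- `screen` embeds proteins one at a time; batching is left to the caller.
- The consensus ensemble's members must share a feature space; mixing
  embedders across members is not supported.
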
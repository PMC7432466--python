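# Methods

This note documents the modelling choices, default parameters and known
limitations of `cb2screen`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Curation model

Activity tables follow the schema of a ChEMBL activity export: SMILES,
standard type, value, unit, relation, document id, confidence score.
The seven-step pipeline is strictly ordered because the assay-size
filter counts records *after* structure and confidence removals:

1. acquisition; 2. structure standardization; 3. confidence ≥ 8;
4. document groups ≥ 10; 5. Ki-family types → pKi; 6. duplicate merge;
7. feature-duplicate removal.

Choices the data model forced:

* **Standardization** strips salts to the largest organic fragment
  (RDKit `FragmentParent`), neutralizes charges and identifies
  compounds by InChIKey. Tautomer canonicalization is deliberately not
  applied: the InChI layer already folds most tautomerism into the key,
  and full canonicalization is slow and version-sensitive. Metal
  complexes, polymers (wildcard atoms) and carbon-free species are
  rejected with reason codes.
* **Ki-family types** default to {Ki, pKi, logKi, log Ki},
  case-insensitive and configurable. Units are normalized through a
  molar lookup (pM..M); unknown units are errors, never guesses.
* **Non-exact relations** (`>`, `<`, `~`, …) are dropped at step 5:
  censored values bias a regression target.
* **Duplicate merge rule**: a same-InChIKey group merges to its mean
  pKi when its population SD is below 10% of the dataset-wide pKi
  range. Groups failing the rule are *dropped entirely* — measurements
  that disagree by dataset-scale amounts carry no usable consensus —
  and logged in the report.
* **Feature duplicates**: *all* members of a bitwise-identical-vector
  group are removed (not one representative kept), because
  indistinguishable compounds may carry different activities and any
  choice between them is arbitrary. Duplicate detection uses the 2D
  descriptor block plus the (achiral) Morgan fingerprint: bitwise
  comparability is the point, and conformer-derived 3D values carry
  numeric jitter that would make no two structures ever collide.

## Featurization

* 2D descriptors: RDKit's full standard set (210 descriptors in the
  pinned build). 3D descriptors (11 shape descriptors) are optional and
  computed on a single ETKDGv3 conformer embedded at a fixed seed
  (default 1905) so vectors are bitwise reproducible; a failed
  embedding marks the 3D block non-finite rather than imputing.
* The variance filter removes columns with any non-finite entry or
  population variance (ddof = 0) below 0.05. Population rather than
  sample variance: the filter describes the training matrix at hand,
  not an estimate of a larger population; at the 0.05 cutoff the
  difference only matters for very small sets.
* The filter is fit on the **training matrix only** and the retained
  column list frozen (`FeatureSpace`); screening-time compounds are
  projected onto exactly that space. Anything else leaks test
  information into feature selection.
* Fingerprints: 1024-bit Morgan, radius 3. Tanimoto of two all-zero
  fingerprints is defined as 1.0 (identical objects).

## Base model and applicability domain

* LightGBM regression ensemble; hyperparameters selected by grid search
  in an inner 5-fold CV (mean squared error). Default grid:
  trees {100, 300} × depth {unlimited, 6} × learning rate {0.05, 0.1};
  `min_child_samples` is fixed at 5 (LightGBM's default of 20 starves
  trees on datasets of a few hundred compounds).
* **Leaf-value embedding**: component *t* is the output value of the
  leaf the compound reaches in tree *t* — real values, not leaf
  indices, so the embedding lives in pKi-contribution units and
  Euclidean distances are meaningful without rescaling. LightGBM folds
  the boosting initialization into the first tree, so the components
  sum exactly to the ensemble prediction (asserted in tests).
* The kNN predictor (k = 3) averages the neighbours' **experimental**
  pKi, not the ensemble's own outputs: the boosted model only shapes
  the geometry; predictions stay anchored to measured data.
* Distance ties at the k-th neighbour break by training-set insertion
  order (stable and documented; predictions are row-order invariant up
  to this rule).
* The threshold grid is the 5th..100th percentiles (step 5) of the
  training distribution of each compound's max-3NN distance
  (self excluded) — 20 levels, non-decreasing by construction.

## Validation

* Outer 5-fold CV with random, seeded folds (no scaffold
  stratification). Inside each fold the variance mask, hyperparameters,
  embedding and threshold grid are all refit — the strictest reading of
  "no leakage", asserted by checking fold artifacts differ.
* Q² uses the mean of the *evaluated subset* per threshold level: each
  threshold admits a different in-domain population, so each defines
  its own null (subset-mean) predictor, which scores exactly 0.
* A threshold level with fewer than two in-domain test compounds (or a
  constant truth subset) reports Q² as undefined (NaN), not an error.
* The sweep report emits both the threshold value and the coverage per
  level, so the curve can be read against either axis.

## Synthetic data: what it emulates and what it does not

The generator exists so that every stage has inputs with known ground
truth. Structures come from a combinatorial scaffold–substituent
grammar (substituted benzenes and biphenyls, naphthalenes, chromenes,
chromones, indoles, cyclohexyl-phenyls) spanning ≈160–650 Da, so the
250–500 Da screening window has members on both sides. Defaults
(n = 300 compounds, 12 documents, 15% replicates, pKi noise SD 0.2,
confidence mix 60/25/15 for scores 9/8/7, 3% broken structures, 10%
non-Ki types, CB1–CB2 correlation 0.7) describe a mid-sized curated
receptor dataset.

The true activity surface is

    pKi_t = 7 + 1.2·(√ρ·s + √(1−ρ)·u_t) + 0.8·sin(2s)·cos(2v),

with s, u₁, u₂, v orthonormalized random projections of ten
standardized physicochemical descriptors. The smooth term fixes the
between-target correlation at ρ; the bounded high-frequency term
models **activity cliffs** — without it the surface is uniformly easy,
every region of chemical space predicts equally well, and the
applicability domain has nothing to detect. With it, sparse regions
are genuinely harder, which is what produces the declining
Q²-vs-threshold curve the architecture is designed around. Values are
clamped to [4, 10] (sub-µM to sub-nM binding).

Planted curation violations are mutually exclusive by construction
(each corrupt row violates exactly one rule; documents are sized
round-robin; replicate spread is kept well under the merge tolerance;
feature-duplicate prey are enantiomer pairs, which collide only under
the 2D + fingerprint featurization used for duplicate detection), so
expected per-step counts follow in closed form — that is what makes the
bookkeeping oracle exact rather than approximate.

What the generator does **not** emulate: real assay heterogeneity
(inter-lab systematic shifts), scaffold-biased sampling of chemical
space, realistic activity distributions beyond the stated moments, or
stereochemistry-dependent activity. Passing tests therefore demonstrate
the pipeline's correctness and the architecture's qualitative
behaviour, not performance on ChEMBL-scale data.

Docking scores use a binormal model: decoys ~ N(0, 1), actives ~
N(−√2·Φ⁻¹(AUC), 1), lower-is-better, giving the target AUC in
expectation.

## Enrichment statistics

* ROC AUC is the Mann–Whitney statistic (midranks for ties), checked in
  tests against explicit concordant-pair counting and against
  scikit-learn.
* EF(x) = (actives in the top ⌈x·N⌉ / total actives) / x. A tie group
  straddling the cutoff contributes pro-rata, rounded down —
  deterministic and conservative. EF(100%) = 1 identically.
* Score polarity is configurable; docking convention (lower = better)
  is the default.

## Problem sizes

The standard study conditions used throughout the test suite and the
acceptance script are n = 300 compounds for cross-validation studies,
n = 150 per target for the screening models, 80-compound activity
tables for curation bookkeeping, and 2000-ligand docking lists. CV
studies run with 2D descriptors only: the synthetic grammar emits
achiral structures, so conformer-derived descriptors add cost without
information there.

## Known limitations

* The leaf-value embedding reading ("the value predicted in each leaf")
  admits an alternative interpretation (one-hot leaf indicators); the
  value-based reading is implemented because it preserves pKi units and
  makes the Euclidean metric natural.
* Q² at very tight thresholds is estimated on few compounds and is
  correspondingly noisy; the sweep report exposes coverage so readers
  can judge.
* The MW filter uses the average molecular weight of the standardized
  parent (salt-stripped), bounds inclusive.
* The dpKi cut is applied as ≥ 1 (configurable); the novelty cut as
  Tanimoto < 0.5 (configurable).
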
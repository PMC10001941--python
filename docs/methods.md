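# Methods

## Problem and model

`grdf` classifies short peptides (11–50 residues over the 20 canonical
amino acids) as anticancer peptides (ACPs, label 1) or non-ACPs (label 0).
The model couples three complementary feature blocks with a cascade deep
forest classifier.

### FEGS graphical features (K + 420 dims; 578 with the bundled table)

For each physicochemical property row (20 values, one per amino acid):

1. The amino acids are sorted ascending by property value; ties break
   alphabetically so the embedding is deterministic across platforms. The
   rank-*i* amino acid is placed on a right cone of height 1 at
   φ(i) = (cos(2πi/20), sin(2πi/20), 1); ordered pairs map a quarter of
   the way between vertices, ψ(i, j) = φ(i) + (φ(j) − φ(i))/4. Vertices
   lie on the unit circle at z = 1; pair points with i ≠ j lie strictly
   inside it.
2. A 3D curve starts at the origin P₀ = (0,0,0). The step for residue
   sᵢ adds its vertex point plus the sum over amino-acid pairs of
   (frequency of the pair among the i − 1 adjacent windows of the prefix
   s₁…sᵢ) × (pair point). The pair sum is defined as zero at i = 1. The
   pair-valued map inside the sum is ψ — the only pair-valued map defined —
   and the frequency denominator is i − 1, the number of adjacent windows
   in the prefix.
3. The curve over the N residue points P₁…PN (the origin is excluded, so
   the matrix is N×N and matches the length-N normalisation below) is
   summarised by M with Mᵢⱼ = ‖Pᵢ − Pⱼ‖ / (along-curve path length from
   Pᵢ to Pⱼ), zero diagonal. Entries lie in [0, 1]; adjacent entries are
   exactly 1; M is symmetric, and translation of the curve leaves it
   unchanged.
4. The scalar descriptor is λ_max(M)/N, computed with a dense symmetric
   eigensolver (`numpy.linalg.eigvalsh`, batched over all K properties per
   peptide); sequences are ≤ 50 residues so M is at most 50×50 and
   iterative solvers are unnecessary.

The K descriptors are concatenated with amino-acid composition (AAC,
20 frequencies summing to 1) and dipeptide composition (DPC, 400 adjacent
pair frequencies summing to 1). AAC and DPC do not depend on the property
table at all, and the graphical descriptor depends on a property row only
through the ascending ordering it induces (adding a constant to a row
changes nothing).

**Bundled property table.** The canonical FEGS construction uses 158
AAindex-derived indices, but no curated list ships with this package; the
bundled `property_table_synthetic_158.tsv` is a deterministic synthetic
stand-in (158 rows named SYN0001…SYN0158, 20 distinct values each,
rounded to 6 decimals with per-row distinctness verified). It fixes the
dimensional contract (158 graphical dims, 578-dim FEGS vector) and
exercises every code path; users with a curated AAindex table can supply
it via `PropertyTable.from_tsv` — the TSV dialect is: first column the
index accession, then 20 columns headed by the amino acids in alphabetical
order, no missing values (rows with NAs are rejected at load time).

### BLOSUM62 and binary-profile encodings (1000 dims each)

Each peptide of length L ≤ 50 becomes a 50×20 matrix, zero-padded after
row L (trailing padding; sequences are left-aligned):

* **BLOSUM62**: row n is the canonical NCBI BLOSUM62 substitution-score
  row of residue n (loaded from biopython's `substitution_matrices`, no
  rescaling), a proxy for evolutionary exchangeability.
* **Binary profile**: row n is one-hot at residue n's column.

Columns follow the fixed alphabetical order ACDEFGHIKLMNPQRSTVWY, and
matrices are flattened row-major (position-major) — classification is
invariant to any fixed coordinate permutation, so a single pinned
convention is used everywhere and tests enforce it. The combined vector is
[FEGS | BLOSUM62 | binary] = 578 + 1000 + 1000 = 2578 dims, with a block
index retained for importance attribution.

### Cascade deep forest

Each level holds n random forests (√d candidate features per split) and
n completely random forests (one uniformly random candidate feature with a
random threshold in its observed range per node, grown to purity /
min-leaf 1 — realised as `ExtraTreesClassifier(max_features=1)`). Each
forest emits a 2-dim class vector (average over trees of leaf-node class
proportions); the 2n class vectors concatenate into a 4n-dim augmented
feature. Level 1 sees the original k features; deeper levels see
[original k | previous 4n], i.e. k + 4n inputs. Final prediction averages
the last level's 2n class vectors; the label is the argmax with ties
resolving to class 0 (pinned so tests are deterministic).

Defaults and rationale:

* `n_forests` n = 2 per type (searchable over {1, 2, 4} by 5-fold CV via
  `grid_search_n`, ties to smaller n).
* `n_trees` = 100 per forest — standard deep-forest practice, balancing
  variance reduction against desk-scale runtime.
* **Cross-fitted class vectors**: training-level augmentations are
  produced out-of-fold by 3-fold stratified cross-fitting so augmented
  features do not leak training labels into deeper levels; the level's
  forests are then refitted on the full data for prediction time. This is
  an implementation choice (ablatable via `crossfit=False`, which falls
  back to in-sample class vectors and training-accuracy level scores).
* **Early stopping**: each level is scored by the accuracy of its averaged
  out-of-fold class vectors (a 3-fold CV estimate obtained at no extra
  cost). Growth stops when a level fails to beat the best score by more
  than ε = 1e-4 absolute for `patience` = 1 consecutive level, or at
  `max_levels` = 20 (with a warning); the cascade is truncated at the best
  level, so retained depth ≤ max_levels and the best level's score is the
  maximum of the per-level scores.
* **Determinism**: one integer seed drives every forest's random state and
  the fold assignment (seeded `StratifiedKFold` over row indices); fixed
  config + seed gives bit-identical predictions. Because folds are
  assigned by row position, permuting training rows can change fold
  assignment and hence level scores — this is the documented contract.
* **Gini importance** is averaged over the first level's forests only:
  only that level sees exclusively original features, so attributions map
  cleanly onto the named blocks; deeper levels mix in augmented
  class-vector coordinates. Importances are normalised to sum to 1 and
  summed per block for group attribution.

### Evaluation

Accuracy, precision, recall and F1 follow the standard confusion-matrix
formulas with class 1 positive; zero-denominator ratios are reported as 0
with a flag rather than raising, so degenerate folds never abort a CV
sweep. AUROC is trapezoidal over the ROC curve; AUPRC uses the step-wise
(interpolation-free) average-precision convention — conventions differ
between packages, so this is pinned. Model selection in CV uses mean
accuracy by default (F1 selectable). Nested CV chooses n on inner folds
(5 by default) of each outer-training part and evaluates once on the
outer-test part.

## Synthetic data generator

The generator emulates the *structure* of ACP benchmark sets — two
labelled classes of 11–50-mer peptides — with an interpretable, seedable
class signal: negatives draw residues uniformly; positives shift a
fraction δ (`effect`) of the probability mass of D/E/N (acidic/neutral
residues depleted in real ACPs) onto K/R/L (cationic/hydrophobic residues
enriched in them), and optionally carry a planted cationic 7-mer motif
(`KWKLFKK`) at a random position. δ = 0 without motif gives exchangeable
classes (null fixture); δ = 0.5 with motif gives a cleanly separable
problem. The study conditions used throughout testing and the acceptance
script are 200 peptides per class, lengths 11–50, δ ∈ {0, 0.5}.

What it does **not** emulate: real ACP physicochemistry beyond coarse
composition bias — no amphipathic helix periodicity, no length–activity
relation, no homology structure between sequences (benchmark sets contain
related peptides; no CD-HIT-style redundancy handling is attempted). A
pipeline passing the synthetic recovery tests is therefore shown to
propagate composition and positional signal end to end, not to achieve any
particular accuracy on real ACP benchmarks; reproducing published
benchmark numbers requires the original datasets and is supported as an
optional workflow, not asserted by tests.

## Numerical choices and degenerate inputs

* Property-row ordering ties: stable alphabetical tie-break.
* Curve matrices reject coincident consecutive points (zero path length);
  by construction cone curves never produce them (every step gains ≥ 1 in z).
* `curve_descriptor` verifies symmetry to 1e-10 before solving.
* Non-canonical residues (B, J, O, U, X, Z): strict rejection by default,
  with an opt-in drop-with-warning mode, because every downstream encoding
  (cone position, BLOSUM62 row, one-hot column) is defined only for the 20
  canonical amino acids.
* The 8:2 split is stratified by label and seeded (the field's benchmark
  descriptions do not state either; both are made explicit defaults).
  Per-class train counts are `round(ratio * class_size)`, clamped to keep
  both sides non-empty.

## Problem sizes

Tests and the acceptance script run the full pipeline at 200 peptides per
class (400 samples, 2578 features) with the default cascade — chosen as
the smallest scale at which the separable/null contrast is unambiguous —
and unit tests use 3-row property tables and 10–50-tree cascades, since
correctness of every operation is independent of K and forest size.

## Known limitations

* The bundled property table is synthetic; absolute feature values (and
  hence any model trained with it) are not comparable to a FEGS
  implementation using the curated AAindex selection, although all
  dimensional and geometric contracts are identical.
* Binary classification only; the class-vector machinery is written for 2
  classes (extension would generalise the reshape/averaging logic).
* No multi-grained scanning stage — the cascade alone, as the framework
  this package implements prescribes.
* Whether the origin P₀ participates in M and whether the original FEGS
  normalises property rows before ordering are unobservable from the
  construction as specified here; the choices above (exclude P₀; ordering
  is scale-invariant anyway) are documented as potential deviation risks.
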
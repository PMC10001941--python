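# grdf

Anticancer peptide (ACP) prediction from sequence alone, combining a
graphical representation of peptide physicochemistry with a cascade deep
forest classifier.

ACPs are short (11–50 residue), mostly cationic peptides — a subset of
antimicrobial peptides — that selectively lyse cancer cells, whose
membranes carry more negative surface charge than healthy cells.
Screening candidate peptides experimentally is slow, so sequence-based
classifiers are used to rank candidates first. `grdf` implements such a
classifier for binary ACP / non-ACP prediction.

## Model

Each peptide `S = s₁…s_N` is encoded as a 2578-dim vector from three blocks:

* **FEGS graphical features (578 dims).** Per physicochemical property
  row, the 20 amino acids are sorted ascending and placed on a right cone
  of height 1 at φ(i) = (cos 2πi/20, sin 2πi/20, 1), with pair points
  ψ(i,j) = φ(i) + (φ(j) − φ(i))/4. The peptide traces a 3D curve from the
  origin, each residue adding its vertex point plus prefix-pair-frequency
  weighted pair points. The curve's N×N distance-ratio matrix M
  (Mᵢⱼ = ‖Pᵢ−Pⱼ‖ / along-curve path length) is summarised by λ_max(M)/N.
  One descriptor per property (158 bundled) plus amino-acid composition
  (20) and dipeptide composition (400).
* **BLOSUM62 encoding (1000 dims).** Row n of a zero-padded 50×20 matrix
  is the BLOSUM62 substitution-score row of residue n (evolutionary
  information).
* **Binary profile (1000 dims).** One-hot 50×20 encoding (composition and
  order).

The classifier is a **cascade deep forest**: levels of n random forests +
n completely random forests, each emitting a 2-dim class vector (averaged
leaf class proportions). Level ℓ ≥ 2 receives the original k features
concatenated with the previous level's 4n class vectors; depth is chosen
automatically by early stopping on out-of-fold level accuracy, and the
final probability averages the last level's 2n class vectors.

## Worked example

Simulate a labelled dataset with planted signal, extract features, train,
and cross-validate — either from Python:

```python
import numpy as np
from grdf import (SimConfig, gen_peptides, featurize,
                  load_default_property_table, CascadeConfig, cross_validate)

peps = gen_peptides(SimConfig(n_per_class=200, effect=0.5, seed=1))
X, names, blocks = featurize(peps, load_default_property_table())
y = np.array([p.label for p in peps])
print(X.shape)
result = cross_validate(X, y, CascadeConfig(seed=1), folds=5, seed=1)
print({k: round(v, 4) for k, v in result.mean.items()})
```

which prints

```
(400, 2578)
{'accuracy': 0.9975, 'precision': 1.0, 'recall': 0.995, 'f1': 0.9975, 'auroc': 1.0, 'auprc': 1.0}
```

— 400 peptides encoded as 2578-dim vectors, and 5-fold cross-validated
accuracy 99.75% on the separable fixture (composition bias δ = 0.5 plus a
planted cationic motif in positives). With `effect=0, motif=None` the same
pipeline scores ≈ 50% (chance), confirming the signal, not an artefact,
drives the accuracy. Or from the shell:

```sh
grdf simulate --out data --n-per-class 200 --effect 0.5 --seed 1
grdf extract --positives data/positives.fasta --negatives data/negatives.fasta \
     --out features.tsv
grdf cv --features features.tsv --folds 5 --seed 1 --out cv.tsv
grdf train --features features.tsv --model model.joblib --seed 1
grdf importance --model model.joblib --features features.tsv --out importance.tsv
```

Subcommands: `simulate`, `extract`, `train`, `predict`, `evaluate`, `cv`,
`nested-cv`, `importance`; every command takes `--seed` and writes its
resolved parameters as a `.config.json` sidecar.

To analyse real data, put ACPs in `positives.fasta` and non-ACPs in
`negatives.fasta` (canonical residues only, lengths 11–50 after
filtering) and start at `grdf extract`. The bundled property table is a
synthetic stand-in that fixes dimensionality; pass a curated AAindex-style
table via `--table` for physicochemically meaningful graphical features
(see `docs/methods.md`).

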
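"""Zero-padded BLOSUM62 and binary-profile peptide encodings, plus feature assembly.

Each peptide of length L <= 50 becomes two 50 x 20 matrices: a BLOSUM62
encoding (row n = the substitution-score row of residue n against the 20
amino acids, capturing evolutionary exchangeability) and a binary profile
(row n = one-hot at residue n's column).  Rows L+1..50 are zero padding,
so variable-length peptides share a fixed shape.  Columns follow the
alphabetical order ACDEFGHIKLMNPQRSTVWY everywhere; matrices are flattened
row-major (position-major), so flattened coordinates group by position.

The combined feature vector is [FEGS | BLOSUM62 | binary] — 578 + 1000 +
1000 = 2578 dimensions with the bundled 158-property table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from .fegs import FegsVector, PropertyTable, fegs_feature_names, fegs_vector
from .seqio import AA_ALPHABET, AA_INDEX, Peptide

#: Maximum encodable sequence length (the dataset length filter's upper bound).
MAX_LEN = 50

_B62 = substitution_matrices.load("BLOSUM62")
#: Canonical BLOSUM62 scores restricted to the 20 amino acids, alphabetical order.
BLOSUM62 = np.array(
    [[float(_B62[a, b]) for b in AA_ALPHABET] for a in AA_ALPHABET]
)


def _check(seq: str) -> str:
    if not seq:
        raise ValueError("empty sequence")
    if len(seq) > MAX_LEN:
        raise ValueError(f"sequence length {len(seq)} exceeds {MAX_LEN}")
    bad = set(seq) - set(AA_ALPHABET)
    if bad:
        raise ValueError(f"non-canonical residue(s) {''.join(sorted(bad))!r}")
    return seq


def blosum62_encode(peptide: Peptide | str) -> np.ndarray:
    """BLOSUM62 encoding: (50, 20) matrix, row n = BLOSUM62 row of residue n."""
    seq = _check(peptide.sequence if isinstance(peptide, Peptide) else peptide)
    out = np.zeros((MAX_LEN, 20))
    idx = [AA_INDEX[a] for a in seq]
    out[: len(seq)] = BLOSUM62[idx]
    return out


def binary_profile(peptide: Peptide | str) -> np.ndarray:
    """One-hot binary profile: (50, 20) matrix, row n one-hot at residue n."""
    seq = _check(peptide.sequence if isinstance(peptide, Peptide) else peptide)
    out = np.zeros((MAX_LEN, 20))
    out[np.arange(len(seq)), [AA_INDEX[a] for a in seq]] = 1.0
    return out


@dataclass(frozen=True)
class CombinedFeature:
    """The concatenated feature vector of one peptide with block bookkeeping.

    ``block_index`` maps each block name to its slice of ``full``; the
    slices partition all coordinates in the fixed order fegs, blosum, binary.
    """

    fegs: np.ndarray
    blosum: np.ndarray   # flattened, 1000 dims
    binary: np.ndarray   # flattened, 1000 dims

    @property
    def full(self) -> np.ndarray:
        return np.concatenate([self.fegs, self.blosum, self.binary])

    @property
    def block_index(self) -> dict[str, slice]:
        k = self.fegs.shape[0]
        return {
            "fegs": slice(0, k),
            "blosum": slice(k, k + self.blosum.shape[0]),
            "binary": slice(k + self.blosum.shape[0], k + self.blosum.shape[0] + self.binary.shape[0]),
        }


def combine(fegs: FegsVector | np.ndarray, blosum: np.ndarray, binary: np.ndarray) -> CombinedFeature:
    """Assemble [FEGS | BLOSUM62 | binary]; matrices are flattened row-major."""
    fegs_flat = fegs.full if isinstance(fegs, FegsVector) else np.asarray(fegs, float)
    if fegs_flat.ndim != 1 or fegs_flat.size == 0:
        raise ValueError("fegs block must be a non-empty 1-D vector")
    blosum = np.asarray(blosum, float)
    binary = np.asarray(binary, float)
    for name, mat in (("blosum", blosum), ("binary", binary)):
        if mat.shape != (MAX_LEN, 20):
            raise ValueError(f"{name} block must be {MAX_LEN} x 20, got {mat.shape}")
    return CombinedFeature(
        fegs=fegs_flat, blosum=blosum.reshape(-1), binary=binary.reshape(-1)
    )


_BLOCK_BUILDERS = ("fegs", "blosum", "binary")


def block_feature_names(blocks: tuple[str, ...], table: PropertyTable | None) -> list[str]:
    """Column names for the selected blocks, matching `featurize` column order."""
    names: list[str] = []
    for block in blocks:
        if block == "fegs":
            if table is None:
                raise ValueError("fegs block needs a property table")
            names += fegs_feature_names(table)
        elif block == "blosum":
            names += [f"blo_p{n}_{a}" for n in range(1, MAX_LEN + 1) for a in AA_ALPHABET]
        elif block == "binary":
            names += [f"bin_p{n}_{a}" for n in range(1, MAX_LEN + 1) for a in AA_ALPHABET]
        else:
            raise ValueError(f"unknown feature block {block!r}")
    return names


def featurize(
    peptides: list[Peptide],
    table: PropertyTable | None = None,
    blocks: tuple[str, ...] = _BLOCK_BUILDERS,
):
    """Encode a dataset with the selected feature blocks.

    Returns
    -------
    X : (m, d) feature matrix
    names : list of d column names
    block_index : dict mapping block name -> slice of columns
    """
    if not peptides:
        raise ValueError("no peptides to featurize")
    for block in blocks:
        if block not in _BLOCK_BUILDERS:
            raise ValueError(f"unknown feature block {block!r}")
    parts: list[np.ndarray] = []
    block_index: dict[str, slice] = {}
    start = 0
    for block in blocks:
        if block == "fegs":
            if table is None:
                raise ValueError("fegs block needs a property table")
            mat = np.stack([fegs_vector(p, table).full for p in peptides])
        elif block == "blosum":
            mat = np.stack([blosum62_encode(p).reshape(-1) for p in peptides])
        else:
            mat = np.stack([binary_profile(p).reshape(-1) for p in peptides])
        parts.append(mat)
        block_index[block] = slice(start, start + mat.shape[1])
        start += mat.shape[1]
    return np.hstack(parts), block_feature_names(tuple(blocks), table), block_index
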
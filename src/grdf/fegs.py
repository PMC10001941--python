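"""FEGS graphical sequence features: cone curves, eigen-descriptors, AAC, DPC.

FEGS (Feature Extraction based on Graphical and Statistical features)
represents a peptide, per physicochemical property, as a 3D curve drawn on
a right circular cone of height 1:

* For one property, the 20 amino acids are sorted ascending by their
  property values (ties broken alphabetically) and the amino acid of rank
  ``i`` is placed on the unit circle at height 1,
  ``phi(i) = (cos(2*pi*i/20), sin(2*pi*i/20), 1)``.
* Each ordered amino-acid pair is mapped a quarter of the way from the
  first vertex toward the second, ``psi(i, j) = phi(i) + (phi(j) - phi(i))/4``.
* The curve starts at the origin P0 = (0, 0, 0) and steps once per residue:
  the increment for residue ``s_i`` is its vertex point plus the
  frequency-weighted sum of pair points over the ``i - 1`` adjacent pairs
  of the prefix ``s_1 .. s_i`` (empty at i = 1).

The curve over points P1..PN is summarised by the N x N matrix M with
``M[i, j] = |Pi - Pj| / (path length from Pi to Pj along the curve)`` and
zero diagonal; the scalar descriptor is the largest eigenvalue of M divided
by N.  One descriptor per property, concatenated with amino-acid
composition (AAC, 20 dims) and dipeptide composition (DPC, 400 dims),
gives the FEGS vector: K + 420 dimensions, 578 for the bundled
158-property table.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import AA_ALPHABET, AA_INDEX, Peptide

N_AA = 20
#: Dimensions contributed by AAC + DPC on top of the K graphical descriptors.
STAT_DIMS = N_AA + N_AA * N_AA


class PropertyTableError(ValueError):
    """Raised for malformed physicochemical property tables."""


@dataclass(frozen=True)
class PropertyTable:
    """K physicochemical indices, each assigning a value to the 20 amino acids.

    ``values[k, j]`` is the value of index ``k`` for the j-th amino acid in
    alphabetical order (ACDEFGHIKLMNPQRSTVWY).
    """

    names: tuple[str, ...]
    values: np.ndarray  # (K, 20)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] != N_AA:
            raise PropertyTableError(f"values must be K x 20, got {values.shape}")
        if len(self.names) != values.shape[0]:
            raise PropertyTableError("names and values row counts differ")
        if values.shape[0] < 1:
            raise PropertyTableError("property table needs at least one row")
        bad = [self.names[k] for k in range(values.shape[0]) if not np.all(np.isfinite(values[k]))]
        if bad:
            raise PropertyTableError(f"non-finite values in property row(s): {bad}")
        object.__setattr__(self, "values", values)

    @property
    def n_properties(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_tsv(cls, path) -> "PropertyTable":
        """Load from TSV: first column = index accession, then one column
        per amino acid in alphabetical order."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.columns) != list(AA_ALPHABET):
            raise PropertyTableError(
                f"{path}: header must be the 20 amino acids in alphabetical "
                f"order, got {list(df.columns)}"
            )
        if df.isna().any().any():
            missing = df.index[df.isna().any(axis=1)].tolist()
            raise PropertyTableError(f"{path}: missing values in row(s) {missing}")
        return cls(names=tuple(str(i) for i in df.index), values=df.to_numpy(float))

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=list(self.names), columns=list(AA_ALPHABET))
        df.to_csv(path, sep="\t")


def load_default_property_table() -> PropertyTable:
    """Load the bundled synthetic 158-row property table.

    The table is a deterministic synthetic stand-in (rows SYN0001..SYN0158)
    with 20 distinct values per row; it fixes the feature dimensionality
    (158 graphical descriptors, 578-dim FEGS vector) and exercises the full
    pipeline.  Real analyses should supply a curated AAindex-derived table
    via ``PropertyTable.from_tsv``.
    """
    ref = importlib.resources.files("grdf.data") / "property_table_synthetic_158.tsv"
    with importlib.resources.as_file(ref) as path:
        return PropertyTable.from_tsv(path)


# ---------------------------------------------------------------------------
# Cone geometry
# ---------------------------------------------------------------------------

def order_amino_acids(property_row) -> str:
    """Sort the 20 amino acids ascending by property value.

    Ties are broken by alphabetical amino-acid order (stable sort), so the
    embedding is deterministic across runs and platforms.
    """
    row = np.asarray(property_row, dtype=float)
    if row.shape != (N_AA,):
        raise ValueError(f"property row must have 20 values, got shape {row.shape}")
    if not np.all(np.isfinite(row)):
        raise ValueError("property row contains non-finite values")
    order = np.argsort(row, kind="stable")
    return "".join(AA_ALPHABET[i] for i in order)


def cone_vertex(i: int) -> np.ndarray:
    """Vertex point of the rank-``i`` amino acid: (cos(2*pi*i/20), sin(2*pi*i/20), 1)."""
    if not 1 <= i <= N_AA:
        raise ValueError(f"rank must be in 1..20, got {i}")
    theta = 2.0 * np.pi * i / N_AA
    return np.array([np.cos(theta), np.sin(theta), 1.0])


def cone_pair(i: int, j: int) -> np.ndarray:
    """Pair point for ranks (i, j): a quarter of the way from vertex i to vertex j."""
    vi, vj = cone_vertex(i), cone_vertex(j)
    return vi + 0.25 * (vj - vi)


@dataclass(frozen=True)
class ConeEmbedding:
    """Cone placement of amino acids and pairs for one property row.

    ``ranks[a]`` is the 1-based rank of alphabetical amino acid ``a``;
    ``vertex_points[r-1]`` is the vertex of rank ``r``;
    ``pair_points[ri-1, rj-1]`` is the pair point psi for ranks (ri, rj).
    """

    ordering: str
    ranks: np.ndarray        # (20,) int, 1-based, indexed alphabetically
    vertex_points: np.ndarray  # (20, 3), indexed by rank-1
    pair_points: np.ndarray    # (20, 20, 3), indexed by (rank_i-1, rank_j-1)

    @classmethod
    def from_property_row(cls, property_row) -> "ConeEmbedding":
        ordering = order_amino_acids(property_row)
        ranks = np.empty(N_AA, dtype=int)
        for r, aa in enumerate(ordering, start=1):
            ranks[AA_INDEX[aa]] = r
        vertices = np.stack([cone_vertex(r) for r in range(1, N_AA + 1)])
        pairs = 0.75 * vertices[:, None, :] + 0.25 * vertices[None, :, :]
        return cls(ordering=ordering, ranks=ranks, vertex_points=vertices, pair_points=pairs)


# ---------------------------------------------------------------------------
# Curves and matrices (batched core: K properties at once)
# ---------------------------------------------------------------------------

def _curves_batch(seq_idx: np.ndarray, vertex_by_aa: np.ndarray) -> np.ndarray:
    """Build the cone curves of one sequence under K properties at once.

    Parameters
    ----------
    seq_idx : (N,) int
        Alphabetical amino-acid indices of the sequence.
    vertex_by_aa : (K, 20, 3)
        Per-property vertex point of each alphabetical amino acid.

    Returns
    -------
    (K, N+1, 3) curve points including P0 = origin.
    """
    n = seq_idx.shape[0]
    vstep = vertex_by_aa[:, seq_idx, :]                    # (K, N, 3) phi(s_i)
    if n > 1:
        # psi(a, b) = 0.75 phi(a) + 0.25 phi(b) for adjacent residues
        pair_psi = 0.75 * vstep[:, :-1, :] + 0.25 * vstep[:, 1:, :]  # (K, N-1, 3)
        cum = np.cumsum(pair_psi, axis=1)
        # running pair-point sum entering step i (empty at i = 1)
        s = np.concatenate([np.zeros_like(vstep[:, :1, :]), cum], axis=1)  # (K, N, 3)
    else:
        s = np.zeros_like(vstep)
    denom = np.maximum(np.arange(n), 1).astype(float)       # i-1 windows, clamped at 1
    inc = vstep + s / denom[None, :, None]
    curves = np.concatenate(
        [np.zeros_like(inc[:, :1, :]), np.cumsum(inc, axis=1)], axis=1
    )
    return curves


def _curve_matrices(curves: np.ndarray) -> np.ndarray:
    """Distance-ratio matrices M for a (K, N+1, 3) stack of curves.

    M is built over the amino-acid points P1..PN (the origin P0 is
    excluded): ``M[i, j] = |Pi - Pj| / sum of edge lengths from Pi to Pj``,
    zero diagonal.
    """
    pts = curves[:, 1:, :]                                   # (K, N, 3)
    if pts.shape[1] < 2:
        raise ValueError("curve matrix needs at least 2 amino-acid points")
    edges = np.linalg.norm(np.diff(pts, axis=1), axis=-1)    # (K, N-1)
    if np.any(edges <= 0):
        raise ValueError("degenerate curve: coincident consecutive points")
    cum = np.concatenate([np.zeros_like(edges[:, :1]), np.cumsum(edges, axis=1)], axis=1)
    path = np.abs(cum[:, :, None] - cum[:, None, :])         # (K, N, N)
    dist = np.linalg.norm(pts[:, :, None, :] - pts[:, None, :, :], axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(path > 0, dist / np.where(path > 0, path, 1.0), 0.0)
    idx = np.arange(pts.shape[1])
    m[:, idx, idx] = 0.0
    return m


def build_curve(peptide: Peptide | str, embedding: ConeEmbedding) -> np.ndarray:
    """Cone curve of one peptide under one property embedding.

    Returns the (N+1, 3) array of points P0..PN, P0 = (0, 0, 0).
    """
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    if not seq:
        raise ValueError("empty sequence")
    seq_idx = np.array([AA_INDEX[a] for a in seq])
    vertex_by_aa = embedding.vertex_points[embedding.ranks - 1][None, :, :]
    return _curves_batch(seq_idx, vertex_by_aa)[0]


def curve_matrix(curve: np.ndarray) -> np.ndarray:
    """Distance-ratio matrix of one curve given as (N+1, 3) points incl. P0."""
    return _curve_matrices(np.asarray(curve, float)[None])[0]


def curve_descriptor(m: np.ndarray, n: int | None = None) -> float:
    """Largest eigenvalue of the (symmetric) curve matrix, divided by N."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"curve matrix must be square, got {m.shape}")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("curve matrix must be symmetric")
    if n is None:
        n = m.shape[0]
    return float(np.linalg.eigvalsh(m)[-1]) / n


# ---------------------------------------------------------------------------
# Statistical features
# ---------------------------------------------------------------------------

def aac(peptide: Peptide | str) -> np.ndarray:
    """Amino-acid composition: 20 residue frequencies summing to 1."""
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    if not seq:
        raise ValueError("empty sequence")
    counts = np.zeros(N_AA)
    for a in seq:
        counts[AA_INDEX[a]] += 1
    return counts / len(seq)


def dpc(peptide: Peptide | str) -> np.ndarray:
    """Dipeptide composition: 400 adjacent-pair frequencies summing to 1.

    Entry ``20*i + j`` is the frequency of the ordered pair (i-th, j-th)
    amino acid among the N-1 adjacent windows.
    """
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    if len(seq) < 2:
        raise ValueError("dipeptide composition needs length >= 2")
    counts = np.zeros(N_AA * N_AA)
    for a, b in zip(seq, seq[1:]):
        counts[N_AA * AA_INDEX[a] + AA_INDEX[b]] += 1
    return counts / (len(seq) - 1)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FegsVector:
    """FEGS features of one peptide: K graphical descriptors + AAC + DPC."""

    graphical: np.ndarray  # (K,)
    aac: np.ndarray        # (20,)
    dpc: np.ndarray        # (400,)

    @property
    def full(self) -> np.ndarray:
        return np.concatenate([self.graphical, self.aac, self.dpc])


def graphical_descriptors(peptide: Peptide | str, table: PropertyTable) -> np.ndarray:
    """The K per-property curve eigen-descriptors of one peptide."""
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    if len(seq) < 2:
        raise ValueError("graphical descriptors need length >= 2")
    seq_idx = np.array([AA_INDEX[a] for a in seq])
    # rank of each alphabetical aa per property: argsort twice, stable ties
    order = np.argsort(table.values, axis=1, kind="stable")   # (K, 20)
    ranks = np.empty_like(order)
    k_idx = np.arange(table.n_properties)[:, None]
    ranks[k_idx, order] = np.arange(1, N_AA + 1)[None, :]
    theta = 2.0 * np.pi * np.arange(1, N_AA + 1) / N_AA
    vertex_by_rank = np.stack(
        [np.cos(theta), np.sin(theta), np.ones_like(theta)], axis=-1
    )                                                         # (20, 3)
    vertex_by_aa = vertex_by_rank[ranks - 1]                  # (K, 20, 3)
    curves = _curves_batch(seq_idx, vertex_by_aa)
    mats = _curve_matrices(curves)
    top = np.linalg.eigvalsh(mats)[:, -1]
    return top / len(seq)


def fegs_vector(peptide: Peptide | str, table: PropertyTable) -> FegsVector:
    """Full FEGS feature vector of one peptide: K + 420 dimensions."""
    return FegsVector(
        graphical=graphical_descriptors(peptide, table),
        aac=aac(peptide),
        dpc=dpc(peptide),
    )


def fegs_feature_names(table: PropertyTable) -> list[str]:
    """Column names for the FEGS vector: fegs_g_<index>, aac_<aa>, dpc_<aa1><aa2>."""
    names = [f"fegs_g_{name}" for name in table.names]
    names += [f"aac_{a}" for a in AA_ALPHABET]
    names += [f"dpc_{a}{b}" for a in AA_ALPHABET for b in AA_ALPHABET]
    return names


def fegs_matrix(peptides: list[Peptide], table: PropertyTable) -> np.ndarray:
    """FEGS vectors for a dataset, one row per peptide: (m, K + 420)."""
    return np.stack([fegs_vector(p, table).full for p in peptides])
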
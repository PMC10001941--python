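"""Synthetic peptide datasets and property tables with controllable signal.

The generator emulates the structure of ACP benchmark sets — a positive
and a negative class of peptides, lengths 11-50 — with a tunable,
interpretable class signal:

* negatives draw residues from the uniform composition (1/20 each);
* positives shift a fraction ``effect`` (delta) of the probability mass of
  three disfavoured residues (D, E, N — acidic/neutral residues real ACPs
  are depleted in) onto three favoured ones (K, R, L — cationic/
  hydrophobic residues real ACPs are enriched in);
* optionally, a fixed k-mer motif is planted at a random position of every
  positive, giving a strong localised signal for the position-aware
  encoders.

At ``effect = 0`` with no motif the classes are exchangeable (null
fixture); at ``effect = 0.5`` with the default cationic motif the classes
are cleanly separable by the full pipeline.  Everything is driven by a
single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .fegs import PropertyTable
from .seqio import AA_ALPHABET, AA_INDEX, Peptide, write_fasta

#: Residues enriched in the positive class (cationic / hydrophobic).
FAVORED = "KRL"
#: Residues depleted in the positive class (acidic / neutral).
DISFAVORED = "DEN"
#: Default planted motif: a cationic amphipathic-like 7-mer.
DEFAULT_MOTIF = "KWKLFKK"


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic dataset draw."""

    n_per_class: int = 200
    length_range: tuple[int, int] = (11, 50)
    seed: int = 0
    effect: float = 0.5          # composition-bias strength delta in [0, 1]
    motif: str | None = DEFAULT_MOTIF

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (11 <= lo <= hi <= 50):
            raise ValueError(f"length_range must lie within [11, 50], got {self.length_range}")
        if not 0.0 <= self.effect <= 1.0:
            raise ValueError("effect must be in [0, 1]")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.motif is not None:
            if not self.motif or set(self.motif) - set(AA_ALPHABET):
                raise ValueError("motif must be a non-empty canonical-residue k-mer")
            if len(self.motif) > lo:
                raise ValueError("motif longer than the minimum sequence length")


def class_compositions(effect: float) -> tuple[np.ndarray, np.ndarray]:
    """Residue probability vectors (negative, positive) for a bias strength."""
    neg = np.full(20, 1.0 / 20)
    pos = neg.copy()
    moved = effect / 20.0
    for aa in DISFAVORED:
        pos[AA_INDEX[aa]] -= moved
    for aa in FAVORED:
        pos[AA_INDEX[aa]] += moved
    return neg, pos


def gen_peptides(config: SimConfig) -> list[Peptide]:
    """Generate a labelled synthetic dataset (positives first, then negatives)."""
    rng = np.random.default_rng(config.seed)
    neg_p, pos_p = class_compositions(config.effect)
    lo, hi = config.length_range
    alphabet = np.array(list(AA_ALPHABET))
    peptides: list[Peptide] = []
    width = len(str(config.n_per_class))
    for label, probs, prefix in ((1, pos_p, "pos"), (0, neg_p, "neg")):
        for i in range(config.n_per_class):
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(alphabet, size=length, p=probs))
            if label == 1 and config.motif is not None:
                start = int(rng.integers(0, length - len(config.motif) + 1))
                seq = seq[:start] + config.motif + seq[start + len(config.motif):]
            peptides.append(
                Peptide(id=f"{prefix}_{i + 1:0{width}d}", sequence=seq, label=label)
            )
    return peptides


def gen_property_table(k: int, seed: int = 0) -> PropertyTable:
    """Generate K synthetic physicochemical index rows with 20 distinct values.

    Values are standard-normal draws with an amino-acid-indexed offset that
    rules out ties by construction, so the ascending ordering of every row
    is unambiguous.
    """
    if k < 1:
        raise ValueError("need at least one property row")
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((k, 20)) + np.arange(20) * 1e-9
    # standard-normal rows are almost surely tie-free; the offset settles
    # exact-float collisions deterministically
    names = tuple(f"SYN{i + 1:04d}" for i in range(k))
    return PropertyTable(names=names, values=values)


def write_fixture(peptides: list[Peptide], config: SimConfig, out_dir) -> dict:
    """Write positives.fasta / negatives.fasta plus a manifest JSON."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta([p for p in peptides if p.label == 1], out / "positives.fasta")
    write_fasta([p for p in peptides if p.label == 0], out / "negatives.fasta")
    manifest = {"config": asdict(config), "n_total": len(peptides)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
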
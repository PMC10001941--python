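"""Reading, validating, filtering and splitting labelled peptide datasets.

Peptides are short amino-acid sequences over the canonical 20-letter
alphabet.  The positive class (label 1) are anticancer peptides (ACPs);
the negative class (label 0) are non-ACPs (e.g. antimicrobial peptides
without anticancer activity, or random peptides).  Benchmark sets in this
field retain only sequences of length 11-50, and models are evaluated on
a stratified 8:2 train/test split; both conventions are the defaults here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids in alphabetical single-letter order.
#: This ordering is the fixed column/position convention used by every
#: encoder in the package.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

#: Default length filter bounds for ACP benchmark datasets.
MIN_LENGTH = 11
MAX_LENGTH = 50


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed."""


class SequenceValidationError(ValueError):
    """Raised when a sequence contains residues outside the canonical alphabet."""


@dataclass(frozen=True)
class Peptide:
    """A validated peptide sequence with identifier and optional binary label.

    Parameters
    ----------
    id : str
        Record identifier (unique within a dataset).
    sequence : str
        Amino-acid sequence; normalised to uppercase and validated against
        the 20-letter canonical alphabet.
    label : int or None
        1 for ACP (positive), 0 for non-ACP, None if unlabelled.
    """

    id: str
    sequence: str
    label: int | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        bad = set(seq) - set(AA_ALPHABET)
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r}: non-canonical residue(s) "
                f"{''.join(sorted(bad))!r} (alphabet is {AA_ALPHABET})"
            )
        if self.label not in (None, 0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0, 1 or None")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DatasetSplit:
    """A stratified train/test partition of a labelled peptide set."""

    train: list[Peptide]
    test: list[Peptide]
    seed: int
    ratio: float


def read_fasta(
    path,
    label: int | None = None,
    strict: bool = True,
) -> list[Peptide]:
    """Read peptides from a FASTA file.

    Parameters
    ----------
    path : path-like
        FASTA file; multi-line records are allowed.
    label : int or None
        Label assigned to every record (the two-file positives/negatives
        convention), or None to leave records unlabelled.
    strict : bool
        If True (default), a record containing a non-canonical residue
        raises :class:`SequenceValidationError`.  If False, offending
        records are dropped with a warning.

    Returns
    -------
    list of Peptide, in file order.  Duplicate ids raise ``FastaParseError``.
    """
    peptides: list[Peptide] = []
    seen: set[str] = set()
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # biopython names the offending line
        raise FastaParseError(f"{path}: {exc}") from exc
    for rec in records:
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        try:
            peptides.append(Peptide(id=rec.id, sequence=str(rec.seq), label=label))
        except SequenceValidationError:
            if strict:
                raise
            warnings.warn(
                f"{path}: dropping record {rec.id!r} with non-canonical residues",
                stacklevel=2,
            )
    return peptides


def read_labeled_pair(positives_path, negatives_path, strict: bool = True) -> list[Peptide]:
    """Read a labelled dataset from positives.fasta / negatives.fasta."""
    pos = read_fasta(positives_path, label=1, strict=strict)
    neg = read_fasta(negatives_path, label=0, strict=strict)
    return pos + neg


def write_fasta(peptides: list[Peptide], path, width: int = 60) -> None:
    """Write peptides to FASTA, wrapping sequences at ``width`` columns."""
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description="") for p in peptides
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def length_filter(
    peptides: list[Peptide],
    min_len: int = MIN_LENGTH,
    max_len: int = MAX_LENGTH,
) -> list[Peptide]:
    """Keep peptides with ``min_len <= length <= max_len``, preserving order."""
    if min_len < 1 or max_len < min_len:
        raise ValueError(f"invalid length bounds [{min_len}, {max_len}]")
    kept = [p for p in peptides if min_len <= len(p) <= max_len]
    removed = len(peptides) - len(kept)
    if removed:
        logger.info("length_filter removed %d of %d peptides", removed, len(peptides))
    return kept


def stratified_split(
    peptides: list[Peptide],
    ratio: float = 0.8,
    seed: int = 0,
) -> DatasetSplit:
    """Seeded, label-stratified train/test split.

    Per class, ``round(ratio * class_size)`` peptides go to the train set,
    so each class's train fraction is within one item of ``ratio``.  The
    same seed always reproduces the identical partition.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    for p in peptides:
        if p.label is None:
            raise ValueError(f"unlabelled peptide {p.id!r}; splitting needs labels")
    by_class: dict[int, list[Peptide]] = {0: [], 1: []}
    for p in peptides:
        by_class[p.label].append(p)
    for cls, members in by_class.items():
        if len(members) < 2:
            raise ValueError(f"class {cls} has {len(members)} member(s); need >= 2")
    rng = np.random.default_rng(seed)
    train: list[Peptide] = []
    test: list[Peptide] = []
    for cls in (1, 0):
        members = by_class[cls]
        order = rng.permutation(len(members))
        n_train = int(round(ratio * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)  # keep both sides non-empty
        train.extend(members[i] for i in sorted(order[:n_train]))
        test.extend(members[i] for i in sorted(order[n_train:]))
    return DatasetSplit(train=train, test=test, seed=seed, ratio=ratio)


def read_label_table(path) -> dict[str, int]:
    """Read an optional TSV label file with columns ``id`` and ``label``."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if not {"id", "label"} <= set(df.columns):
        raise ValueError(f"{path}: label table needs columns 'id' and 'label'")
    return dict(zip(df["id"], df["label"].astype(int)))


def attach_labels(peptides: list[Peptide], labels: dict[str, int]) -> list[Peptide]:
    """Return peptides relabelled from an id -> label mapping."""
    out = []
    for p in peptides:
        if p.id not in labels:
            raise ValueError(f"no label for record {p.id!r}")
        out.append(Peptide(id=p.id, sequence=p.sequence, label=int(labels[p.id])))
    return out
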
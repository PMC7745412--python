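"""Reading, normalisation and assembly of labeled RNA sequence datasets.

Binding-site classifiers are trained from two FASTA files — bound (positive)
and unbound (negative) sites — optionally accompanied by one structural
"shape" string per sequence (see :mod:`kebind.structure`).  This module reads
those files, normalises residues to the RNA alphabet ``{A, C, G, U}`` and
assembles :class:`LabeledDataset` objects that the rest of the pipeline
consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, AlphabetError, DatasetError, ParseError

RNA_ALPHABET = "ACGU"

__all__ = [
    "RNA_ALPHABET",
    "NucleotideSequence",
    "LabeledExample",
    "LabeledDataset",
    "normalize_rna",
    "read_fasta",
    "write_fasta",
    "load_labeled_dataset",
]


@dataclass(frozen=True)
class NucleotideSequence:
    """An identified RNA sequence over the alphabet ``{A, C, G, U}``."""

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class LabeledExample:
    """One classification example: sequence, optional shape string, binary label."""

    sequence: NucleotideSequence
    shape: Optional[str]
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise DatasetError(f"label must be 0 or 1, got {self.label!r}")
        if self.shape is not None and len(self.shape) != len(self.sequence):
            raise AlignmentError(
                f"shape length {len(self.shape)} != sequence length "
                f"{len(self.sequence)} for record {self.sequence.id!r}"
            )


@dataclass
class LabeledDataset:
    """An ordered collection of labeled examples with provenance metadata."""

    examples: list[LabeledExample]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.examples)

    def __iter__(self) -> Iterator[LabeledExample]:
        return iter(self.examples)

    def __getitem__(self, i: int) -> LabeledExample:
        return self.examples[i]

    @property
    def labels(self) -> np.ndarray:
        return np.array([ex.label for ex in self.examples], dtype=np.int64)

    @property
    def has_shapes(self) -> bool:
        return all(ex.shape is not None for ex in self.examples)

    def subset(self, indices: Sequence[int], provenance_suffix: str = "") -> "LabeledDataset":
        return LabeledDataset(
            examples=[self.examples[i] for i in indices],
            provenance=self.provenance + provenance_suffix,
        )

    def require_both_classes(self) -> None:
        labels = self.labels
        if len(self) == 0 or labels.min() == labels.max():
            raise DatasetError("dataset must contain at least one example of each label")


def normalize_rna(
    raw: str,
    mode: str = "strict",
    seed: Optional[int] = None,
) -> str:
    """Normalise a raw residue string to uppercase RNA.

    DNA-style ``T`` is converted to ``U``.  Any remaining character outside
    ``{A, C, G, U}`` is rejected in ``strict`` mode (default) or replaced by a
    uniformly random unambiguous base in ``permissive`` mode, reproducibly for
    a given ``seed``.
    """
    if not raw:
        raise ParseError("empty sequence string")
    if mode not in ("strict", "permissive"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    s = raw.upper().replace("T", "U")
    bad = [i for i, ch in enumerate(s) if ch not in RNA_ALPHABET]
    if not bad:
        return s
    if mode == "strict":
        i = bad[0]
        raise AlphabetError(
            f"invalid residue {s[i]!r} at position {i + 1} (strict mode)"
        )
    rng = np.random.default_rng(seed)
    chars = list(s)
    for i in bad:
        chars[i] = RNA_ALPHABET[rng.integers(4)]
    return "".join(chars)


def read_fasta(
    path: str | Path,
    mode: str = "strict",
    seed: Optional[int] = None,
) -> list[NucleotideSequence]:
    """Read a FASTA file into normalised :class:`NucleotideSequence` records.

    Order is preserved; residues pass through :func:`normalize_rna`.
    Raises :class:`ParseError` for an empty file or a record with an empty body.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # biopython signals headerless content this way
        raise ParseError(f"{path}: malformed FASTA: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        body = str(rec.seq)
        if not body:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence body")
        try:
            residues = normalize_rna(body, mode=mode, seed=seed)
        except AlphabetError as exc:
            raise AlphabetError(f"{path}: record {rec.id!r}: {exc}") from exc
        out.append(NucleotideSequence(id=rec.id, residues=residues))
    return out


def write_fasta(records: Iterable[NucleotideSequence], path: str | Path) -> None:
    """Write records as single-line-per-sequence FASTA."""
    seq_records = [
        SeqRecord(Seq(rec.residues), id=rec.id, description="") for rec in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta-2line")


def load_labeled_dataset(
    pos_path: str | Path,
    neg_path: str | Path,
    shape_path: Optional[str | Path] = None,
    mode: str = "strict",
    seed: Optional[int] = None,
) -> LabeledDataset:
    """Assemble a labeled dataset from positive and negative FASTA files.

    Positives are labeled 1, negatives 0, positives first, file order
    preserved.  If ``shape_path`` is given it must supply exactly one shape
    string per sequence, in the same order (positives then negatives); each
    shape must match its sequence's length.
    """
    positives = read_fasta(pos_path, mode=mode, seed=seed)
    negatives = read_fasta(neg_path, mode=mode, seed=seed)
    sequences = positives + negatives
    labels = [1] * len(positives) + [0] * len(negatives)

    shapes: list[Optional[str]]
    if shape_path is not None:
        from .structure import load_structure_strings

        expected = [len(s) for s in sequences]
        shapes = list(
            load_structure_strings(shape_path, expected_lengths=expected,
                                   record_ids=[s.id for s in sequences])
        )
    else:
        shapes = [None] * len(sequences)

    examples = [
        LabeledExample(sequence=seq, shape=shape, label=label)
        for seq, shape, label in zip(sequences, shapes, labels)
    ]
    prov = f"pos={pos_path} neg={neg_path}" + (
        f" shapes={shape_path}" if shape_path is not None else ""
    )
    return LabeledDataset(examples=examples, provenance=prov)
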
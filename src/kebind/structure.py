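"""RNA secondary-structure shape annotation.

Binding preferences of many RNA-binding proteins depend on the structural
context of a site, not only on its primary sequence.  This module reduces a
secondary structure (dot-bracket notation) to a per-position string over six
generic structural contexts:

====== =============================================
letter context
====== =============================================
``S``  stem (paired position)
``M``  multiloop (unpaired, closing pair encloses >= 2 branch helices)
``H``  hairpin loop (unpaired, no enclosed branch)
``I``  internal loop / bulge (unpaired, exactly one enclosed branch)
``T``  dangling end (unpaired, external, after the first helix)
``F``  dangling start (unpaired, external, before the first helix)
====== =============================================

The per-position classification rules are defined here explicitly so that
shape strings are reproducible without external folding/annotation tools; an
adapter (:func:`load_structure_strings`) accepts precomputed shape strings
when users have them.  Convention choices: a fully unpaired structure is
annotated all-``T``; external positions between two helices are ``T``.
Pseudoknots are rejected (dot-bracket semantics).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import AlignmentError, AlphabetError, ParseError

SHAPE_ALPHABET = "FHIMST"  # lexicographic order of the six context letters

__all__ = [
    "SHAPE_ALPHABET",
    "PairTable",
    "parse_dot_bracket",
    "annotate_shapes",
    "shapes_from_dot_bracket",
    "load_structure_strings",
    "read_dot_bracket_file",
    "validate_shape_string",
]


@dataclass(frozen=True)
class PairTable:
    """Base-pair table: ``partner[i]`` is the 1-based partner of position
    ``i+1``, or 0 if unpaired."""

    partner: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.partner, dtype=np.int64)
        object.__setattr__(self, "partner", p)
        n = len(p)
        for i, j in enumerate(p):
            if j < 0 or j > n:
                raise ValueError(f"partner index {j} out of range at position {i + 1}")
            if j:
                if j == i + 1:
                    raise ValueError(f"position {i + 1} paired with itself")
                if p[j - 1] != i + 1:
                    raise ValueError(f"partner table is not an involution at {i + 1}")

    def __len__(self) -> int:
        return len(self.partner)

    @property
    def n_paired(self) -> int:
        return int(np.count_nonzero(self.partner))

    def pairs(self) -> list[tuple[int, int]]:
        """Base pairs as 0-based (open, close) tuples with open < close."""
        return [
            (i, int(j) - 1)
            for i, j in enumerate(self.partner)
            if j and i < int(j) - 1
        ]


def parse_dot_bracket(db: str) -> PairTable:
    """Parse a dot-bracket string into a :class:`PairTable`.

    Matched parentheses are paired by stack discipline; dots are unpaired.
    Raises :class:`ParseError` with a 1-based position for unbalanced input
    or a foreign character.
    """
    if not db:
        raise ParseError("empty dot-bracket string")
    partner = np.zeros(len(db), dtype=np.int64)
    stack: list[int] = []
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ParseError(f"unmatched ')' at position {i + 1}")
            j = stack.pop()
            partner[i] = j + 1
            partner[j] = i + 1
        elif ch != ".":
            raise ParseError(f"illegal dot-bracket character {ch!r} at position {i + 1}")
    if stack:
        raise ParseError(f"unmatched '(' at position {stack[-1] + 1}")
    return PairTable(partner=partner)


def annotate_shapes(pt: PairTable) -> str:
    """Classify each position of a pair table into the six shape letters.

    Paired positions are ``S``.  An unpaired position outside every pair is
    ``F`` before the first paired position and ``T`` otherwise (including a
    fully unpaired structure).  An unpaired position directly enclosed by a
    pair takes ``H``, ``I`` or ``M`` according to whether that pair encloses
    zero, one, or two-or-more branch helices.
    """
    n = len(pt)
    partner = pt.partner
    out = ["?"] * n

    # enclosing pair (0-based open index) for every position, via stack scan
    enclosing: list[Optional[int]] = [None] * n
    stack: list[int] = []
    for i in range(n):
        if partner[i] and int(partner[i]) - 1 > i:  # opening
            enclosing[i] = stack[-1] if stack else None
            stack.append(i)
        elif partner[i]:  # closing
            stack.pop()
            enclosing[i] = stack[-1] if stack else None
        else:
            enclosing[i] = stack[-1] if stack else None

    # number of branch helices directly inside each pair (keyed by open index)
    branches: dict[int, int] = {}
    for open_i, close_i in pt.pairs():
        count = 0
        k = open_i + 1
        while k < close_i:
            if partner[k] and int(partner[k]) - 1 > k:
                count += 1
                k = int(partner[k])  # jump past the branch's closing position
            else:
                k += 1
        branches[open_i] = count

    paired_any = pt.n_paired > 0
    first_paired = int(np.flatnonzero(partner)[0]) if paired_any else -1

    for i in range(n):
        if partner[i]:
            out[i] = "S"
        elif enclosing[i] is None:
            out[i] = "F" if (paired_any and i < first_paired) else "T"
        else:
            b = branches[enclosing[i]]
            out[i] = "H" if b == 0 else ("I" if b == 1 else "M")
    return "".join(out)


def shapes_from_dot_bracket(db: str) -> str:
    """Convenience: dot-bracket string straight to shape string."""
    return annotate_shapes(parse_dot_bracket(db))


def validate_shape_string(
    shape: str,
    expected_length: Optional[int] = None,
    where: str = "",
) -> str:
    prefix = f"{where}: " if where else ""
    for i, ch in enumerate(shape):
        if ch not in SHAPE_ALPHABET:
            raise AlphabetError(
                f"{prefix}illegal shape character {ch!r} at position {i + 1}"
            )
    if expected_length is not None and len(shape) != expected_length:
        raise AlignmentError(
            f"{prefix}shape length {len(shape)} != sequence length {expected_length}"
        )
    return shape


def load_structure_strings(
    path: str | Path,
    expected_lengths: Sequence[int],
    record_ids: Optional[Sequence[str]] = None,
) -> list[str]:
    """Read precomputed shape strings, one per line, blank lines ignored.

    Each line is validated against the six-letter alphabet and the expected
    length of the corresponding sequence (order-matched).
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    lines = [ln for ln in lines if ln]
    if len(lines) != len(expected_lengths):
        raise AlignmentError(
            f"{path}: {len(lines)} shape strings for {len(expected_lengths)} sequences"
        )
    out = []
    for i, (line, length) in enumerate(zip(lines, expected_lengths)):
        name = record_ids[i] if record_ids is not None else f"line {i + 1}"
        out.append(validate_shape_string(line, expected_length=length, where=str(name)))
    return out


def read_dot_bracket_file(path: str | Path) -> list[str]:
    """Read dot-bracket strings from plain text (one structure per line,
    blank lines ignored, ``>`` header lines and sequence lines of Vienna-style
    triplets skipped)."""
    path = Path(path)
    structures = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith(">"):
                continue
            if set(ln) <= set("().") :
                structures.append(ln)
    if not structures:
        raise ParseError(f"{path}: no dot-bracket lines found")
    return structures
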
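"""Synthetic motif-implantation benchmarks with known ground truth.

Emulates the structure of CLIP-seq-derived binding-site datasets: positives
are random-background RNA sequences carrying a (noisy) consensus motif,
optionally inside a declared structural context; negatives are
dinucleotide-preserving shuffles of the positives (or pure background, or
motif-bearing decoys).  Because the implant position and context of every
example are recorded, each pipeline stage — tokenization, embedding,
structure annotation and the classifier itself — can be tested end to end
without external downloads.

Shape strings are generated directly (exact ground truth); an option routes
them through the dot-bracket annotator of :mod:`kebind.structure` on
constructed structures instead.  All output is bitwise-reproducible from
(spec, seed); coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .seqio import LabeledDataset, LabeledExample, NucleotideSequence, RNA_ALPHABET
from .structure import shapes_from_dot_bracket

NEGATIVE_MODES = ("shuffle", "background", "decoy_motif", "swapped_pair")
STRUCTURAL_CONTEXTS = ("none", "hairpin_loop", "stem")

# helix length flanking a synthetic hairpin loop
_STEM_LEN = 6

__all__ = [
    "SyntheticSpec",
    "sample_background",
    "implant_motif",
    "dinucleotide_shuffle",
    "generate_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    Defaults mirror a GraphProt-style variable-length benchmark: 500
    positives and 500 negatives of 150-375 nt uniform-background RNA, a
    14-nt consensus motif with 10% per-position mutation, negatives by
    dinucleotide shuffle.  (The consensus is long because the negatives
    are composition-matched shuffles of the positives — a short motif's
    scrambled dinucleotides make such negatives nearly inseparable.)  ``structural_context``/``coupling`` control
    whether (and how often) the implanted motif sits inside a declared
    structural context; ``motif2``/``gap_range`` switch to a spaced
    motif-pair construction for long-range-dependency experiments.
    """

    n_pos: int = 500
    n_neg: int = 500
    length_range: tuple[int, int] = (150, 375)
    background_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    motif: str = "UGCAUGACGCAUGC"
    per_position_mutation_rate: float = 0.1
    structural_context: str = "none"
    coupling: float = 1.0
    seed: int = 0
    negative_mode: str = "shuffle"
    motif2: Optional[str] = None
    gap_range: tuple[int, int] = (10, 40)
    use_annotator: bool = False

    def __post_init__(self) -> None:
        comp = np.asarray(self.background_composition, dtype=np.float64)
        if comp.shape != (4,) or comp.min() < 0 or abs(comp.sum() - 1.0) > 1e-9:
            raise ConfigError("background_composition must be 4 probabilities summing to 1")
        if not (0.0 <= self.per_position_mutation_rate <= 1.0
                and 0.0 <= self.coupling <= 1.0):
            raise ConfigError("rates must lie in [0, 1]")
        if self.structural_context not in STRUCTURAL_CONTEXTS:
            raise ConfigError(f"structural_context must be one of {STRUCTURAL_CONTEXTS}")
        if self.negative_mode not in NEGATIVE_MODES:
            raise ConfigError(f"negative_mode must be one of {NEGATIVE_MODES}")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ConfigError("length_range must satisfy 1 <= min <= max")
        if self.n_pos < 1 or self.n_neg < 1:
            raise ConfigError("n_pos and n_neg must be >= 1")
        for m in filter(None, (self.motif, self.motif2)):
            if set(m) - set(RNA_ALPHABET):
                raise ConfigError(f"motif {m!r} contains non-RNA characters")
        footprint = len(self.motif)
        if self.motif2 is not None:
            footprint += self.gap_range[1] + len(self.motif2)
        elif self.structural_context != "none":
            footprint += 2 * _STEM_LEN
        if footprint >= lo:
            raise ConfigError(
                f"motif footprint {footprint} does not fit the minimum length {lo}")


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_background(
    length: int,
    composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed=0,
    id: str = "bg",
) -> NucleotideSequence:
    """I.i.d. background sequence from the base composition; seeded."""
    if length < 1:
        raise ConfigError("length must be >= 1")
    comp = np.asarray(composition, dtype=np.float64)
    if comp.shape != (4,) or comp.min() < 0 or abs(comp.sum() - 1.0) > 1e-9:
        raise ConfigError("composition must be 4 probabilities summing to 1")
    rng = _as_rng(seed)
    idx = rng.choice(4, size=length, p=comp)
    return NucleotideSequence(id=id, residues="".join(RNA_ALPHABET[i] for i in idx))


def implant_motif(
    seq: NucleotideSequence,
    motif: str,
    mutation_rate: float = 0.0,
    position: Optional[int] = None,
    seed=0,
) -> tuple[NucleotideSequence, int]:
    """Copy the motif over a window, mutating each position independently to
    a random *different* base with probability ``mutation_rate``.

    Returns the modified sequence and the 0-based half-open implant start.
    ``position=None`` draws the start uniformly from the valid range.
    """
    L, w = len(seq), len(motif)
    if w > L:
        raise ConfigError(f"motif of length {w} does not fit sequence of length {L}")
    rng = _as_rng(seed)
    if position is None:
        position = int(rng.integers(0, L - w + 1))
    if not 0 <= position <= L - w:
        raise ConfigError(f"implant position {position} out of range")
    window = []
    for ch in motif:
        if rng.random() < mutation_rate:
            others = [b for b in RNA_ALPHABET if b != ch]
            ch = others[rng.integers(3)]
        window.append(ch)
    residues = seq.residues[:position] + "".join(window) + seq.residues[position + w :]
    return NucleotideSequence(id=seq.id, residues=residues), position


def dinucleotide_shuffle(seq: NucleotideSequence | str, seed=0) -> NucleotideSequence:
    """Eulerian-path shuffle preserving all dinucleotide counts.

    The returned sequence has exactly the input's adjacent-pair count
    multiset (hence also its mononucleotide counts and length) but random
    order among the valid arrangements; reproducible given ``seed``.
    """
    residues = seq if isinstance(seq, str) else seq.residues
    name = "shuffled" if isinstance(seq, str) else seq.id
    if len(residues) < 2:
        raise ConfigError("dinucleotide shuffle needs length >= 2")
    rng = _as_rng(seed)
    start, end = residues[0], residues[-1]
    out_edges: dict[str, list[str]] = {}
    for a, b in zip(residues, residues[1:]):
        out_edges.setdefault(a, []).append(b)

    vertices = list(out_edges)
    while True:
        # reserve a random last out-edge per vertex (except the end vertex)
        last: dict[str, str] = {}
        for v in vertices:
            if v != end:
                last[v] = out_edges[v][rng.integers(len(out_edges[v]))]
        # the reserved edges must form paths leading into the end vertex
        ok = True
        for v in last:
            seen = set()
            cur = v
            while cur != end:
                if cur in seen or cur not in last:
                    ok = False
                    break
                seen.add(cur)
                cur = last[cur]
            if not ok:
                break
        if ok:
            break

    pools: dict[str, list[str]] = {}
    for v in vertices:
        pool = list(out_edges[v])
        if v in last:
            pool.remove(last[v])
        rng.shuffle(pool)
        if v in last:
            pool.append(last[v])
        pools[v] = pool

    walk = [start]
    cur = start
    positions = {v: 0 for v in vertices}
    for _ in range(len(residues) - 1):
        nxt = pools[cur][positions[cur]]
        positions[cur] += 1
        walk.append(nxt)
        cur = nxt
    return NucleotideSequence(id=name, residues="".join(walk))


# ---------------------------------------------------------------------------
# Shape-string construction.


def _hairpin_shape(L: int, loop_start: int, loop_end: int,
                   use_annotator: bool) -> str:
    """Shape string with a hairpin loop over [loop_start, loop_end) flanked
    by helices of length ``_STEM_LEN``; F before, T after."""
    s = _STEM_LEN
    a = loop_start - s
    b = L - (loop_end + s)
    if use_annotator:
        db = "." * a + "(" * s + "." * (loop_end - loop_start) + ")" * s + "." * b
        return shapes_from_dot_bracket(db)
    return "F" * a + "S" * s + "H" * (loop_end - loop_start) + "S" * s + "T" * b


def _stem_shape(L: int, stem_start: int, stem_end: int,
                use_annotator: bool) -> str:
    """Shape string where [stem_start, stem_end) is one helix side, followed
    by a 4-nt hairpin loop and the partner helix."""
    w = stem_end - stem_start
    loop = 4
    a = stem_start
    b = L - (stem_end + loop + w)
    if use_annotator:
        db = "." * a + "(" * w + "." * loop + ")" * w + "." * b
        return shapes_from_dot_bracket(db)
    return "F" * a + "S" * w + "H" * loop + "S" * w + "T" * b


def _context_free_shape(L: int, rng: np.random.Generator,
                        avoid: Optional[tuple[int, int]],
                        use_annotator: bool, loop: int = 6) -> str:
    """A decoy hairpin at a random position, optionally not overlapping
    ``avoid``; falls back to all-unpaired if nothing fits."""
    s = _STEM_LEN
    total = 2 * s + loop
    candidates = []
    for start in range(0, L - total + 1):
        if avoid is not None:
            lo, hi = start + s, start + s + loop  # decoy loop window
            if not (hi <= avoid[0] or lo >= avoid[1]):
                continue
        candidates.append(start)
    if not candidates:
        return "T" * L
    start = candidates[int(rng.integers(len(candidates)))]
    loop_start = start + s
    return _hairpin_shape(L, loop_start, loop_start + loop, use_annotator)


def generate_dataset(spec: SyntheticSpec) -> tuple[LabeledDataset, pd.DataFrame]:
    """Generate a labeled dataset plus its ground-truth table.

    Positives carry the implanted motif (inside the declared structural
    context with probability ``coupling``); negatives are produced per
    ``negative_mode``.  Every example carries a shape string.  The truth
    table records, per example: id, label, implant coordinates (0-based
    half-open; -1 if none) and whether the implant sits in context.
    """
    rng = np.random.default_rng(spec.seed)
    comp = np.asarray(spec.background_composition, dtype=np.float64)
    lo, hi = spec.length_range
    w = len(spec.motif)
    # decoy hairpin loops match the in-context loop width so that loop
    # length alone never separates the classes
    decoy_loop = w if spec.structural_context != "none" else 6

    examples: list[LabeledExample] = []
    rows = []

    positives: list[NucleotideSequence] = []
    for i in range(spec.n_pos):
        L = int(rng.integers(lo, hi + 1))
        seq = sample_background(L, comp, rng, id=f"pos_{i:05d}")
        row = {"id": seq.id, "label": 1, "implant_start": -1, "implant_end": -1,
               "implant2_start": -1, "implant2_end": -1, "in_context": False}

        if spec.motif2 is not None:
            gap = int(rng.integers(spec.gap_range[0], spec.gap_range[1] + 1))
            w2 = len(spec.motif2)
            span = w + gap + w2
            start = int(rng.integers(0, L - span + 1))
            seq, p1 = implant_motif(seq, spec.motif,
                                    spec.per_position_mutation_rate, start, rng)
            seq, p2 = implant_motif(seq, spec.motif2,
                                    spec.per_position_mutation_rate,
                                    start + w + gap, rng)
            row.update(implant_start=p1, implant_end=p1 + w,
                       implant2_start=p2, implant2_end=p2 + w2)
            shape = _context_free_shape(L, rng, None, spec.use_annotator, decoy_loop)
        elif spec.structural_context != "none" and rng.random() < spec.coupling:
            pos = int(rng.integers(_STEM_LEN, L - w - _STEM_LEN + 1))
            if spec.structural_context == "stem":
                pos = int(rng.integers(0, L - (2 * w + 4) + 1))
            seq, pos = implant_motif(seq, spec.motif,
                                     spec.per_position_mutation_rate, pos, rng)
            if spec.structural_context == "hairpin_loop":
                shape = _hairpin_shape(L, pos, pos + w, spec.use_annotator)
            else:
                shape = _stem_shape(L, pos, pos + w, spec.use_annotator)
            row.update(implant_start=pos, implant_end=pos + w, in_context=True)
        else:
            seq, pos = implant_motif(seq, spec.motif,
                                     spec.per_position_mutation_rate, None, rng)
            shape = _context_free_shape(L, rng, None, spec.use_annotator, decoy_loop)
            row.update(implant_start=pos, implant_end=pos + w)

        positives.append(seq)
        examples.append(LabeledExample(sequence=seq, shape=shape, label=1))
        rows.append(row)

    for i in range(spec.n_neg):
        row = {"id": f"neg_{i:05d}", "label": 0, "implant_start": -1,
               "implant_end": -1, "implant2_start": -1, "implant2_end": -1,
               "in_context": False}
        if spec.negative_mode == "shuffle":
            src = positives[i % len(positives)]
            seq = dinucleotide_shuffle(src, rng)
            seq = NucleotideSequence(id=row["id"], residues=seq.residues)
            shape = _context_free_shape(len(seq), rng, None, spec.use_annotator, decoy_loop)
        elif spec.negative_mode == "background":
            L = int(rng.integers(lo, hi + 1))
            seq = sample_background(L, comp, rng, id=row["id"])
            shape = _context_free_shape(L, rng, None, spec.use_annotator, decoy_loop)
        elif spec.negative_mode == "decoy_motif":
            # same motif, but presented without structural context: the
            # decoy site does not fold, so its shape string is all-external
            L = int(rng.integers(lo, hi + 1))
            seq = sample_background(L, comp, rng, id=row["id"])
            seq, pos = implant_motif(seq, spec.motif,
                                     spec.per_position_mutation_rate, None, rng)
            shape = "T" * L
            row.update(implant_start=pos, implant_end=pos + w)
        else:  # swapped_pair: both motifs present but in reversed order
            if spec.motif2 is None:
                raise ConfigError("negative_mode='swapped_pair' requires motif2")
            L = int(rng.integers(lo, hi + 1))
            seq = sample_background(L, comp, rng, id=row["id"])
            gap = int(rng.integers(spec.gap_range[0], spec.gap_range[1] + 1))
            w2 = len(spec.motif2)
            span = w2 + gap + w
            start = int(rng.integers(0, L - span + 1))
            seq, p1 = implant_motif(seq, spec.motif2,
                                    spec.per_position_mutation_rate, start, rng)
            seq, p2 = implant_motif(seq, spec.motif,
                                    spec.per_position_mutation_rate,
                                    start + w2 + gap, rng)
            row.update(implant_start=p2, implant_end=p2 + w,
                       implant2_start=p1, implant2_end=p1 + w2)
            shape = _context_free_shape(L, rng, None, spec.use_annotator, decoy_loop)
        examples.append(LabeledExample(sequence=seq, shape=shape, label=0))
        rows.append(row)

    truth = pd.DataFrame(rows)
    ds = LabeledDataset(examples=examples, provenance=f"synthetic spec={spec}")
    return ds, truth


def write_dataset(ds: LabeledDataset, truth: pd.DataFrame, out_dir) -> None:
    """Write positives.fa / negatives.fa / shapes_{pos,neg}.txt / truth.tsv."""
    from pathlib import Path

    from .seqio import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pos = [ex for ex in ds if ex.label == 1]
    neg = [ex for ex in ds if ex.label == 0]
    write_fasta([ex.sequence for ex in pos], out / "positives.fa")
    write_fasta([ex.sequence for ex in neg], out / "negatives.fa")
    for name, group in (("shapes_pos.txt", pos), ("shapes_neg.txt", neg)):
        with open(out / name, "w") as fh:
            for ex in group:
                fh.write((ex.shape or "") + "\n")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
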
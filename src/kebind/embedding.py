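"""Distributed representations of overlapping k-mers via skip-gram.

Each RNA sequence (and each structural shape string) is treated as a
sentence whose "words" are its overlapping k-mers (stride 1, default k=3).
A skip-gram model with negative sampling learns a dense d-dimensional vector
per k-mer from co-occurrence within a context window.  For a center token
``c``, an observed context token ``o`` and ``n`` noise tokens ``s_i`` drawn
from the noise distribution ``P_n``, the per-pair objective being maximised
is::

    log sigma(u_o . v_c) + sum_i log sigma(-u_{s_i} . v_c)

where ``v`` are input (center) vectors and ``u`` are output (context)
vectors.  The input vectors are the downstream representation.

Vocabularies are complete enumerations of all |alphabet|^k k-mers — 4^3 = 64
for RNA sequences, and 6^3 = 216 (or 125 under a 5-letter structure
convention) for shape strings — so indices are stable across corpora and
runs.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import AlphabetError, ConfigError
from .seqio import RNA_ALPHABET
from .structure import SHAPE_ALPHABET

__all__ = [
    "KmerVocabulary",
    "SkipGramConfig",
    "KmerEmbedding",
    "build_vocabulary",
    "tokenize",
    "skipgram_pairs",
    "unigram_noise_distribution",
    "sgns_pair_loss",
    "sgns_pair_gradients",
    "sgns_expected_objective",
    "train_skipgram",
    "embed_tokens",
]


@dataclass(frozen=True)
class KmerVocabulary:
    """Bijection between all |alphabet|^k k-mers and indices [0, V)."""

    k: int
    alphabet: str
    kmers: tuple[str, ...]
    index_of: dict[str, int]

    @property
    def V(self) -> int:
        return len(self.kmers)

    def __len__(self) -> int:
        return len(self.kmers)


def build_vocabulary(alphabet: str | Sequence[str], k: int) -> KmerVocabulary:
    """Enumerate all ``|alphabet|^k`` k-mers in lexicographic order of the
    given (ordered) alphabet; indices are stable across runs."""
    alphabet = "".join(alphabet)
    if not alphabet or len(set(alphabet)) != len(alphabet):
        raise ConfigError(f"alphabet must be non-empty without repeats: {alphabet!r}")
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    kmers = tuple("".join(t) for t in itertools.product(alphabet, repeat=k))
    return KmerVocabulary(
        k=k,
        alphabet=alphabet,
        kmers=kmers,
        index_of={km: i for i, km in enumerate(kmers)},
    )


def rna_vocabulary(k: int = 3) -> KmerVocabulary:
    return build_vocabulary(RNA_ALPHABET, k)


def shape_vocabulary(k: int = 3, alphabet: str = SHAPE_ALPHABET) -> KmerVocabulary:
    return build_vocabulary(alphabet, k)


def tokenize(s: str, vocab: KmerVocabulary) -> np.ndarray:
    """Overlapping k-mer token indices (stride 1): token i is ``s[i:i+k]``.

    A string of length L yields exactly L - k + 1 tokens.
    """
    k = vocab.k
    if len(s) < k:
        raise ValueError(
            f"string of length {len(s)} is shorter than k-mer size {k}"
        )
    index = vocab.index_of
    try:
        return np.array([index[s[i : i + k]] for i in range(len(s) - k + 1)],
                        dtype=np.int64)
    except KeyError as exc:
        raise AlphabetError(
            f"k-mer {exc.args[0]!r} not in vocabulary over alphabet "
            f"{vocab.alphabet!r}"
        ) from exc


def tokens_to_kmers(tokens: Sequence[int], vocab: KmerVocabulary) -> list[str]:
    return [vocab.kmers[int(t)] for t in tokens]


def skipgram_pairs(tokens: np.ndarray, m: int) -> list[tuple[int, int]]:
    """All (center, context) token pairs within window ``m``.

    For each position t (ascending) and offset j in [-m, m] \\ {0}
    (ascending) that stays in bounds, one pair (tokens[t], tokens[t+j]).
    """
    if m < 1:
        raise ConfigError(f"window must be >= 1, got {m}")
    n = len(tokens)
    pairs = []
    for t in range(n):
        for j in range(-m, m + 1):
            if j == 0:
                continue
            u = t + j
            if 0 <= u < n:
                pairs.append((int(tokens[t]), int(tokens[u])))
    return pairs


@dataclass(frozen=True)
class SkipGramConfig:
    """Hyperparameters of skip-gram training.

    Defaults follow standard word2vec practice on small vocabularies:
    window 5, dimension 30, 5 negatives per positive, 10 epochs, initial
    learning rate 0.025 with linear decay, noise distribution = unigram
    frequency raised to 0.75.
    """

    window: int = 5
    dim: int = 30
    n_neg: int = 5
    lr: float = 0.025
    epochs: int = 10
    seed: int = 0
    noise_power: float = 0.75
    batch_size: int = 256

    def __post_init__(self) -> None:
        if self.window < 1 or self.dim < 1 or self.n_neg < 1:
            raise ConfigError("window, dim and n_neg must all be >= 1")
        if self.epochs < 0 or self.lr <= 0 or self.batch_size < 1:
            raise ConfigError("epochs >= 0, lr > 0, batch_size >= 1 required")


@dataclass
class KmerEmbedding:
    """Paired input/output vector matrices of a trained skip-gram model.

    ``input_vectors`` (V x d) is the downstream representation; the output
    (context) matrix is kept for inspection and continued training.
    """

    vocab: KmerVocabulary
    input_vectors: np.ndarray
    output_vectors: np.ndarray
    config: Optional[SkipGramConfig] = None

    @property
    def dim(self) -> int:
        return self.input_vectors.shape[1]

    def save(self, path: str | Path) -> None:
        """Serialise to an ``.npz`` container with vocabulary metadata."""
        meta = {
            "k": self.vocab.k,
            "alphabet": self.vocab.alphabet,
            "V": self.vocab.V,
            "d": self.dim,
        }
        if self.config is not None:
            meta["config"] = vars(self.config).copy() if not hasattr(
                self.config, "__dataclass_fields__") else {
                f: getattr(self.config, f)
                for f in self.config.__dataclass_fields__
            }
        np.savez(
            path,
            input_vectors=self.input_vectors,
            output_vectors=self.output_vectors,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path: str | Path) -> "KmerEmbedding":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"].tobytes()).decode())
            vocab = build_vocabulary(meta["alphabet"], meta["k"])
            cfg = SkipGramConfig(**meta["config"]) if "config" in meta else None
            return cls(
                vocab=vocab,
                input_vectors=data["input_vectors"],
                output_vectors=data["output_vectors"],
                config=cfg,
            )

    def export_word2vec_text(self, path: str | Path) -> None:
        """Word2vec text format: header 'V d', then one k-mer + d floats/line."""
        with open(path, "w") as fh:
            fh.write(f"{self.vocab.V} {self.dim}\n")
            for i, km in enumerate(self.vocab.kmers):
                vec = " ".join(f"{x:.6f}" for x in self.input_vectors[i])
                fh.write(f"{km} {vec}\n")


def unigram_noise_distribution(
    corpora: Iterable[np.ndarray], V: int, power: float = 0.75
) -> np.ndarray:
    """Unigram token distribution raised to ``power`` and renormalised.

    Tokens absent from the corpus get probability 0 and are never drawn as
    negatives.
    """
    counts = np.zeros(V, dtype=np.float64)
    for toks in corpora:
        np.add.at(counts, np.asarray(toks, dtype=np.int64), 1.0)
    if counts.sum() == 0:
        raise ConfigError("empty corpus: no tokens to train on")
    weights = counts**power
    return weights / weights.sum()


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500.0, 500.0)))


def sgns_pair_loss(
    input_vectors: np.ndarray,
    output_vectors: np.ndarray,
    center: int,
    context: int,
    negatives: Sequence[int],
) -> float:
    """Negative of the per-pair skip-gram objective (a loss to minimise),
    with the expectation over the noise distribution replaced by the given
    sampled negative tokens."""
    v_c = input_vectors[center]
    pos = np.log(_sigmoid(output_vectors[context] @ v_c))
    neg = np.log(_sigmoid(-(output_vectors[list(negatives)] @ v_c))).sum()
    return float(-(pos + neg))


def sgns_pair_gradients(
    input_vectors: np.ndarray,
    output_vectors: np.ndarray,
    center: int,
    context: int,
    negatives: Sequence[int],
) -> tuple[float, np.ndarray, np.ndarray]:
    """Analytic gradients of :func:`sgns_pair_loss` w.r.t. both matrices.

    Returns (loss, d_input_vectors, d_output_vectors); the gradient arrays
    are dense V x d (duplicated negative indices accumulate).
    """
    v_c = input_vectors[center]
    d_in = np.zeros_like(input_vectors)
    d_out = np.zeros_like(output_vectors)

    u_o = output_vectors[context]
    g_pos = _sigmoid(u_o @ v_c) - 1.0  # d loss / d (u_o . v_c)
    d_out[context] += g_pos * v_c
    grad_vc = g_pos * u_o

    for s in negatives:
        u_s = output_vectors[s]
        g_neg = _sigmoid(u_s @ v_c)  # d loss / d (u_s . v_c)
        d_out[s] += g_neg * v_c
        grad_vc = grad_vc + g_neg * u_s

    d_in[center] += grad_vc
    loss = sgns_pair_loss(input_vectors, output_vectors, center, context, negatives)
    return loss, d_in, d_out


def sgns_expected_objective(
    emb: KmerEmbedding,
    pairs: np.ndarray,
    noise: np.ndarray,
    n_neg: int,
) -> float:
    """Mean per-pair objective with the noise expectation computed exactly.

    Deterministic (no sampling); useful for monotone-trend checks of
    training progress.
    """
    pairs = np.asarray(pairs, dtype=np.int64)
    v = emb.input_vectors[pairs[:, 0]]  # (N, d)
    u = emb.output_vectors[pairs[:, 1]]  # (N, d)
    pos = np.log(_sigmoid(np.einsum("nd,nd->n", u, v)))
    # expectation term: for each center, sum_s noise[s] * log sigma(-u_s.v_c)
    scores = emb.output_vectors @ v.T  # (V, N)
    neg = noise @ np.log(_sigmoid(-scores))  # (N,)
    return float(np.mean(pos + n_neg * neg))


def initialize_embedding(
    vocab: KmerVocabulary, dim: int, seed: int
) -> KmerEmbedding:
    """Reference word2vec initialisation: input vectors uniform in
    (-0.5/d, 0.5/d), output vectors zero; seeded."""
    rng = np.random.default_rng(seed)
    win = (rng.random((vocab.V, dim)) - 0.5) / dim
    wout = np.zeros((vocab.V, dim))
    return KmerEmbedding(vocab=vocab, input_vectors=win, output_vectors=wout)


def train_skipgram(
    corpora: Iterable[np.ndarray],
    vocab: KmerVocabulary,
    cfg: SkipGramConfig,
    epoch_callback=None,
) -> KmerEmbedding:
    """Train skip-gram with negative sampling by SGD over all window pairs.

    ``corpora`` is one or more collections of token sequences (each a 1-D
    integer array from :func:`tokenize`).  Negatives are drawn from the
    unigram distribution raised to ``cfg.noise_power``.  The learning rate
    decays linearly over the total number of updates (floored at 1e-4 of
    the initial rate).  Fully reproducible given ``cfg.seed``; rows of
    k-mers absent from the corpus keep their initial values.
    """
    token_seqs = [np.asarray(t, dtype=np.int64) for t in corpora]
    if not token_seqs:
        raise ConfigError("corpora must contain at least one token sequence")
    for toks in token_seqs:
        if len(toks) and (toks.min() < 0 or toks.max() >= vocab.V):
            raise IndexError("token index out of vocabulary range")

    emb = initialize_embedding(vocab, cfg.dim, cfg.seed)
    if cfg.epochs == 0:
        emb.config = cfg
        return emb

    pair_list = []
    for toks in token_seqs:
        pair_list.extend(skipgram_pairs(toks, cfg.window))
    pairs = np.array(pair_list, dtype=np.int64)
    if len(pairs) == 0:
        emb.config = cfg
        return emb

    noise = unigram_noise_distribution(token_seqs, vocab.V, cfg.noise_power)
    rng = np.random.default_rng(cfg.seed)
    win, wout = emb.input_vectors, emb.output_vectors
    total = cfg.epochs * len(pairs)
    done = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(len(pairs))
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            c = pairs[idx, 0]
            o = pairs[idx, 1]
            negs = rng.choice(vocab.V, size=(len(idx), cfg.n_neg), p=noise)

            v_c = win[c]  # (b, d)
            u_o = wout[o]  # (b, d)
            u_n = wout[negs]  # (b, n, d)

            # reference word2vec clamp: scores beyond +-6 contribute no
            # gradient, which keeps highly repetitive corpora stable
            s_pos = np.einsum("bd,bd->b", u_o, v_c)
            s_neg = np.einsum("bnd,bd->bn", u_n, v_c)
            g_pos = (_sigmoid(s_pos) - 1.0) * (np.abs(s_pos) <= 6.0)  # (b,)
            g_neg = _sigmoid(s_neg) * (np.abs(s_neg) <= 6.0)  # (b, n)

            d_vc = g_pos[:, None] * u_o + np.einsum("bn,bnd->bd", g_neg, u_n)

            lr = cfg.lr * max(1e-4, 1.0 - done / total)
            # scatter-add so repeated indices within a batch accumulate
            np.add.at(win, c, -lr * d_vc)
            np.add.at(wout, o, -lr * g_pos[:, None] * v_c)
            np.add.at(
                wout,
                negs.ravel(),
                -lr * (g_neg[..., None] * v_c[:, None, :]).reshape(-1, cfg.dim),
            )
            done += len(idx)
        if epoch_callback is not None:
            epoch_callback(emb)
    if not (np.all(np.isfinite(win)) and np.all(np.isfinite(wout))):
        raise FloatingPointError("skip-gram training diverged (non-finite vectors)")
    emb.config = cfg
    return emb


def embed_tokens(tokens: np.ndarray, emb: KmerEmbedding) -> np.ndarray:
    """Look up input vectors for a token sequence -> (len(tokens), d) matrix."""
    tokens = np.asarray(tokens, dtype=np.int64)
    if len(tokens) and (tokens.min() < 0 or tokens.max() >= emb.vocab.V):
        raise IndexError("token index out of range for embedding")
    return emb.input_vectors[tokens].copy()
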
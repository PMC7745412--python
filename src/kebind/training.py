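"""Dataset splitting, classifier training, prediction, AUC and ablations.

Training minimises binary cross-entropy with Adam, early-stops on
validation AUC (the evaluation metric throughout) and restores the best
validation weights.  `run_ablation` trains the architecture variants on
identical splits, embeddings and seeds so AUC differences are attributable
to the removed component alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .embedding import (
    KmerEmbedding,
    SkipGramConfig,
    rna_vocabulary,
    shape_vocabulary,
    tokenize,
    train_skipgram,
)
from .errors import ConfigError, DatasetError
from .model import ModelConfig, Network, build_model, pad_and_mask
from .nn import Adam
from .seqio import LabeledDataset, NucleotideSequence, RNA_ALPHABET

__all__ = [
    "SplitDataset",
    "TrainConfig",
    "EvalReport",
    "EmbeddingSet",
    "split_dataset",
    "learn_embeddings",
    "train_model",
    "predict",
    "compute_auc",
    "one_hot_encode",
    "one_hot_decode",
    "run_ablation",
]


@dataclass
class SplitDataset:
    """Disjoint train/validation/test partitions of a labeled dataset."""

    train: LabeledDataset
    validation: LabeledDataset
    test: LabeledDataset
    seed: int = 0


def split_dataset(
    ds: LabeledDataset,
    val_fraction: float = 1.0 / 3.0,
    test_fraction: float = 0.0,
    seed: int = 0,
) -> SplitDataset:
    """Stratified, reproducible split.

    ``test_fraction`` of each class is held out first (0 when an external
    test set exists); ``val_fraction`` of the remainder becomes the
    validation set and the rest the training set — by default one third for
    validation and two thirds for training.
    """
    if not 0.0 < val_fraction < 1.0:
        raise ConfigError("val_fraction must be in (0, 1)")
    if not 0.0 <= test_fraction < 1.0:
        raise ConfigError("test_fraction must be in [0, 1)")
    labels = ds.labels
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    test_idx: list[int] = []
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise DatasetError(
                f"label class {cls} has {len(idx)} example(s); need >= 2 to stratify"
            )
        idx = idx[rng.permutation(len(idx))]
        n_test = int(round(test_fraction * len(idx)))
        n_val = int(round(val_fraction * (len(idx) - n_test)))
        test_idx.extend(idx[:n_test].tolist())
        val_idx.extend(idx[n_test : n_test + n_val].tolist())
        train_idx.extend(idx[n_test + n_val :].tolist())
    return SplitDataset(
        train=ds.subset(sorted(train_idx), " [train]"),
        validation=ds.subset(sorted(val_idx), " [validation]"),
        test=ds.subset(sorted(test_idx), " [test]"),
        seed=seed,
    )


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters: Adam with lr 1e-3, batches of 32,
    at most ``epochs`` passes, early stopping on validation AUC with
    ``patience`` non-improving epochs allowed.

    The small default batch suits datasets of a few hundred to a few
    thousand examples, where large batches starve training of update steps.
    """

    epochs: int = 50
    batch_size: int = 32
    lr: float = 1e-3
    weight_decay: float = 1e-3
    patience: int = 5
    seed: int = 0
    finetune_embeddings: bool = False

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.lr <= 0 or self.patience < 0:
            raise ConfigError("epochs, batch_size, lr must be positive; patience >= 0")
        if self.weight_decay < 0:
            raise ConfigError("weight_decay must be >= 0")


@dataclass
class EmbeddingSet:
    """The k-mer embeddings a model consumes (structure one optional)."""

    sequence: KmerEmbedding
    structure: Optional[KmerEmbedding] = None


@dataclass
class EvalReport:
    """Evaluation of one trained variant: AUC plus per-example scores."""

    auc: float
    per_example: list[tuple[int, float]]
    variant: str
    history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError(f"AUC {self.auc} outside [0, 1]")


def _standardize_columns(matrix: np.ndarray) -> None:
    matrix -= matrix.mean(axis=0)
    matrix /= matrix.std(axis=0) + 1e-8


def learn_embeddings(
    ds: LabeledDataset,
    cfg: Optional[SkipGramConfig] = None,
    include_structure: bool = True,
    struct_alphabet: Optional[str] = None,
    standardize: bool = True,
) -> EmbeddingSet:
    """Train skip-gram embeddings on a dataset's sequences (and shapes).

    Sequence and structure models are trained separately — their k-mer
    vocabularies are disjoint (4^k vs |shape alphabet|^k).  Pass the
    training split here to avoid test leakage into the unsupervised corpus.

    With ``standardize`` (default) each embedding dimension is z-scored
    across the vocabulary after training.  Raw skip-gram vectors are small
    and anisotropic, which conditions the downstream convolution badly; the
    per-dimension affine rescaling preserves all co-occurrence information
    while giving the classifier O(1)-scale inputs.
    """
    cfg = cfg or SkipGramConfig()
    seq_vocab = rna_vocabulary(k=3)
    seq_corpus = [tokenize(ex.sequence.residues, seq_vocab) for ex in ds]
    seq_emb = train_skipgram(seq_corpus, seq_vocab, cfg)
    struct_emb = None
    if include_structure and ds.has_shapes:
        sv = shape_vocabulary(k=3) if struct_alphabet is None else shape_vocabulary(
            k=3, alphabet=struct_alphabet)
        struct_corpus = [tokenize(ex.shape, sv) for ex in ds]
        struct_emb = train_skipgram(struct_corpus, sv, cfg)
    if standardize:
        _standardize_columns(seq_emb.input_vectors)
        if struct_emb is not None:
            _standardize_columns(struct_emb.input_vectors)
    return EmbeddingSet(sequence=seq_emb, structure=struct_emb)


def one_hot_encode(seq: NucleotideSequence | str) -> np.ndarray:
    """Identity encoding, one row per nucleotide:
    A=(1,0,0,0), C=(0,1,0,0), G=(0,0,1,0), U=(0,0,0,1)."""
    residues = seq if isinstance(seq, str) else seq.residues
    idx = np.empty(len(residues), dtype=np.int64)
    for i, ch in enumerate(residues):
        j = RNA_ALPHABET.find(ch)
        if j < 0:
            raise ConfigError(f"cannot one-hot encode residue {ch!r} at position {i + 1}")
        idx[i] = j
    return np.eye(4, dtype=np.float32)[idx]


def one_hot_decode(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode`."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != 4:
        raise ValueError("expected an (L, 4) one-hot matrix")
    return "".join(RNA_ALPHABET[j] for j in matrix.argmax(axis=1))


# ---------------------------------------------------------------------------
# Feature preparation.


def _prepare_features(
    ds: LabeledDataset,
    cfg: ModelConfig,
    embeddings: Optional[EmbeddingSet],
) -> tuple[list[np.ndarray], Optional[list[np.ndarray]], np.ndarray]:
    """Per-example input matrices for a given variant."""
    labels = ds.labels
    if cfg.variant == "one_hot":
        seq_mats = [one_hot_encode(ex.sequence) for ex in ds]
        return seq_mats, None, labels
    if embeddings is None or embeddings.sequence is None:
        raise ConfigError(f"variant {cfg.variant!r} requires a sequence embedding")
    semb = embeddings.sequence
    seq_mats = [
        semb.input_vectors[tokenize(ex.sequence.residues, semb.vocab)].astype(
            np.float32)
        for ex in ds
    ]
    struct_mats = None
    if cfg.uses_structure:
        if embeddings.structure is None:
            raise ConfigError("full variant requires a structure embedding")
        if not ds.has_shapes:
            raise DatasetError(
                "full variant requires shape strings but the dataset lacks them")
        temb = embeddings.structure
        struct_mats = [
            temb.input_vectors[tokenize(ex.shape, temb.vocab)].astype(np.float32)
            for ex in ds
        ]
    return seq_mats, struct_mats, labels


def _bce_loss(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _forward_batches(
    net: Network,
    seq_mats: Sequence[np.ndarray],
    struct_mats: Optional[Sequence[np.ndarray]],
    batch_size: int = 256,
) -> np.ndarray:
    """Deterministic (eval-mode) scores, batched for memory."""
    scores = np.empty(len(seq_mats), dtype=np.float64)
    for start in range(0, len(seq_mats), batch_size):
        sl = slice(start, start + batch_size)
        Xs, lengths = pad_and_mask(seq_mats[sl])
        Xt = None
        if struct_mats is not None:
            Xt, _ = pad_and_mask(struct_mats[sl])
        scores[sl] = net.forward(Xs, lengths, X_struct=Xt, train=False)
    return scores


def train_model(
    cfg: ModelConfig,
    tcfg: TrainConfig,
    splits: SplitDataset,
    embeddings: Optional[EmbeddingSet] = None,
) -> tuple[Network, list[dict]]:
    """Train one variant; returns the best-validation network and the
    per-epoch history (train loss, validation AUC)."""
    splits.train.require_both_classes()
    splits.validation.require_both_classes()
    tr_seq, tr_struct, tr_y = _prepare_features(splits.train, cfg, embeddings)
    va_seq, va_struct, _ = _prepare_features(splits.validation, cfg, embeddings)
    va_y = splits.validation.labels

    net = build_model(cfg)
    params = net.parameters()
    if tcfg.finetune_embeddings and cfg.variant != "one_hot":
        raise ConfigError(
            "finetune_embeddings is not supported with precomputed feature "
            "matrices; re-embed per epoch externally if needed")
    adam = Adam(lr=tcfg.lr, weight_decay=tcfg.weight_decay)
    rng = np.random.default_rng(tcfg.seed)

    history: list[dict] = []
    best_auc = -np.inf
    best_params: Optional[dict[str, np.ndarray]] = None
    bad_epochs = 0
    n = len(tr_seq)

    for epoch in range(1, tcfg.epochs + 1):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            Xs, lengths = pad_and_mask([tr_seq[i] for i in idx])
            Xt = None
            if tr_struct is not None:
                Xt, _ = pad_and_mask([tr_struct[i] for i in idx])
            y = tr_y[idx].astype(np.float64)
            p = net.forward(Xs, lengths, X_struct=Xt, train=True, rng=rng)
            losses.append(_bce_loss(p, y))
            dlogit = (p - y) / len(idx)
            grads, _, _ = net.backward(dlogit)
            adam.step(params, grads)

        val_scores = _forward_batches(net, va_seq, va_struct)
        val_auc = float(roc_auc_score(va_y, val_scores))
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_auc": val_auc}
        )
        if val_auc > best_auc:
            best_auc = val_auc
            best_params = {k: v.copy() for k, v in params.items()}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > tcfg.patience:
                break

    if best_params is not None:
        net.set_parameters(best_params)
    return net, history


def predict(
    net: Network,
    ds: LabeledDataset,
    embeddings: Optional[EmbeddingSet] = None,
    batch_size: int = 256,
) -> list[tuple[int, float]]:
    """(label, score) pairs for every example, in dataset order."""
    seq_mats, struct_mats, labels = _prepare_features(ds, net.config, embeddings)
    scores = _forward_batches(net, seq_mats, struct_mats, batch_size=batch_size)
    return [(int(y), float(s)) for y, s in zip(labels, scores)]


def compute_auc(pairs: Iterable[tuple[int, float]]) -> float:
    """Area under the ROC curve = P(score+ > score-) + 0.5 P(tie)."""
    pairs = list(pairs)
    labels = np.array([p[0] for p in pairs])
    scores = np.array([p[1] for p in pairs], dtype=np.float64)
    if len(set(labels.tolist())) < 2:
        raise DatasetError("AUC is undefined with a single class present")
    return float(roc_auc_score(labels, scores))


def run_ablation(
    ds: LabeledDataset,
    variants: Sequence[str] = ("full", "no_structure", "one_hot", "cnn_only"),
    seed: int = 0,
    test_fraction: float = 0.25,
    val_fraction: float = 1.0 / 3.0,
    sg_cfg: Optional[SkipGramConfig] = None,
    model_kwargs: Optional[dict] = None,
    train_kwargs: Optional[dict] = None,
    verbose: bool = False,
) -> list[EvalReport]:
    """Train and evaluate architecture variants under identical conditions.

    One split and one set of skip-gram embeddings (learned on the training
    partition only) are shared by all variants; each variant trains with
    the same seeds and is scored on the held-out test partition.
    """
    if "full" in variants and not ds.has_shapes:
        raise DatasetError("full variant requested but dataset has no shape strings")
    splits = split_dataset(ds, val_fraction=val_fraction,
                           test_fraction=test_fraction, seed=seed)
    model_kwargs = dict(model_kwargs or {})
    train_kwargs = dict(train_kwargs or {})
    sg = sg_cfg or SkipGramConfig(seed=seed)

    need_embeddings = any(v != "one_hot" for v in variants)
    embeddings = None
    if need_embeddings:
        embeddings = learn_embeddings(
            splits.train, cfg=sg, include_structure="full" in variants)

    reports = []
    for variant in variants:
        mk = dict(model_kwargs)
        if variant == "one_hot":
            mk["input_dim_seq"] = 4
        elif embeddings is not None:
            mk.setdefault("input_dim_seq", embeddings.sequence.dim)
            if variant == "full":
                mk.setdefault("input_dim_struct", embeddings.structure.dim)
        cfg = ModelConfig(variant=variant, seed=seed, **mk)
        tcfg = TrainConfig(seed=seed, **train_kwargs)
        net, history = train_model(cfg, tcfg, splits, embeddings)
        per_example = predict(net, splits.test, embeddings)
        auc = compute_auc(per_example)
        reports.append(EvalReport(auc=auc, per_example=per_example,
                                  variant=variant, history=history))
        if verbose:
            print(f"{variant:>12s}  AUC = {auc:.3f}  "
                  f"({len(history)} epochs)")
    return reports
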
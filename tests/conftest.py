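"""Shared fixtures.

The expensive end-to-end training runs are session-scoped so that the
learnability, null-control and ablation checks reuse one set of trained
models.  All problem sizes are desk-scale (hundreds of examples, ~100 nt)
and every source of randomness is seeded.
"""

import numpy as np
import pytest

import kebind as kb
from kebind.seqio import LabeledDataset, LabeledExample


@pytest.fixture(scope="session")
def learnability_run():
    """Full-variant model trained on strongly separable synthetic data:
    a 14-nt consensus (5% per-position mutation) implanted in a hairpin
    loop, dinucleotide-shuffle negatives, 500+500 examples of 101 nt."""
    spec = kb.SyntheticSpec(
        n_pos=500, n_neg=500, length_range=(101, 101),
        per_position_mutation_rate=0.05,
        structural_context="hairpin_loop", coupling=1.0,
        negative_mode="shuffle", seed=7,
    )
    ds, truth = kb.generate_dataset(spec)
    splits = kb.split_dataset(ds, test_fraction=0.25, seed=7)
    emb = kb.learn_embeddings(splits.train, kb.SkipGramConfig(seed=7, epochs=5))
    net, history = kb.train_model(
        kb.ModelConfig(variant="full", seed=7),
        kb.TrainConfig(epochs=20, patience=20, seed=7),
        splits, emb,
    )
    pairs = kb.predict(net, splits.test, emb)
    return {
        "spec": spec, "dataset": ds, "truth": truth, "splits": splits,
        "embeddings": emb, "net": net, "history": history,
        "test_pairs": pairs, "test_auc": kb.compute_auc(pairs),
    }


@pytest.fixture(scope="session")
def label_shuffled_run(learnability_run):
    """Same sequences with labels randomly permuted: no real signal."""
    ds = learnability_run["dataset"]
    rng = np.random.default_rng(7)
    labels = ds.labels.copy()
    rng.shuffle(labels)
    shuffled = LabeledDataset(
        [LabeledExample(ex.sequence, ex.shape, int(l)) for ex, l in zip(ds, labels)],
        provenance="label-shuffled null",
    )
    splits = kb.split_dataset(shuffled, test_fraction=0.25, seed=7)
    emb = kb.learn_embeddings(splits.train, kb.SkipGramConfig(seed=7, epochs=5))
    net, history = kb.train_model(
        kb.ModelConfig(variant="full", seed=7),
        kb.TrainConfig(epochs=8, patience=3, seed=7),
        splits, emb,
    )
    pairs = kb.predict(net, splits.test, emb)
    return {"test_auc": kb.compute_auc(pairs), "history": history}


@pytest.fixture(scope="session")
def structure_coupled_reports():
    """Ablation full-vs-no_structure where the motif is only predictive in
    its hairpin context (decoy negatives carry the motif unstructured)."""
    spec = kb.SyntheticSpec(
        n_pos=500, n_neg=500, length_range=(101, 101),
        per_position_mutation_rate=0.05,
        structural_context="hairpin_loop", coupling=1.0,
        negative_mode="decoy_motif", seed=11,
    )
    ds, _ = kb.generate_dataset(spec)
    reports = kb.run_ablation(
        ds, ["full", "no_structure"], seed=11,
        sg_cfg=kb.SkipGramConfig(seed=11, epochs=5),
        train_kwargs=dict(epochs=15, patience=15),
    )
    return {r.variant: r for r in reports}


@pytest.fixture(scope="session")
def structure_control_reports():
    """Negative control: structure strings uninformative by construction
    (coupling=0), sequence signal strong enough that both variants solve it."""
    spec = kb.SyntheticSpec(
        n_pos=500, n_neg=500, length_range=(101, 101),
        per_position_mutation_rate=0.02,
        structural_context="hairpin_loop", coupling=0.0,
        negative_mode="shuffle", seed=11,
    )
    ds, _ = kb.generate_dataset(spec)
    reports = kb.run_ablation(
        ds, ["full", "no_structure"], seed=11,
        sg_cfg=kb.SkipGramConfig(seed=11, epochs=5),
        train_kwargs=dict(epochs=30, patience=30),
    )
    return {r.variant: r for r in reports}


@pytest.fixture(scope="session")
def spaced_pair_reports():
    """Ordered spaced motif pair (gap 80-140 nt) with order-swapped
    negatives: long-range dependency that defeats order-blind pooling."""
    spec = kb.SyntheticSpec(
        n_pos=500, n_neg=500, length_range=(180, 220),
        motif="UGCAUGA", motif2="CCGGAUC", gap_range=(80, 140),
        per_position_mutation_rate=0.05,
        negative_mode="swapped_pair", seed=11,
    )
    ds, _ = kb.generate_dataset(spec)
    reports = kb.run_ablation(
        ds, ["full", "no_structure", "one_hot", "cnn_only"], seed=11,
        sg_cfg=kb.SkipGramConfig(seed=11, epochs=5),
        train_kwargs=dict(epochs=15, patience=15),
    )
    return {r.variant: r for r in reports}
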
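"""Attribute performance to the structure branch via an ablation.

The dataset is built so the motif appears in BOTH classes, but only the
positives fold it into a hairpin loop: sequence alone cannot separate the
classes, structure can.  The full model and its structure-less ablation are
trained on identical splits, embeddings and seeds.
"""

import kebind as kb

spec = kb.SyntheticSpec(
    n_pos=300, n_neg=300, length_range=(101, 101),
    per_position_mutation_rate=0.05,
    structural_context="hairpin_loop", coupling=1.0,
    negative_mode="decoy_motif",  # negatives carry the motif, unstructured
    seed=9,
)
dataset, _ = kb.generate_dataset(spec)

reports = kb.run_ablation(
    dataset, ["full", "no_structure"], seed=9,
    sg_cfg=kb.SkipGramConfig(seed=9, epochs=5),
    train_kwargs=dict(epochs=12, patience=12),
    verbose=True,
)
full, seq_only = (next(r for r in reports if r.variant == v)
                  for v in ("full", "no_structure"))
print(f"\nstructure-aware model AUC : {full.auc:.3f}")
print(f"sequence-only model AUC   : {seq_only.auc:.3f}")
print(f"structure contribution    : {full.auc - seq_only.auc:+.3f}")
# The sequence-only model hovers near chance because the motif alone is
# uninformative here; the full model reads the motif-in-hairpin signal.
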
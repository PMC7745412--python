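# kebind

Prediction of RNA-binding-protein (RBP) binding sites from RNA primary
sequence and secondary structure, using distributed k-mer representations
and a CNN + BiLSTM classifier — with the ablation variants and a synthetic
benchmark generator needed to test every claim at desk scale.

## The problem

RBPs regulate splicing, export, stability and translation by binding short
sequence motifs whose accessibility depends on the RNA's secondary
structure.  CLIP-seq experiments yield genome-wide catalogues of bound
sites; the computational task is a binary classifier: given an RNA fragment
(and optionally its structural context), predict whether the protein binds
it.  This package is for computational biologists who want a
self-contained, inspectable implementation of the k-mer-embedding +
CNN/BiLSTM approach, including the controls that attribute performance to
each component.

## The method

**Representation.** A sequence is decomposed into overlapping 3-mers
(`AUUGC → AUU, UUG, UGC`).  A skip-gram model with negative sampling learns
a dense vector per k-mer by maximising, for each (center `c`, context `o`)
pair within a window and noise samples `s_i ~ P_n`,

    log σ(u_oᵀ v_c) + Σ_i log σ(−u_{s_i}ᵀ v_c),        σ(x) = 1/(1+e^{−x})

over complete vocabularies — 4³ = 64 sequence k-mers, and 6³ = 216 (or 125
under a five-letter convention) structure k-mers.  Secondary structure
enters as a per-position *shape string* over {S stem, H hairpin, I internal
loop, M multiloop, F dangling start, T dangling end}, computed from
dot-bracket structures by an explicit loop-type annotator.

**Classifier.** Embedded sequence and shape strings pass through separate
convolution modules (kernel widths 8 and 16, ReLU, max-pool 2), are fused
channel-wise, pass a joint convolution (width 32, ReLU, max-pool 2), then a
bidirectional LSTM

    f_t = σ(W_f x_t + U_f h_{t−1} + b_f)       i_t = σ(W_i x_t + U_i h_{t−1} + b_i)
    c_t = f_t ⊙ c_{t−1} + i_t ⊙ tanh(W_c x_t + U_c h_{t−1} + b_c)
    o_t = σ(W_o x_t + U_o h_{t−1} + b_o)       h_t = o_t ⊙ tanh(c_t)

with 32 units per direction (64 concatenated output features), two fully
connected layers and a sigmoid.  Variable-length batches are zero-padded
with masking so padding never affects a prediction.  Ablation variants drop
the structure branch (`no_structure`), additionally replace embeddings with
one-hot encoding (`one_hot`), or replace the BiLSTM with global max-pooling
(`cnn_only`).  Performance is measured as AUROC.  The network and the
skip-gram trainer are implemented in NumPy with hand-written
backpropagation (Adam, binary cross-entropy), so every gradient is
inspectable and testable against finite differences.

**Synthetic benchmarks.** `kebind.synthetic` builds labeled datasets with
exact ground truth: background RNA with an implanted (noisy) consensus
motif — optionally inside a hairpin-loop context — and negatives by
Eulerian dinucleotide shuffle (composition-matched), pure background,
motif-bearing unstructured decoys, or order-swapped motif pairs.

## Worked example

`examples/04_train_and_evaluate.py` generates 500+500 synthetic sites
(101 nt, 14-nt consensus at 5% per-position mutation inside a hairpin loop,
dinucleotide-shuffle negatives), learns embeddings on the training split
and trains the full model:

```
split: 500 train / 250 val / 250 test
epoch  1  train loss 0.709  val AUC 0.469
...
epoch 13  train loss 0.578  val AUC 0.688
epoch 14  train loss 0.491  val AUC 0.843
epoch 15  train loss 0.339  val AUC 0.958
held-out test AUC: 0.949
```

Held-out AUC ≈ 0.95 means a random bound site outscores a random shuffled
decoy 95% of the time.  `examples/05_ablation_study.py` shows the structure
branch at work — on data where the motif occurs in *both* classes but only
positives fold it into a hairpin:

```
        full  AUC = 1.000  (12 epochs)
no_structure  AUC = 0.546  (12 epochs)
structure contribution    : +0.454
```

The other examples cover dataset simulation, shape-string annotation of
dot-bracket structures, and inspection of the learned k-mer space.  A thin
CLI mirrors the library (`kebind simulate / annotate / embed / train /
predict / evaluate / ablate`).

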
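"""Learn distributed 3-mer representations with skip-gram.

Each sequence is a sentence of overlapping 3-mers (AUUGC -> AUU, UUG, UGC);
skip-gram with negative sampling embeds the complete 64-kmer vocabulary in
a low-dimensional space where k-mers sharing sequence contexts sit close
together.
"""

import numpy as np

import kebind as kb
from kebind.embedding import tokens_to_kmers

spec = kb.SyntheticSpec(n_pos=100, n_neg=100, length_range=(101, 101),
                        per_position_mutation_rate=0.05, seed=1)
dataset, _ = kb.generate_dataset(spec)

vocab = kb.rna_vocabulary(k=3)
tokens = kb.tokenize("AUUGC", vocab)
print("tokenization of AUUGC:", tokens_to_kmers(tokens, vocab))
print(f"vocabulary: {vocab.V} k-mers over {vocab.alphabet!r}")

emb_set = kb.learn_embeddings(dataset, kb.SkipGramConfig(seed=1, epochs=5),
                              include_structure=False)
emb = emb_set.sequence

# nearest neighbours of a motif k-mer in embedding space
query = "UGC"  # part of the implanted consensus
q = emb.input_vectors[vocab.index_of[query]]
sims = emb.input_vectors @ q / (
    np.linalg.norm(emb.input_vectors, axis=1) * np.linalg.norm(q) + 1e-12)
order = np.argsort(-sims)
print(f"k-mers most similar to {query}:",
      [vocab.kmers[i] for i in order[1:6]])
# k-mers that co-occur with UGC inside the recurring motif context score
# highest; cosine similarity reflects shared contexts, not shared letters.
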
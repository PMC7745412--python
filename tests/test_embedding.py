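"""k-mer vocabularies, tokenization and skip-gram training."""

import numpy as np
import pytest
from scipy import stats

from kebind.embedding import (
    KmerEmbedding,
    SkipGramConfig,
    build_vocabulary,
    embed_tokens,
    initialize_embedding,
    rna_vocabulary,
    sgns_expected_objective,
    sgns_pair_gradients,
    sgns_pair_loss,
    shape_vocabulary,
    skipgram_pairs,
    tokenize,
    tokens_to_kmers,
    train_skipgram,
    unigram_noise_distribution,
)
from kebind.errors import AlphabetError, ConfigError


class TestVocabulary:
    def test_rna_3mer_vocabulary_size(self):
        assert rna_vocabulary(3).V == 64

    def test_shape_vocabulary_sizes(self):
        assert shape_vocabulary(3).V == 216
        assert shape_vocabulary(3, alphabet="FHIST").V == 125

    def test_two_letter_singletons(self):
        v = build_vocabulary("AC", 1)
        assert v.V == 2 and v.index_of == {"A": 0, "C": 1}

    def test_bijection_and_lexicographic_order(self):
        v = build_vocabulary("ACGU", 2)
        assert len(set(v.index_of.values())) == v.V == 16
        assert v.kmers[0] == "AA" and v.kmers[-1] == "UU"
        assert list(v.kmers) == sorted(v.kmers)

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ConfigError):
            build_vocabulary("AAC", 2)


class TestTokenize:
    def test_worked_sequence_example(self):
        v = rna_vocabulary(3)
        assert tokens_to_kmers(tokenize("AUUGC", v), v) == ["AUU", "UUG", "UGC"]

    def test_worked_structure_example(self):
        v = shape_vocabulary(3)
        assert tokens_to_kmers(tokenize("FHSIH", v), v) == ["FHS", "HSI", "SIH"]

    def test_token_count_is_length_minus_k_plus_one(self):
        v = rna_vocabulary(3)
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(3, 60))
            s = "".join(rng.choice(list("ACGU"), size=n))
            assert len(tokenize(s, v)) == n - 2

    def test_too_short_string_rejected(self):
        with pytest.raises(ValueError):
            tokenize("AU", rna_vocabulary(3))

    def test_foreign_character_rejected(self):
        with pytest.raises(AlphabetError):
            tokenize("ACGTN", rna_vocabulary(3))


class TestSkipgramPairs:
    def test_window_one_enumeration(self):
        pairs = skipgram_pairs(np.array([5, 8, 9]), m=1)
        assert pairs == [(5, 8), (8, 5), (8, 9), (9, 8)]

    def test_single_token_no_pairs(self):
        assert skipgram_pairs(np.array([3]), m=4) == []

    def test_window_covering_sequence_gives_all_ordered_pairs(self):
        tokens = np.arange(7)
        pairs = skipgram_pairs(tokens, m=10)
        assert len(pairs) == 7 * 6  # n(n-1) ordered pairs


class TestSgnsGradients:
    def test_analytic_gradient_matches_central_differences(self):
        rng = np.random.default_rng(0)
        V, d = 6, 4
        win = rng.normal(scale=0.3, size=(V, d))
        wout = rng.normal(scale=0.3, size=(V, d))
        center, context, negs = 1, 3, [0, 3, 5, 5]
        _, d_in, d_out = sgns_pair_gradients(win, wout, center, context, negs)
        eps = 1e-6
        for mat, grad in ((win, d_in), (wout, d_out)):
            for idx in np.ndindex(mat.shape):
                old = mat[idx]
                mat[idx] = old + eps
                lp = sgns_pair_loss(win, wout, center, context, negs)
                mat[idx] = old - eps
                lm = sgns_pair_loss(win, wout, center, context, negs)
                mat[idx] = old
                num = (lp - lm) / (2 * eps)
                if abs(num) + abs(grad[idx]) > 1e-12:
                    rel = abs(num - grad[idx]) / (abs(num) + abs(grad[idx]))
                    assert rel < 1e-5, (idx, num, grad[idx])

    def test_objective_nondecreasing_over_epochs(self):
        v = rna_vocabulary(3)
        rng = np.random.default_rng(3)
        corpus = [
            tokenize("".join(rng.choice(list("ACGU"), size=40)), v)
            for _ in range(12)
        ]
        pairs = np.array(
            [p for toks in corpus for p in skipgram_pairs(toks, 3)], dtype=np.int64
        )
        noise = unigram_noise_distribution(corpus, v.V)
        objectives = []
        cfg = SkipGramConfig(window=3, dim=8, epochs=12, lr=0.01, seed=5)
        train_skipgram(
            corpus, v, cfg,
            epoch_callback=lambda e: objectives.append(
                sgns_expected_objective(e, pairs, noise, cfg.n_neg)),
        )
        diffs = np.diff(objectives)
        assert np.all(diffs > -1e-3), objectives  # monotone up to small jitter
        assert objectives[-1] > objectives[0]

    def test_zero_epochs_returns_initialization(self):
        v = build_vocabulary("ACGU", 2)
        cfg = SkipGramConfig(dim=6, epochs=0, seed=9)
        emb = train_skipgram([np.array([0, 1, 2])], v, cfg)
        ref = initialize_embedding(v, 6, seed=9)
        np.testing.assert_array_equal(emb.input_vectors, ref.input_vectors)
        np.testing.assert_array_equal(emb.output_vectors, ref.output_vectors)

    def test_distributional_hypothesis(self):
        # tokens sharing contexts end up closer than tokens that never do:
        # A and G always precede C; U only ever neighbours U.
        v = rna_vocabulary(1)
        corpus = [tokenize("AC" * 30, v), tokenize("GC" * 30, v),
                  tokenize("U" * 60, v)]
        emb = train_skipgram(corpus, v, SkipGramConfig(window=1, dim=8,
                                                       epochs=20, seed=2))
        a, g, u = (emb.input_vectors[v.index_of[ch]] for ch in "AGU")

        def cos(x, y):
            return float(x @ y / (np.linalg.norm(x) * np.linalg.norm(y)))

        assert cos(a, g) > cos(a, u)

    def test_training_is_reproducible(self):
        v = rna_vocabulary(3)
        rng = np.random.default_rng(4)
        corpus = [tokenize("".join(rng.choice(list("ACGU"), size=30)), v)
                  for _ in range(5)]
        cfg = SkipGramConfig(dim=6, epochs=3, seed=11)
        e1 = train_skipgram(corpus, v, cfg)
        e2 = train_skipgram(corpus, v, cfg)
        np.testing.assert_array_equal(e1.input_vectors, e2.input_vectors)


class TestNoiseDistribution:
    def test_matches_unigram_power_law(self):
        v = build_vocabulary("ACGU", 1)
        corpus = [np.array([0] * 80 + [1] * 40 + [2] * 10)]
        noise = unigram_noise_distribution(corpus, v.V, power=0.75)
        expected = np.array([80.0, 40.0, 10.0, 0.0]) ** 0.75
        expected[3] = 0.0
        expected /= expected.sum()
        np.testing.assert_allclose(noise, expected)

    def test_sampler_draws_match_distribution(self):
        v = build_vocabulary("ACGU", 1)
        corpus = [np.array([0] * 500 + [1] * 300 + [2] * 150 + [3] * 50)]
        noise = unigram_noise_distribution(corpus, v.V, power=0.75)
        rng = np.random.default_rng(0)
        n = 100_000
        draws = rng.choice(v.V, size=n, p=noise)
        counts = np.bincount(draws, minlength=v.V)
        chi2, p = stats.chisquare(counts, noise * n)
        assert p > 1e-3  # draws consistent with the specified noise law


class TestEmbedTokens:
    def test_shape_and_lookup(self):
        v = rna_vocabulary(3)
        emb = initialize_embedding(v, 10, seed=0)
        tokens = tokenize("AUUGC", v)
        mat = embed_tokens(tokens, emb)
        assert mat.shape == (3, 10)
        np.testing.assert_array_equal(mat[0], emb.input_vectors[tokens[0]])

    def test_repeated_token_identical_rows(self):
        v = rna_vocabulary(3)
        emb = initialize_embedding(v, 5, seed=1)
        mat = embed_tokens(tokenize("AAAAA", v), emb)
        np.testing.assert_array_equal(mat[0], mat[1])
        np.testing.assert_array_equal(mat[1], mat[2])

    def test_out_of_range_index_rejected(self):
        v = build_vocabulary("AC", 1)
        emb = initialize_embedding(v, 4, seed=0)
        with pytest.raises(IndexError):
            embed_tokens(np.array([0, 5]), emb)


class TestSerialization:
    def test_npz_round_trip(self, tmp_path):
        v = rna_vocabulary(3)
        emb = train_skipgram(
            [tokenize("ACGUACGUACGU", v)], v,
            SkipGramConfig(dim=5, epochs=2, seed=3))
        p = tmp_path / "emb.npz"
        emb.save(p)
        back = KmerEmbedding.load(p)
        np.testing.assert_array_equal(back.input_vectors, emb.input_vectors)
        assert back.vocab.kmers == v.kmers
        assert back.config == emb.config

    def test_word2vec_text_export(self, tmp_path):
        v = build_vocabulary("AC", 1)
        emb = initialize_embedding(v, 3, seed=0)
        p = tmp_path / "emb.txt"
        emb.export_word2vec_text(p)
        lines = p.read_text().strip().splitlines()
        assert lines[0] == "2 3"
        assert lines[1].split()[0] == "A" and len(lines[1].split()) == 4
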
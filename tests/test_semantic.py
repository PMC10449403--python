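import itertools

import numpy as np
import pytest

from scenebound import DescriptionCorpus, EmbeddingTable
from scenebound.semantic import (
    EmptyCorpusError,
    OOVError,
    aggregate_semantic_features,
    description_length,
    lexical_entropy,
    mean_pairwise_distance,
    semantic_feature_table,
    tokenize,
)

SENTENCE = "The quick brown fox jumps over the lazy dog"


def pairwise_oracle(descriptions, emb, count_only=False):
    """Brute-force nested-loop mean cosine distance (independent of the
    vectorized implementation)."""
    per_desc, n_pairs = [], 0
    for d in descriptions:
        toks = [w for w in tokenize(d) if w in emb]
        dists = []
        for w1, w2 in itertools.combinations(toks, 2):
            v1, v2 = emb.vector(w1), emb.vector(w2)
            cos = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            dists.append(1.0 - cos)
        n_pairs += len(dists)
        if dists:
            per_desc.append(sum(dists) / len(dists))
    if count_only:
        return n_pairs
    return sum(per_desc) / len(per_desc)


class TestTokenize:
    def test_worked_example_keeps_seven_tokens(self):
        assert tokenize(SENTENCE) == [
            "quick", "brown", "fox", "jumps", "over", "lazy", "dog",
        ]

    def test_empty_string(self):
        assert tokenize("") == []

    def test_punctuation_case_and_stopwords(self):
        assert tokenize("A dog, a DOG!") == ["dog", "dog"]

    def test_hyphenated_words_split(self):
        assert tokenize("sun-lit rooftop") == ["sun", "lit", "rooftop"]


class TestDescriptionLength:
    @pytest.mark.parametrize(
        "text, n", [(SENTENCE, 9), ("", 0), ("dog", 1)]
    )
    def test_raw_whitespace_count(self, text, n):
        assert description_length(text) == n


class TestLexicalEntropy:
    def test_single_type_is_zero(self):
        assert lexical_entropy(["dog."] * 100) == 0.0

    def test_two_balanced_types_give_one_bit(self):
        assert lexical_entropy(["cat dog", "dog cat"]) == pytest.approx(1.0)

    def test_hand_computed_histogram(self):
        # pooled counts {walrus: 2, seal: 1, otter: 1} -> 1.5 bits
        assert lexical_entropy(["walrus walrus seal", "otter."]) == pytest.approx(1.5)

    def test_order_invariance(self):
        descs = ["red barn door", "old red tractor", "barn cat"]
        assert lexical_entropy(descs) == lexical_entropy(descs[::-1])

    def test_new_unique_token_flattens_histogram(self):
        base = lexical_entropy(["dog dog cat", "dog bird"])
        flat = lexical_entropy(["dog fish cat", "dog bird"])
        assert flat > base

    def test_stopword_only_corpus_rejected(self):
        with pytest.raises(EmptyCorpusError):
            lexical_entropy(["the and of", "a the"])


class TestMeanPairwiseDistance:
    def test_seven_tokens_contribute_21_pairs(self, basis_embeddings):
        assert pairwise_oracle([SENTENCE], basis_embeddings, count_only=True) == 21
        # all basis vectors are mutually orthogonal: every pair distance is 1
        assert mean_pairwise_distance([SENTENCE], basis_embeddings) == pytest.approx(1.0)

    def test_pair_count_law(self, basis_embeddings):
        words = ["quick", "brown", "fox", "jumps", "lazy"]
        for k in range(2, 6):
            text = " ".join(words[:k])
            assert pairwise_oracle([text], basis_embeddings, count_only=True) == (
                k * (k - 1) // 2
            )

    def test_identical_vectors_give_zero(self):
        emb = EmbeddingTable({"dog": [1.0, 0.0], "hound": [2.0, 0.0]})
        assert mean_pairwise_distance(["dog hound dog"], emb) == pytest.approx(0.0)

    def test_orthogonal_pair_gives_one(self):
        emb = EmbeddingTable({"dog": [1.0, 0.0], "sky": [0.0, 3.0]})
        assert mean_pairwise_distance(["dog sky"], emb) == pytest.approx(1.0)

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(11)
        vocab = [f"word{i}" for i in range(12)]
        emb = EmbeddingTable({w: rng.normal(size=8) for w in vocab})
        descs = [
            " ".join(rng.choice(vocab, size=rng.integers(2, 8)))
            for _ in range(25)
        ]
        assert mean_pairwise_distance(descs, emb) == pytest.approx(
            pairwise_oracle(descs, emb), abs=1e-12
        )

    def test_range_invariant(self):
        rng = np.random.default_rng(5)
        vocab = [f"w{i}" for i in range(20)]
        emb = EmbeddingTable({w: rng.normal(size=6) for w in vocab})
        descs = [" ".join(rng.choice(vocab, size=5)) for _ in range(30)]
        assert 0.0 <= mean_pairwise_distance(descs, emb) <= 2.0

    def test_oov_pairs_skipped(self, basis_embeddings):
        # "zebra" is OOV: only the quick-fox pair remains
        val = mean_pairwise_distance(["quick zebra fox"], basis_embeddings)
        assert val == pytest.approx(1.0)

    def test_no_valid_pairs_rejected(self, basis_embeddings):
        with pytest.raises(EmptyCorpusError):
            mean_pairwise_distance(["zebra yak", "gnu"], basis_embeddings)

    def test_oov_lookup_signals(self, basis_embeddings):
        with pytest.raises(OOVError):
            basis_embeddings.vector("zebra")


class TestAggregate:
    def test_median_lengths(self, basis_embeddings):
        corpus = DescriptionCorpus(
            "img1", ("quick fox dog", "lazy dog fox brown over", "dog brown fox jumps quick lazy over")
        )
        feats = aggregate_semantic_features(corpus, basis_embeddings)
        assert feats.median_length == 5.0  # [3, 5, 7]

    def test_even_count_median_averages_middle_two(self, basis_embeddings):
        corpus = DescriptionCorpus(
            "img2",
            (
                "quick fox dog",
                "lazy dog fox brown over",
                "dog brown fox jumps quick lazy over",
                "dog brown fox jumps quick lazy over fox dog",
            ),
        )
        assert aggregate_semantic_features(corpus, basis_embeddings).median_length == 6.0

    def test_deterministic(self, basis_embeddings):
        corpus = DescriptionCorpus("img3", ("quick brown fox", "lazy dog over fox"))
        a = aggregate_semantic_features(corpus, basis_embeddings)
        b = aggregate_semantic_features(corpus, basis_embeddings)
        assert a == b

    def test_table_drops_starved_images_with_warning(self, basis_embeddings):
        good = DescriptionCorpus("good", ("quick brown fox", "lazy dog fox"))
        starved = DescriptionCorpus("starved", ("zebra yak", "gnu emu"))
        with pytest.warns(UserWarning, match="starved"):
            table = semantic_feature_table([good, starved], basis_embeddings)
        assert table["image_id"].tolist() == ["good"]
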
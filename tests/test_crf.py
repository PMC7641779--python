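"""CRF core: exact inference vs brute force, gradient vs finite differences,
training determinism and descent."""

import itertools
import math

import numpy as np
import pytest

from pgxkit.corpus import tokenize
from pgxkit.ner import (
    CRFModel,
    LookupEncoder,
    TrainConfig,
    load_model,
    log_partition,
    save_model,
    sequence_log_likelihood,
    train_crf,
    viterbi_decode,
    viterbi_decode_dense,
)
from pgxkit.ner.crf import emission_matrix, gradient, objective_and_gradient
from pgxkit.ner.features import extract_features
from pgxkit.ner.tagger import token_sequence_from_tokens


# -- brute-force oracles ----------------------------------------------------

def enumerate_scores(E, T):
    """Score of every tag sequence, by exhaustive enumeration."""
    N, L = E.shape
    out = {}
    for y in itertools.product(range(L), repeat=N):
        s = sum(E[t, y[t]] for t in range(N))
        s += sum(T[y[t - 1], y[t]] for t in range(1, N))
        out[y] = s
    return out


def brute_log_partition(E, T):
    scores = np.array(list(enumerate_scores(E, T).values()))
    m = scores.max()
    return m + math.log(np.exp(scores - m).sum())


def brute_viterbi(E, T):
    """Lexicographically smallest argmax sequence (itertools.product order is lexicographic)."""
    scores = enumerate_scores(E, T)
    best = max(scores.values())
    for y in sorted(scores):
        if scores[y] >= best - 1e-12:
            return list(y), scores[y]


def make_random_model(rng, n_labels, n_features, scale=1.0):
    labels = tuple(f"L{i}" for i in range(n_labels))
    feature_index = {f"f{i}": i for i in range(n_features)}
    w = rng.normal(scale=scale, size=n_features * n_labels + n_labels * n_labels)
    return CRFModel(labels=labels, feature_index=feature_index, weights=w)


def random_featurized(rng, n_positions, n_features):
    return [
        np.asarray(
            sorted(rng.choice(n_features, size=rng.integers(1, min(4, n_features + 1)),
                              replace=False)),
            dtype=np.int64,
        )
        for _ in range(n_positions)
    ]


class TestLogPartition:
    def test_zero_weights_two_tokens_two_labels(self):
        m = CRFModel(labels=("A", "B"), feature_index={"f": 0}, weights=np.zeros(2 + 4))
        seq = [np.array([0]), np.array([0])]
        assert log_partition(m, seq) == pytest.approx(math.log(4))

    @pytest.mark.parametrize("n,L", [(1, 2), (3, 2), (4, 3), (5, 4)])
    def test_zero_weights_closed_form(self, n, L):
        m = CRFModel(labels=tuple(f"L{i}" for i in range(L)), feature_index={"f": 0},
                     weights=np.zeros(L + L * L))
        seq = [np.array([0])] * n
        assert log_partition(m, seq) == pytest.approx(n * math.log(L))

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            L = int(rng.integers(2, 4))
            N = int(rng.integers(1, 5))
            m = make_random_model(rng, L, 5)
            seq = random_featurized(rng, N, 5)
            E = emission_matrix(m, seq)
            assert log_partition(m, seq) == pytest.approx(
                brute_log_partition(E, m.transition_weights), abs=1e-8
            )

    def test_empty_sequence_rejected(self):
        m = make_random_model(np.random.default_rng(0), 2, 3)
        with pytest.raises(ValueError):
            log_partition(m, [])


class TestLogLikelihood:
    def test_zero_weights_uniform(self):
        m = CRFModel(labels=("A", "B"), feature_index={"f": 0}, weights=np.zeros(2 + 4))
        seq = [np.array([0])] * 3
        for tags in (["A", "A", "A"], ["B", "A", "B"]):
            assert sequence_log_likelihood(m, seq, tags) == pytest.approx(-3 * math.log(2))

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            L, N = int(rng.integers(2, 4)), int(rng.integers(1, 5))
            m = make_random_model(rng, L, 4)
            seq = random_featurized(rng, N, 4)
            total = sum(
                math.exp(sequence_log_likelihood(m, seq, [m.labels[i] for i in y]))
                for y in itertools.product(range(L), repeat=N)
            )
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_loglik_never_positive(self):
        rng = np.random.default_rng(3)
        m = make_random_model(rng, 3, 4)
        seq = random_featurized(rng, 4, 4)
        for y in itertools.product(range(3), repeat=4):
            assert sequence_log_likelihood(m, seq, [m.labels[i] for i in y]) <= 1e-12

    def test_gold_only_feature_weight_raises_likelihood(self):
        """Boosting a feature that fires only at gold-tagged positions helps the gold."""
        labels = ("A", "B")
        feature_index = {"gold": 0, "other": 1}
        seq = [np.array([0]), np.array([1])]
        tags = ["A", "B"]
        w = np.zeros(2 * 2 + 4)
        m = CRFModel(labels=labels, feature_index=feature_index, weights=w.copy())
        base = sequence_log_likelihood(m, seq, tags)
        w2 = w.copy()
        w2[0 * 2 + 0] = 2.0  # feature "gold" with label A
        m2 = CRFModel(labels=labels, feature_index=feature_index, weights=w2)
        assert sequence_log_likelihood(m2, seq, tags) > base

    def test_unknown_tag_rejected(self):
        m = make_random_model(np.random.default_rng(0), 2, 3)
        with pytest.raises(ValueError, match="not in the model's label set"):
            sequence_log_likelihood(m, random_featurized(np.random.default_rng(1), 2, 3),
                                    ["L0", "Z9"])


class TestGradient:
    def test_matches_central_finite_differences(self):
        rng = np.random.default_rng(11)
        cfg = TrainConfig(l2_sigma=5.0)
        m = make_random_model(rng, 3, 4, scale=0.5)
        batch = []
        for _ in range(3):
            seq = random_featurized(rng, int(rng.integers(1, 5)), 4)
            tags = [m.labels[i] for i in rng.integers(0, 3, size=len(seq))]
            batch.append((seq, tags))
        g = gradient(m, batch, cfg)
        w0 = m.weights.copy()
        eps = 1e-6
        for k in range(0, len(w0), 3):  # probe a third of the coordinates
            m.weights = w0.copy(); m.weights[k] += eps
            hi, _ = objective_and_gradient(m, batch, cfg)
            m.weights = w0.copy(); m.weights[k] -= eps
            lo, _ = objective_and_gradient(m, batch, cfg)
            fd = (hi - lo) / (2 * eps)
            denom = max(1.0, abs(fd))
            assert abs(g[k] - fd) / denom < 1e-5
        m.weights = w0

    def test_single_token_logistic_case(self):
        """One token, one feature, two labels: gradient is (marginal - indicator)."""
        labels = ("A", "B")
        w = np.array([1.0, -0.5, 0, 0, 0, 0])  # emission f*A=1, f*B=-0.5; T=0
        m = CRFModel(labels=labels, feature_index={"f": 0}, weights=w)
        cfg = TrainConfig(l2_sigma=1e6)  # negligible prior
        seq = [np.array([0])]
        g = gradient(m, [(seq, ["A"])], cfg)
        pA = math.exp(1.0) / (math.exp(1.0) + math.exp(-0.5))
        assert g[0] == pytest.approx(pA - 1.0, abs=1e-9)
        assert g[1] == pytest.approx((1 - pA) - 0.0, abs=1e-9)

    def test_gradient_small_at_tightly_trained_optimum(self):
        seqs = [
            (token_sequence_from_tokens(["a", "b"]), ["X", "Y"]),
            (token_sequence_from_tokens(["b", "a"]), ["Y", "X"]),
        ]
        tagger = train_crf(seqs, TrainConfig(l2_sigma=2.0, max_iterations=500, tolerance=1e-14))
        feats = [
            [tagger.extractor.extract(seq, i) for i in range(len(seq))]
            for seq, _ in seqs
        ]
        batch = [
            (tagger.model.featurize(f), tags) for f, (_, tags) in zip(feats, seqs)
        ]
        g = gradient(tagger.model, batch, TrainConfig(l2_sigma=2.0))
        assert np.abs(g).max() < 1e-3


class TestViterbi:
    def test_zero_weights_tie_breaks_to_first_label(self):
        m = CRFModel(labels=("A", "B"), feature_index={"f": 0}, weights=np.zeros(2 + 4))
        tags, score = viterbi_decode(m, [np.array([0])] * 4)
        assert tags == ["A"] * 4 and score == 0.0

    def test_matches_brute_force_with_tie_breaking(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            L, N = int(rng.integers(2, 4)), int(rng.integers(1, 5))
            m = make_random_model(rng, L, 5)
            seq = random_featurized(rng, N, 5)
            E = emission_matrix(m, seq)
            expected_path, expected_score = brute_viterbi(E, m.transition_weights)
            tags, score = viterbi_decode(m, seq)
            assert [m.labels.index(t) for t in tags] == expected_path
            assert score == pytest.approx(expected_score, abs=1e-8)

    def test_dominant_emission_wins(self):
        labels = ("B-Drug", "O")
        feature_index = {"0:lower=trametinib": 0, "bias": 1}
        w = np.zeros(2 * 2 + 4)
        w[0 * 2 + 0] = 10.0  # trametinib feature -> B-Drug
        m = CRFModel(labels=labels, feature_index=feature_index, weights=w)
        seq = tokenize("take trametinib daily")
        feats = m.featurize([extract_features(seq, i) for i in range(3)])
        tags, _ = viterbi_decode(m, feats)
        assert tags[1] == "B-Drug"

    def test_dense_encoder_path(self):
        """The LookupEncoder + dense Viterbi route decodes like the feature path."""
        labels = ("B-Drug", "O")
        enc = LookupEncoder(table={"trametinib": {"B-Drug": 5.0}})
        seq = tokenize("take trametinib daily")
        E = enc.emissions(seq, labels)
        path, score = viterbi_decode_dense(E, np.zeros((2, 2)))
        assert path[1] == labels.index("B-Drug")
        assert score == pytest.approx(5.0)


class TestTraining:
    corpus = [
        (token_sequence_from_tokens(["trametinib", "treats", "melanoma"]),
         ["B-Drug", "O", "B-Disease"]),
        (token_sequence_from_tokens(["dabrafenib", "treats", "melanoma"]),
         ["B-Drug", "O", "B-Disease"]),
        (token_sequence_from_tokens(["take", "2", "mg", "daily"]),
         ["O", "B-Daily_Dose", "I-Daily_Dose", "O"]),
    ]

    def test_same_seed_identical_weights(self):
        cfg = TrainConfig(seed=9, max_iterations=50)
        a = train_crf(self.corpus, cfg)
        b = train_crf(self.corpus, cfg)
        assert np.array_equal(a.model.weights, b.model.weights)

    def test_objective_descends(self):
        cfg = TrainConfig(max_iterations=50)
        tagger = train_crf(self.corpus, cfg)
        feats = [
            tagger.model.featurize(
                [tagger.extractor.extract(seq, i) for i in range(len(seq))]
            )
            for seq, _ in self.corpus
        ]
        batch = [(f, list(tags)) for f, (_, tags) in zip(feats, self.corpus)]
        final, _ = objective_and_gradient(tagger.model, batch, cfg)
        zero = tagger.model.weights * 0
        m0 = CRFModel(labels=tagger.model.labels, feature_index=tagger.model.feature_index,
                      weights=zero)
        initial, _ = objective_and_gradient(m0, batch, cfg)
        assert final <= initial

    def test_fits_training_data(self):
        tagger = train_crf(self.corpus, TrainConfig(max_iterations=100))
        for seq, tags in self.corpus:
            assert tagger.tag(seq) == list(tags)

    def test_single_tag_corpus_rejected(self):
        degenerate = [(token_sequence_from_tokens(["a", "b"]), ["O", "O"])]
        with pytest.raises(ValueError, match="degenerate"):
            train_crf(degenerate)

    def test_model_file_round_trip(self):
        tagger = train_crf(self.corpus, TrainConfig(max_iterations=50))
        restored = load_model(save_model(tagger))
        assert restored.model.labels == tagger.model.labels
        assert restored.model.feature_index == tagger.model.feature_index
        assert np.array_equal(restored.model.weights, tagger.model.weights)
        seq = token_sequence_from_tokens(["vemurafenib", "treats", "melanoma"])
        assert restored.tag(seq) == tagger.tag(seq)
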
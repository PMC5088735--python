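"""Linear-chain CRF: scoring, decoding, marginals, training."""

import itertools

import numpy as np
import pytest

from disner.corpus import BIO_LABELS
from disner.crf import CRFTagger, score_sequence, token_marginals, train_crf, viterbi_decode


def _random_model(rng, T, n_feats=5, scale=2.0):
    sent = [{f"f{rng.integers(n_feats)}": "v", "bias": "1"} for _ in range(T)]
    model = CRFTagger()
    model.feature_index_ = model._index_features([sent])
    model.W_ = rng.normal(0, scale, (len(model.feature_index_), 3))
    model.T_ = rng.normal(0, scale, (3, 3))
    return model, sent


def _enumerate(model, sent):
    """Brute-force best path, log-partition and per-token marginals."""
    T = len(sent)
    best_path, best_score = None, -np.inf
    logZ = -np.inf
    scores = {}
    for path in itertools.product(BIO_LABELS, repeat=T):
        s = score_sequence(model, sent, list(path))
        scores[path] = s
        logZ = np.logaddexp(logZ, s)
        if s > best_score + 1e-12:
            best_score, best_path = s, path
    marg = np.zeros((T, 3))
    for path, s in scores.items():
        p = np.exp(s - logZ)
        for t, lab in enumerate(path):
            marg[t, BIO_LABELS.index(lab)] += p
    return list(best_path), logZ, marg


class TestScoreSequence:
    def test_zero_weights_score_zero(self):
        rng = np.random.default_rng(0)
        model, sent = _random_model(rng, 3)
        model.W_[:] = 0.0
        model.T_[:] = 0.0
        for path in itertools.product(BIO_LABELS, repeat=3):
            assert score_sequence(model, sent, list(path)) == 0.0

    def test_single_active_feature(self):
        model = CRFTagger()
        sent = [{"w": "pain"}]
        model.feature_index_ = {"w=pain": 0}
        model.W_ = np.array([[1.0, 0.0, 0.0]])
        model.T_ = np.zeros((3, 3))
        assert score_sequence(model, sent, ["B"]) == 1.0
        assert score_sequence(model, sent, ["O"]) == 0.0

    def test_unknown_label_raises(self):
        model, sent = _random_model(np.random.default_rng(0), 2)
        with pytest.raises(ValueError):
            score_sequence(model, sent, ["B", "X"])

    def test_matches_independent_resummation(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            model, sent = _random_model(rng, int(rng.integers(1, 5)))
            labels = [BIO_LABELS[i] for i in rng.integers(0, 3, len(sent))]
            expected = 0.0
            idx = model.feature_index_
            for fmap, lab in zip(sent, labels):
                li = BIO_LABELS.index(lab)
                for k, v in fmap.items():
                    expected += model.W_[idx[f"{k}={v}"], li]
            for a, b in zip(labels[:-1], labels[1:]):
                expected += model.T_[BIO_LABELS.index(a), BIO_LABELS.index(b)]
            assert score_sequence(model, sent, labels) == pytest.approx(expected)


class TestViterbi:
    def test_single_token_emission(self):
        model = CRFTagger()
        model.feature_index_ = {"w=x": 0}
        model.W_ = np.array([[0.0, 0.0, 2.0]])
        model.T_ = np.zeros((3, 3))
        assert viterbi_decode(model, [{"w": "x"}]) == ["O"]

    def test_empty_sentence(self):
        model, _ = _random_model(np.random.default_rng(0), 1)
        assert model.predict([[]]) == [[]]

    def test_agrees_with_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            model, sent = _random_model(rng, int(rng.integers(1, 7)))
            expected, _, _ = _enumerate(model, sent)
            assert viterbi_decode(model, sent) == expected

    def test_negative_transition_forbids_i_runs(self):
        model = CRFTagger()
        model.feature_index_ = {"w=x": 0}
        model.W_ = np.array([[0.0, 1.0, 0.0]])  # every token prefers I
        model.T_ = np.zeros((3, 3))
        model.T_[1, 1] = -100.0  # I -> I forbidden
        labels = viterbi_decode(model, [{"w": "x"}] * 5)
        assert "II" not in "".join(labels)


class TestMarginals:
    def test_uniform_at_zero_weights(self):
        model = CRFTagger()
        model.feature_index_ = {"w=x": 0}
        model.W_ = np.zeros((1, 3))
        model.T_ = np.zeros((3, 3))
        marg = token_marginals(model, [{"w": "x"}] * 4)
        assert np.allclose(marg, 1 / 3)

    def test_rows_sum_to_one_and_match_enumeration(self):
        rng = np.random.default_rng(13)
        for _ in range(15):
            model, sent = _random_model(rng, int(rng.integers(1, 7)))
            marg = token_marginals(model, sent)
            assert np.allclose(marg.sum(axis=1), 1.0, atol=1e-9)
            _, _, expected = _enumerate(model, sent)
            assert np.allclose(marg, expected, atol=1e-9)

    def test_stable_at_large_weights(self):
        model = CRFTagger()
        model.feature_index_ = {"w=x": 0}
        model.W_ = np.array([[50.0, -50.0, 0.0]])
        model.T_ = np.full((3, 3), 40.0)
        marg = token_marginals(model, [{"w": "x"}] * 6)
        assert np.all(np.isfinite(marg))
        assert np.allclose(marg.sum(axis=1), 1.0, atol=1e-9)


class TestTraining:
    def test_empty_corpus_raises(self):
        with pytest.raises(ValueError):
            train_crf([])

    def test_separable_corpus_reaches_perfect_decode(self):
        corpus = [([{"u": lab} for lab in ["B", "I", "O"]], ["B", "I", "O"])
                  for _ in range(5)]
        model = train_crf(corpus, c2=0.01)
        assert model.predict([corpus[0][0]])[0] == ["B", "I", "O"]

    def test_gradient_matches_finite_differences(self):
        sent = [{"w": "a", "s": "x"}, {"w": "b"}, {"w": "a", "s": "y"}]
        labs = ["B", "I", "O"]
        model = CRFTagger(c2=0.5)
        model.feature_index_ = model._index_features([sent])
        n = len(model.feature_index_)
        theta = np.random.default_rng(1).normal(0, 1, n * 3 + 9)
        _, grad = model.nll_and_grad([sent], [labs], theta)
        eps = 1e-6
        for i in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            num = (model.nll_and_grad([sent], [labs], tp)[0]
                   - model.nll_and_grad([sent], [labs], tm)[0]) / (2 * eps)
            rel = abs(grad[i] - num) / max(abs(grad[i]) + abs(num), 1e-8)
            assert rel < 1e-5

    def test_training_deterministic(self):
        corpus = [([{"u": lab, "p": str(i % 2)} for lab in ["B", "I", "O"]],
                   ["B", "I", "O"]) for i in range(4)]
        m1 = train_crf(corpus, c2=1.0, max_iter=50)
        m2 = train_crf(corpus, c2=1.0, max_iter=50)
        assert np.array_equal(m1.W_, m2.W_) and np.array_equal(m1.T_, m2.T_)

    def test_likelihood_monotone_in_regularization(self):
        """At the optimum, the unpenalized training NLL is non-decreasing
        in the regularization strength."""
        rng = np.random.default_rng(3)
        corpus = []
        for _ in range(8):
            T = int(rng.integers(2, 5))
            labs = [BIO_LABELS[i] for i in rng.integers(0, 3, T)]
            corpus.append(([{"w": f"t{rng.integers(4)}"} for _ in range(T)], labs))
        nlls = []
        for c2 in (0.1, 1.0, 10.0):
            model = train_crf(corpus, c2=c2, max_iter=200)
            theta = np.concatenate([model.W_.ravel(), model.T_.ravel()])
            raw_nll = model.nll_and_grad([fm for fm, _ in corpus],
                                         [lb for _, lb in corpus], theta)[0]
            raw_nll -= 0.5 * c2 * float(theta @ theta)
            nlls.append(raw_nll)
        assert nlls[0] <= nlls[1] + 1e-6 <= nlls[2] + 2e-6
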
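"""Softmax/CRF decoding and the recall-weighted loss."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from deidseq._autograd import Tensor
from deidseq.corpus_io import LabelIndex, bioes_decode
from deidseq.decoding import (
    NEG,
    CrfParams,
    LossConfig,
    bioes_transition_mask,
    count_fn_tp,
    crf_log_likelihood,
    crf_viterbi,
    recall_penalty,
    recall_weighted_loss,
    softmax_cross_entropy,
    softmax_decode,
)


def enumerate_scores(emis, params):
    """Independent brute-force path scores (plain loops over all k^n paths)."""
    W, bs, be = params.effective()
    n, k = emis.shape
    scores = {}
    for y in itertools.product(range(k), repeat=n):
        s = bs[y[0]] + emis[0, y[0]]
        for t in range(1, n):
            s += W[y[t - 1], y[t]] + emis[t, y[t]]
        scores[y] = s + be[y[-1]]
    return scores


class TestSoftmax:
    def test_uniform_row(self):
        q, _ = softmax_decode(np.zeros((1, 5)))
        np.testing.assert_allclose(q, 0.2)

    def test_hand_arithmetic(self):
        q, path = softmax_decode(np.array([[math.log(2.0), 0.0]]))
        np.testing.assert_allclose(q[0], [2 / 3, 1 / 3])
        assert path[0] == 0

    def test_shift_invariance_and_tie_break(self):
        r = np.array([[1.0, 3.0, 3.0]])
        q1, p1 = softmax_decode(r)
        q2, p2 = softmax_decode(r + 100.0)
        np.testing.assert_allclose(q1, q2)
        assert p1[0] == p2[0] == 1  # lowest id among tied maxima

    def test_rows_normalize(self, rng):
        q, _ = softmax_decode(rng.normal(size=(7, 4)))
        np.testing.assert_allclose(q.sum(axis=1), 1.0, atol=1e-9)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            softmax_decode(np.array([[np.inf, 0.0]]))


class TestCrf:
    def test_single_token_reduces_to_softmax(self):
        emis = np.array([[1.3, -0.4]])
        params = CrfParams(2)
        params.W.data[:] = 0.0
        loss = crf_log_likelihood(emis, np.array([0]), params).item()
        q, _ = softmax_decode(emis)
        assert loss == pytest.approx(-math.log(q[0, 0]), abs=1e-12)

    def test_forward_partition_matches_enumeration(self, rng):
        for _ in range(30):
            n, k = int(rng.integers(1, 6)), int(rng.integers(2, 5))
            emis = rng.normal(0, 2, (n, k))
            params = CrfParams(k, rng)
            scores = enumerate_scores(emis, params)
            logZ = np.logaddexp.reduce(list(scores.values()))
            gold = np.array(max(scores, key=scores.get))
            nll = crf_log_likelihood(emis, gold, params).item()
            assert nll == pytest.approx(logZ - scores[tuple(gold)], rel=1e-10)

    def test_viterbi_matches_enumeration(self, rng):
        for _ in range(30):
            n, k = int(rng.integers(1, 6)), int(rng.integers(2, 5))
            emis = rng.normal(0, 2, (n, k))
            params = CrfParams(k, rng)
            scores = enumerate_scores(emis, params)
            best = max(scores, key=scores.get)
            path, score = crf_viterbi(emis, params)
            assert tuple(path) == best
            assert score == pytest.approx(scores[best])

    def test_certain_gold_path_has_zero_loss(self):
        emis = np.full((3, 3), NEG)
        gold = np.array([0, 2, 1])
        emis[np.arange(3), gold] = 0.0
        params = CrfParams(3)
        params.W.data[:] = 0.0
        assert crf_log_likelihood(emis, gold, params).item() == pytest.approx(0.0, abs=1e-8)

    def test_zero_transitions_viterbi_is_argmax(self, rng):
        emis = rng.normal(size=(6, 4))
        params = CrfParams(4)
        params.W.data[:] = 0.0
        params.b_start.data[:] = 0.0
        params.b_end.data[:] = 0.0
        path, _ = crf_viterbi(emis, params)
        np.testing.assert_array_equal(path, emis.argmax(axis=1))

    def test_exact_ties_resolve_to_lowest_label_id(self):
        params = CrfParams(3)
        params.W.data[:] = 0.0
        params.b_start.data[:] = 0.0
        params.b_end.data[:] = 0.0
        path, _ = crf_viterbi(np.zeros((4, 3)), params)
        np.testing.assert_array_equal(path, 0)

    def test_constrained_paths_are_grammar_valid(self, rng):
        idx = LabelIndex(["DATE", "NAME"])
        params = CrfParams(idx.k, rng, constraint_mask=bioes_transition_mask(idx))
        for _ in range(25):
            emis = rng.normal(0, 3, (int(rng.integers(1, 9)), idx.k))
            path, _ = crf_viterbi(emis, params)
            _, repairs = bioes_decode(idx.decode(path))
            assert repairs == 0

    def test_fully_masked_decoding_fails_loudly(self):
        k = 3
        mask = (np.full((k, k), NEG), np.full(k, NEG), np.full(k, NEG))
        params = CrfParams(k, constraint_mask=mask)
        with pytest.raises(ValueError):
            crf_viterbi(np.zeros((2, k)), params)

    def test_zero_transition_gradient_equals_softmax_gradient(self, rng):
        """With transitions pinned to zero the CRF objective decouples per
        token, so its emission gradient equals the cross-entropy gradient
        (up to the per-token vs per-sentence averaging factor)."""
        emis_data = rng.normal(size=(2, 4, 3))
        gold = rng.integers(0, 3, (2, 4))
        params = CrfParams(3)
        params.W.data[:] = 0.0
        params.W.requires_grad = False
        t1 = Tensor(emis_data.copy(), requires_grad=True)
        crf_log_likelihood(t1, gold, params).backward()
        t2 = Tensor(emis_data.copy(), requires_grad=True)
        softmax_cross_entropy(t2, gold).backward()
        np.testing.assert_allclose(t1.grad, t2.grad * 4, atol=1e-10)


class TestRecallLoss:
    @pytest.mark.parametrize(
        "fn, tp, dp, rho",
        [
            (0, 5, 10.0, 0.0),
            (3, 7, 10.0, (3 / 11) * 10.0),
            (3, 7, 1.0, 3 / 11),
            (4, 0, 2.0, (4 / 5) * 2.0),
            (0, 0, 5.0, 0.0),
        ],
    )
    def test_penalty_grid_matches_hand_arithmetic(self, fn, tp, dp, rho):
        assert recall_penalty(fn, tp, dp) == pytest.approx(rho)

    def test_literal_mode_multiplies_by_rho(self):
        cfg = LossConfig(delta_p=10.0, recall_weight_mode="literal")
        loss, rho = recall_weighted_loss(1.0, 3, 7, cfg)
        assert rho == pytest.approx(2.727272727272727)
        assert loss == pytest.approx(rho)

    def test_one_plus_rho_mode_preserves_base_signal(self):
        cfg = LossConfig(delta_p=10.0, recall_weight_mode="one_plus_rho")
        loss, rho = recall_weighted_loss(2.0, 0, 5, cfg)
        assert rho == 0.0 and loss == pytest.approx(2.0)

    @given(
        fn=st.integers(0, 500), tp=st.integers(0, 500),
        dp=st.floats(1.0, 50.0, allow_nan=False),
    )
    def test_rho_bounded_by_delta_p(self, fn, tp, dp):
        rho = recall_penalty(fn, tp, dp)
        assert 0.0 <= rho <= dp

    @given(tp=st.integers(0, 100), dp=st.floats(1.0, 20.0))
    def test_rho_monotone_in_false_negatives(self, tp, dp):
        rhos = [recall_penalty(fn, tp, dp) for fn in range(0, 30)]
        assert all(a <= b for a, b in zip(rhos, rhos[1:]))

    def test_delta_p_below_one_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(delta_p=0.5)
        with pytest.raises(ValueError):
            recall_penalty(1, 1, 0.9)


class TestCountFnTp:
    def test_all_negative_gold(self):
        assert count_fn_tp(np.zeros(5, int), np.zeros(5, int)) == (0, 0)

    def test_perfect_prediction(self):
        gold = np.array([0, 3, 1, 0, 2])
        assert count_fn_tp(gold, gold) == (0, 3)

    def test_set_arithmetic_example(self):
        gold = np.zeros(8, int)
        gold[[1, 2, 5]] = 1
        pred = np.zeros(8, int)
        pred[[2, 5, 7]] = 1
        assert count_fn_tp(pred, gold) == (1, 2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            count_fn_tp(np.zeros(3, int), np.zeros(4, int))
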
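"""Context models: recurrent variants, self-attention, dropout."""

import math

import numpy as np
import pytest

from deidseq._autograd import Tensor
from deidseq.context import (
    BiGRUContext,
    SelfAttentionContext,
    StackedContext,
    apply_dropout,
    make_context_model,
    single_head_attention,
)


def rand_input(rng, n=5, d=6, batch=None):
    shape = (n, d) if batch is None else (batch, n, d)
    return Tensor(rng.normal(size=shape))


class TestInterchangeability:
    @pytest.mark.parametrize("name", ["gru", "gru_gru", "lstm_gru", "self_attention"])
    def test_length_preserved_and_dims_fixed(self, name, rng):
        model = make_context_model(
            name, np.random.default_rng(0), d_in=8, hidden=5,
            d_model=8, n_heads=2, n_layers=2, d_ff=16,
        )
        for n in (1, 4, 9):
            out = model(rand_input(rng, n=n, d=8))
            assert out.shape == (n, model.d_out)
            assert np.all(np.isfinite(out.data))

    @pytest.mark.parametrize("name", ["gru", "gru_gru", "lstm_gru", "self_attention"])
    def test_bitwise_stable_across_calls(self, name, rng):
        model = make_context_model(
            name, np.random.default_rng(1), d_in=8, hidden=5,
            d_model=8, n_heads=2, n_layers=1, d_ff=16,
        )
        x = rand_input(rng, n=4, d=8)
        np.testing.assert_array_equal(model(x).data, model(x).data)

    @pytest.mark.parametrize("name", ["gru", "gru_gru", "lstm_gru", "self_attention"])
    def test_empty_sequence_rejected(self, name):
        model = make_context_model(
            name, np.random.default_rng(2), d_in=4, hidden=3,
            d_model=4, n_heads=2, n_layers=1, d_ff=8,
        )
        with pytest.raises(ValueError):
            model(Tensor(np.zeros((1, 0, 4))))


class TestBiGRU:
    def test_single_step_concatenates_both_directions(self, rng):
        model = BiGRUContext(np.random.default_rng(3), d_in=4, hidden=3)
        out = model(rand_input(rng, n=1, d=4))
        assert out.shape == (1, 6)

    def test_direction_symmetry_with_tied_weights(self, rng):
        """Reversing the input of a BiGRU whose directions share weights
        reverses and direction-swaps the output."""
        model = BiGRUContext(np.random.default_rng(4), d_in=4, hidden=3)
        model.bwd = model.fwd
        x = rng.normal(size=(5, 4))
        out_fwd = model(Tensor(x)).data
        out_rev = model(Tensor(x[::-1].copy())).data
        # forward half on x == backward half on reversed x, reversed
        np.testing.assert_allclose(out_fwd[:, :3], out_rev[::-1, 3:], atol=1e-12)


class TestStacked:
    def test_identity_second_layer_reduces_to_bigru(self, rng):
        seed_rng = np.random.default_rng(5)
        stacked = StackedContext(seed_rng, d_in=4, hidden=3, variant="gru_gru")
        bigru = BiGRUContext(np.random.default_rng(99), d_in=4, hidden=3)
        bigru.fwd, bigru.bwd = stacked.fwd1, stacked.bwd1  # share layer-1 weights
        stacked.fwd2.step = lambda x, h: x  # identity pass-through
        stacked.bwd2.step = lambda x, h: x
        x = rand_input(rng, n=6, d=4)
        np.testing.assert_allclose(stacked(x).data, bigru(x).data, atol=1e-12)

    def test_lstm_and_gru_first_layers_differ(self, rng):
        x = rand_input(rng, n=4, d=4)
        a = StackedContext(np.random.default_rng(6), 4, 3, "lstm_gru")(x).data
        b = StackedContext(np.random.default_rng(6), 4, 3, "gru_gru")(x).data
        assert not np.allclose(a, b)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            StackedContext(np.random.default_rng(7), 4, 3, "gru_lstm")


class TestSelfAttention:
    def test_attention_rows_sum_to_one_all_layers_heads(self, rng):
        model = SelfAttentionContext(
            np.random.default_rng(8), d_model=8, n_heads=4, n_layers=3, d_ff=16,
        )
        model(rand_input(rng, n=7, d=8))
        for gamma in model.last_attention_:
            np.testing.assert_allclose(gamma.sum(axis=-1), 1.0, atol=1e-6)

    def test_single_token_attends_only_to_itself(self):
        rng = np.random.default_rng(9)
        e = rng.normal(size=(1, 2))
        Wq, Wk, Wv = (rng.normal(size=(2, 2)) for _ in range(3))
        z, gamma, _ = single_head_attention(e, Wq, Wk, Wv)
        assert gamma[0, 0] == pytest.approx(1.0)
        np.testing.assert_allclose(z, e @ Wv)

    def test_hand_computed_two_dimensional_example(self):
        """Single head, n=3, d=2: a, γ and z recomputed with scalar math."""
        e = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        Wq = np.array([[1.0, 0.0], [0.0, 1.0]])
        Wk = np.array([[0.0, 1.0], [1.0, 0.0]])
        Wv = np.array([[2.0, 0.0], [0.0, 3.0]])
        z, gamma, a = single_head_attention(e, Wq, Wk, Wv)
        sqrt2 = math.sqrt(2.0)
        for i in range(3):
            qi = e[i] @ Wq
            scores = [
                (qi[0] * (e[j] @ Wk)[0] + qi[1] * (e[j] @ Wk)[1]) / sqrt2
                for j in range(3)
            ]
            assert a[i] == pytest.approx(scores)
            denom = sum(math.exp(s) for s in scores)
            weights = [math.exp(s) / denom for s in scores]
            assert gamma[i] == pytest.approx(weights)
            zi = [
                sum(weights[j] * (e[j] @ Wv)[k] for j in range(3)) for k in range(2)
            ]
            assert z[i] == pytest.approx(zi)

    def test_permutation_equivariance_without_positions(self, rng):
        model = SelfAttentionContext(
            np.random.default_rng(10), d_model=8, n_heads=2, n_layers=2, d_ff=16,
        )
        x = rng.normal(size=(6, 8))
        perm = np.random.default_rng(11).permutation(6)
        out = model(Tensor(x)).data
        out_perm = model(Tensor(x[perm].copy())).data
        np.testing.assert_allclose(out_perm, out[perm], atol=1e-10)

    def test_d_model_head_divisibility_enforced(self):
        with pytest.raises(ValueError):
            SelfAttentionContext(np.random.default_rng(12), d_model=10, n_heads=4)


class TestDropout:
    def test_rate_zero_and_eval_mode_are_identity(self, rng):
        x = rand_input(rng, n=4, d=4)
        g = np.random.default_rng(0)
        np.testing.assert_array_equal(apply_dropout(x, 0.0, g, True).data, x.data)
        np.testing.assert_array_equal(apply_dropout(x, 0.9, g, False).data, x.data)

    def test_training_keeps_half_and_rescales(self):
        x = Tensor(np.ones((400, 400)))
        out = apply_dropout(x, 0.5, np.random.default_rng(13), True).data
        kept = np.count_nonzero(out) / out.size
        assert 0.48 <= kept <= 0.52
        assert set(np.unique(out)) == {0.0, 2.0}

    def test_rate_one_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_dropout(rand_input(rng), 1.0, np.random.default_rng(0), True)
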
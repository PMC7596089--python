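"""Context modeling: map token embeddings e_1..e_n to context vectors r_1..r_n.

Four interchangeable models share one contract — input (B, T, d_in),
output (B, T, d_out), length always preserved:

* ``BiGRUContext`` — one bidirectional GRU layer; r_i = g_i^f ⊕ g_i^b,
  the *per-step* forward/backward states (unlike the character encoder,
  which keeps only final states).
* ``StackedContext`` — two bidirectional layers wired direction-wise
  (forward feeds forward, backward feeds backward); the first layer is
  LSTM ("lstm_gru") or GRU ("gru_gru"), the second is always GRU, and
  r_i is the second layer's g_i^f ⊕ g_i^b.
* ``SelfAttentionContext`` — a Transformer-style bidirectional encoder:
  per head, a_ij = (e_i W^Q)(e_j W^K)^T / sqrt(d_z), attention weights
  γ_ij = softmax_j(a_ij), z_i = Σ_j γ_ij (e_j W^V); heads concatenated
  and linearly transformed, with residual connections, layer
  normalization and a position-wise feed-forward block per layer.  No
  causal mask: every token attends to both left and right context.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor, concatenate, logsumexp, relu
from ._nn import (
    GRUCell,
    LSTMCell,
    Linear,
    dropout,
    layer_norm,
    layer_norm_params,
    run_rnn,
    stack_steps,
)

__all__ = [
    "BiGRUContext",
    "StackedContext",
    "SelfAttentionContext",
    "single_head_attention",
    "apply_dropout",
    "make_context_model",
]


def _as_batched(e: Tensor) -> tuple[Tensor, bool]:
    if e.ndim == 2:
        n, d = e.shape
        return e.reshape(1, n, d), True
    return e, False


class BiGRUContext:
    """Single bidirectional GRU layer; output dimension 2*hidden."""

    def __init__(self, rng: np.random.Generator, d_in: int, hidden: int):
        self.fwd = GRUCell(rng, d_in, hidden)
        self.bwd = GRUCell(rng, d_in, hidden)
        self.d_out = 2 * hidden

    def parameters(self):
        return self.fwd.parameters() + self.bwd.parameters()

    def __call__(self, e: Tensor, rng=None, training: bool = False) -> Tensor:
        e, squeeze = _as_batched(e)
        if e.shape[1] == 0:
            raise ValueError("empty sequence")
        f = stack_steps(run_rnn(self.fwd, e, reverse=False))
        b = stack_steps(run_rnn(self.bwd, e, reverse=True))
        r = concatenate([f, b], axis=2)
        return r.reshape(r.shape[1], r.shape[2]) if squeeze else r


class StackedContext:
    """Two bidirectional layers, direction-wise wiring; variant picks layer 1."""

    def __init__(
        self, rng: np.random.Generator, d_in: int, hidden: int, variant: str,
        dropout_rate: float = 0.0,
    ):
        if variant not in ("lstm_gru", "gru_gru"):
            raise ValueError(f"unknown stacked variant {variant!r}")
        cell1 = LSTMCell if variant == "lstm_gru" else GRUCell
        self.variant = variant
        self.dropout_rate = dropout_rate
        self.fwd1 = cell1(rng, d_in, hidden)
        self.bwd1 = cell1(rng, d_in, hidden)
        self.fwd2 = GRUCell(rng, hidden, hidden)
        self.bwd2 = GRUCell(rng, hidden, hidden)
        self.d_out = 2 * hidden

    def parameters(self):
        return (
            self.fwd1.parameters()
            + self.bwd1.parameters()
            + self.fwd2.parameters()
            + self.bwd2.parameters()
        )

    def __call__(self, e: Tensor, rng=None, training: bool = False) -> Tensor:
        e, squeeze = _as_batched(e)
        if e.shape[1] == 0:
            raise ValueError("empty sequence")
        f1 = stack_steps(run_rnn(self.fwd1, e, reverse=False))
        b1 = stack_steps(run_rnn(self.bwd1, e, reverse=True))
        if training and self.dropout_rate and rng is not None:
            f1 = dropout(f1, self.dropout_rate, rng, training)
            b1 = dropout(b1, self.dropout_rate, rng, training)
        f2 = stack_steps(run_rnn(self.fwd2, f1, reverse=False))
        b2 = stack_steps(run_rnn(self.bwd2, b1, reverse=True))
        r = concatenate([f2, b2], axis=2)
        return r.reshape(r.shape[1], r.shape[2]) if squeeze else r


def _softmax_last(x: Tensor) -> Tensor:
    from ._autograd import exp

    return exp(x - logsumexp(x, axis=-1, keepdims=True))


class _EncoderLayer:
    def __init__(self, rng, d_model: int, n_heads: int, d_ff: int):
        self.h = n_heads
        self.d_z = d_model // n_heads
        self.Wq = Linear(rng, d_model, d_model)
        self.Wk = Linear(rng, d_model, d_model)
        self.Wv = Linear(rng, d_model, d_model)
        self.Wo = Linear(rng, d_model, d_model)
        self.ff1 = Linear(rng, d_model, d_ff)
        self.ff2 = Linear(rng, d_ff, d_model)
        self.ln1 = layer_norm_params(d_model)
        self.ln2 = layer_norm_params(d_model)

    def parameters(self):
        ps = []
        for lin in (self.Wq, self.Wk, self.Wv, self.Wo, self.ff1, self.ff2):
            ps += lin.parameters()
        ps += list(self.ln1) + list(self.ln2)
        return ps

    def attention(self, e: Tensor) -> tuple[Tensor, Tensor]:
        B, T, d = e.shape

        def heads(x: Tensor) -> Tensor:
            return x.reshape(B, T, self.h, self.d_z).swapaxes(1, 2)  # (B,h,T,dz)

        q, k, v = heads(self.Wq(e)), heads(self.Wk(e)), heads(self.Wv(e))
        scores = (q @ k.swapaxes(2, 3)) * (1.0 / np.sqrt(self.d_z))  # (B,h,T,T)
        gamma = _softmax_last(scores)
        z = gamma @ v  # (B,h,T,dz)
        z = z.swapaxes(1, 2).reshape(B, T, d)
        return self.Wo(z), gamma

    def __call__(self, e, rng, rate, training):
        att, gamma = self.attention(e)
        if training and rate and rng is not None:
            att = dropout(att, rate, rng, training)
        x = layer_norm(e + att, *self.ln1)
        ff = self.ff2(relu(self.ff1(x)))
        if training and rate and rng is not None:
            ff = dropout(ff, rate, rng, training)
        out = layer_norm(x + ff, *self.ln2)
        return out, gamma


class SelfAttentionContext:
    """Multi-layer multi-head self-attention encoder (bidirectional)."""

    def __init__(
        self,
        rng: np.random.Generator,
        d_model: int = 128,
        n_heads: int = 4,
        n_layers: int = 4,
        d_ff: int = 512,
        dropout_rate: float = 0.25,
    ):
        if d_model % n_heads != 0:
            raise ValueError(f"d_model={d_model} not divisible by n_heads={n_heads}")
        self.layers = [_EncoderLayer(rng, d_model, n_heads, d_ff) for _ in range(n_layers)]
        self.dropout_rate = dropout_rate
        self.d_out = d_model
        self.last_attention_: list[np.ndarray] = []  # per-layer γ, for inspection

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def __call__(self, e: Tensor, rng=None, training: bool = False) -> Tensor:
        e, squeeze = _as_batched(e)
        if e.shape[1] == 0:
            raise ValueError("empty sequence")
        self.last_attention_ = []
        x = e
        for layer in self.layers:
            x, gamma = layer(x, rng, self.dropout_rate, training)
            self.last_attention_.append(gamma.data)
        return x.reshape(x.shape[1], x.shape[2]) if squeeze else x


def single_head_attention(
    e: np.ndarray, Wq: np.ndarray, Wk: np.ndarray, Wv: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One attention head in plain NumPy, returning (z, γ, a).

    a_ij = (e_i W^Q)(e_j W^K)^T / sqrt(d_z);  γ_ij = softmax_j(a_ij);
    z_i = Σ_j γ_ij (e_j W^V).  This is the arithmetic each head of
    :class:`SelfAttentionContext` performs before head concatenation.
    """
    q, k, v = e @ Wq, e @ Wk, e @ Wv
    d_z = k.shape[1]
    a = q @ k.T / np.sqrt(d_z)
    a_shift = a - a.max(axis=1, keepdims=True)
    gamma = np.exp(a_shift) / np.exp(a_shift).sum(axis=1, keepdims=True)
    return gamma @ v, gamma, a


def apply_dropout(
    x: Tensor, rate: float, rng: np.random.Generator, training: bool
) -> Tensor:
    """Inverted dropout on any tensor; identity in evaluation mode."""
    return dropout(x, rate, rng, training)


def make_context_model(
    name: str,
    rng: np.random.Generator,
    d_in: int,
    hidden: int = 64,
    dropout_rate: float = 0.5,
    d_model: int = 128,
    n_heads: int = 4,
    n_layers: int = 4,
    d_ff: int = 512,
):
    """Factory over the four interchangeable context models."""
    if name == "gru":
        return BiGRUContext(rng, d_in, hidden)
    if name in ("gru_gru", "lstm_gru"):
        return StackedContext(rng, d_in, hidden, name, dropout_rate)
    if name == "self_attention":
        return SelfAttentionContext(rng, d_model, n_heads, n_layers, d_ff, dropout_rate)
    raise ValueError(f"unknown context model {name!r}")
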
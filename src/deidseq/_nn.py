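"""Shared neural building blocks on top of the autograd engine.

Recurrent cells, linear layers, embeddings, layer normalization and
inverted dropout.  Parameter initialization is Glorot-uniform from an
explicit ``numpy.random.Generator`` — no global random state anywhere.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor, concatenate, sigmoid, tanh

__all__ = [
    "glorot",
    "Linear",
    "Embedding",
    "GRUCell",
    "LSTMCell",
    "run_rnn",
    "layer_norm_params",
    "layer_norm",
    "dropout",
]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Linear:
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int):
        self.W = glorot(rng, d_in, d_out)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]


class Embedding:
    """Trainable lookup table; row gather with scatter-add gradient."""

    def __init__(self, rng: np.random.Generator, n: int, d: int):
        self.table = Tensor(rng.normal(0.0, 0.1, size=(n, d)), requires_grad=True)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.table[np.asarray(ids, dtype=np.intp)]

    def parameters(self):
        return [self.table]


class GRUCell:
    """Gated recurrent unit: h' = (1-z)*n + z*h with reset-gated candidate."""

    def __init__(self, rng: np.random.Generator, d_in: int, d_hidden: int):
        self.h = d_hidden
        self.W_zr = glorot(rng, d_in, 2 * d_hidden)
        self.U_zr = glorot(rng, d_hidden, 2 * d_hidden)
        self.b_zr = Tensor(np.zeros(2 * d_hidden), requires_grad=True)
        self.W_n = glorot(rng, d_in, d_hidden)
        self.U_n = glorot(rng, d_hidden, d_hidden)
        self.b_n = Tensor(np.zeros(d_hidden), requires_grad=True)

    def step(self, x: Tensor, h: Tensor) -> Tensor:
        zr = sigmoid(x @ self.W_zr + h @ self.U_zr + self.b_zr)
        z = zr[:, : self.h]
        r = zr[:, self.h :]
        n = tanh(x @ self.W_n + (r * h) @ self.U_n + self.b_n)
        return (1.0 - z) * n + z * h

    def initial(self, batch: int) -> Tensor:
        return Tensor(np.zeros((batch, self.h)))

    def parameters(self):
        return [self.W_zr, self.U_zr, self.b_zr, self.W_n, self.U_n, self.b_n]


class LSTMCell:
    def __init__(self, rng: np.random.Generator, d_in: int, d_hidden: int):
        self.h = d_hidden
        self.W = glorot(rng, d_in, 4 * d_hidden)
        self.U = glorot(rng, d_hidden, 4 * d_hidden)
        self.b = Tensor(np.zeros(4 * d_hidden), requires_grad=True)

    def step(self, x: Tensor, state: tuple[Tensor, Tensor]) -> tuple[Tensor, Tensor]:
        h, c = state
        gates = x @ self.W + h @ self.U + self.b
        H = self.h
        i = sigmoid(gates[:, :H])
        f = sigmoid(gates[:, H : 2 * H])
        o = sigmoid(gates[:, 2 * H : 3 * H])
        g = tanh(gates[:, 3 * H :])
        c_new = f * c + i * g
        return o * tanh(c_new), c_new

    def initial(self, batch: int) -> tuple[Tensor, Tensor]:
        z = np.zeros((batch, self.h))
        return Tensor(z.copy()), Tensor(z.copy())

    def parameters(self):
        return [self.W, self.U, self.b]


def run_rnn(cell, x: Tensor, reverse: bool = False) -> list[Tensor]:
    """Run a recurrent cell over ``x`` of shape (B, T, d_in).

    Returns the list of per-step hidden states in *input order* (the
    reverse pass is unreversed before returning), each (B, H).
    """
    B, T = x.shape[0], x.shape[1]
    state = cell.initial(B)
    is_lstm = isinstance(state, tuple)
    steps = range(T - 1, -1, -1) if reverse else range(T)
    outputs: list[Tensor] = []
    for t in steps:
        xt = x[:, t, :]
        if is_lstm:
            state = cell.step(xt, state)
            outputs.append(state[0])
        else:
            state = cell.step(xt, state)
            outputs.append(state)
    if reverse:
        outputs.reverse()
    return outputs


def stack_steps(outputs: list[Tensor]) -> Tensor:
    """(list of T tensors (B, H)) -> (B, T, H)."""
    B, H = outputs[0].shape
    return concatenate([o.reshape(B, 1, H) for o in outputs], axis=1)


def layer_norm_params(d: int) -> tuple[Tensor, Tensor]:
    return (
        Tensor(np.ones(d), requires_grad=True),
        Tensor(np.zeros(d), requires_grad=True),
    )


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered * (var + eps) ** -0.5 * gain + bias


def dropout(
    x: Tensor, rate: float, rng: np.random.Generator, training: bool
) -> Tensor:
    """Inverted dropout: survivors scaled by 1/(1-rate); identity at eval."""
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
    if not training or rate == 0.0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)
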
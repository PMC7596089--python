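"""Label decoding and training losses: softmax, linear-chain CRF, recall weighting.

The CRF scores a label path y for emissions r as

    score(y) = b_start[y_1] + Σ_t r[t, y_t] + Σ_t W[y_{t-1}, y_t] + b_end[y_n]

with conditional probability p(y|r) = exp score(y) / Σ_{y'} exp score(y').
Training minimizes −log p(gold|r); the partition runs the forward
algorithm entirely in log space.  Decoding is Viterbi; an optional hard
constraint mask forbids BIOES-invalid transitions (O→I, B-X→S, category
switches inside a span, starting with I/E, ending on B/I), so the decoded
path is always grammar-valid when enabled.

The recall-weighted loss follows the false-negative-rate penalty:
FNR = FN / (1 + FN + TP) (never infinite), ρ = FNR × [(δ_p − 1) + 1]
(so ρ ∈ [0, δ_p]), and L_recall = L_regular × ρ.  Because the literal
product vanishes whenever a batch has no false negatives, the default
training mode weights by (1 + ρ) instead; both forms are implemented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor, logsumexp
from .corpus_io import LabelIndex

__all__ = [
    "CrfParams",
    "LossConfig",
    "softmax_decode",
    "crf_log_likelihood",
    "crf_viterbi",
    "recall_weighted_loss",
    "count_fn_tp",
    "bioes_transition_mask",
]

NEG = -1e4  # effective -inf that keeps float arithmetic finite


def bioes_transition_mask(label_index: LabelIndex) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hard BIOES grammar constraints.

    Returns (transition_mask (k,k), start_mask (k,), end_mask (k,)) with 0
    for allowed and ``NEG`` for forbidden.  Allowed successors: after O/E/S
    any of O, B-*, S-*; after B-X or I-X only I-X or E-X.  Paths may not
    start with I/E nor end on B/I.
    """
    labels = label_index.labels
    k = len(labels)
    trans = np.full((k, k), NEG)
    start = np.full(k, NEG)
    end = np.full(k, NEG)

    def kind(lab):
        return ("O", None) if lab == "O" else tuple(lab.split("-", 1))

    for i, a in enumerate(labels):
        pa, ca = kind(a)
        if pa in ("O", "S", "B"):
            start[i] = 0.0
        if pa in ("O", "E", "S"):
            end[i] = 0.0
        for j, b in enumerate(labels):
            pb, cb = kind(b)
            if pa in ("O", "E", "S"):
                ok = pb in ("O", "B", "S")
            else:  # after B-X / I-X the span must continue
                ok = pb in ("I", "E") and cb == ca
            if ok:
                trans[i, j] = 0.0
    return trans, start, end


class CrfParams:
    """Transition weights and start/end biases, optionally BIOES-constrained."""

    def __init__(
        self,
        k: int,
        rng: np.random.Generator | None = None,
        constraint_mask: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.W = Tensor(rng.normal(0.0, 0.01, size=(k, k)), requires_grad=True)
        self.b_start = Tensor(np.zeros(k), requires_grad=True)
        self.b_end = Tensor(np.zeros(k), requires_grad=True)
        self.mask = constraint_mask

    def parameters(self):
        return [self.W, self.b_start, self.b_end]

    def effective(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Transition/start/end scores with constraints applied (NumPy view)."""
        if self.mask is None:
            return self.W.data, self.b_start.data, self.b_end.data
        t, s, e = self.mask
        return self.W.data + t, self.b_start.data + s, self.b_end.data + e

    def effective_tensors(self) -> tuple[Tensor, Tensor, Tensor]:
        if self.mask is None:
            return self.W, self.b_start, self.b_end
        t, s, e = self.mask
        return self.W + Tensor(t), self.b_start + Tensor(s), self.b_end + Tensor(e)


@dataclass(frozen=True)
class LossConfig:
    decoder: str = "crf"  # or "softmax"
    delta_p: float = 1.0
    recall_weight_mode: str = "off"  # off | literal | one_plus_rho

    def __post_init__(self):
        if self.decoder not in ("crf", "softmax"):
            raise ValueError(f"unknown decoder {self.decoder!r}")
        if self.delta_p < 1:
            raise ValueError("delta_p must be >= 1")
        if self.recall_weight_mode not in ("off", "literal", "one_plus_rho"):
            raise ValueError(f"unknown recall_weight_mode {self.recall_weight_mode!r}")


# ---------------------------------------------------------------------------
# softmax path
# ---------------------------------------------------------------------------

def softmax_decode(emissions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-token probabilities q_j(r_i) = exp r_ij / Σ_k exp r_ik and argmax.

    Ties break toward the lowest label id.  Accepts (n, k) or (B, T, k).
    """
    r = np.asarray(emissions, dtype=np.float64)
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite emissions")
    shift = r - r.max(axis=-1, keepdims=True)
    q = np.exp(shift)
    q /= q.sum(axis=-1, keepdims=True)
    return q, r.argmax(axis=-1)


def softmax_cross_entropy(emissions: Tensor, gold: np.ndarray) -> Tensor:
    """Mean token-level cross-entropy; emissions (B, T, k), gold (B, T) ids."""
    gold = np.asarray(gold, dtype=np.intp)
    B, T, _ = emissions.shape
    lse = logsumexp(emissions, axis=-1)  # (B, T)
    bi, ti = np.meshgrid(np.arange(B), np.arange(T), indexing="ij")
    gold_scores = emissions[(bi, ti, gold)]
    return (lse - gold_scores).mean()


# ---------------------------------------------------------------------------
# CRF path
# ---------------------------------------------------------------------------

def crf_log_likelihood(
    emissions: Tensor | np.ndarray, gold: np.ndarray, params: CrfParams
) -> Tensor:
    """Negative mean log-likelihood −log p(gold | emissions) of a batch.

    ``emissions`` is (B, T, k) (or (T, k), auto-batched); ``gold`` the
    matching integer label paths.  Differentiable end to end.
    """
    if not isinstance(emissions, Tensor):
        emissions = Tensor(emissions)
    if not np.all(np.isfinite(emissions.data)):
        raise ValueError("non-finite emissions")
    if emissions.ndim == 2:
        emissions = emissions.reshape(1, *emissions.shape)
        gold = np.asarray(gold, dtype=np.intp).reshape(1, -1)
    gold = np.asarray(gold, dtype=np.intp)
    B, T, k = emissions.shape
    W, b_start, b_end = params.effective_tensors()

    # gold path score
    bi = np.arange(B)
    score = b_start[gold[:, 0]] + emissions[(bi, np.zeros(B, dtype=np.intp), gold[:, 0])]
    for t in range(1, T):
        score = score + W[(gold[:, t - 1], gold[:, t])]
        score = score + emissions[(bi, np.full(B, t, dtype=np.intp), gold[:, t])]
    score = score + b_end[gold[:, T - 1]]

    # partition by the forward algorithm in log space
    alpha = emissions[:, 0, :] + b_start.reshape(1, k)  # (B, k)
    Wb = W.reshape(1, k, k)
    for t in range(1, T):
        alpha = logsumexp(alpha.reshape(B, k, 1) + Wb, axis=1) + emissions[:, t, :]
    log_z = logsumexp(alpha + b_end.reshape(1, k), axis=1)  # (B,)
    return (log_z - score).mean()


def crf_viterbi(
    emissions: np.ndarray, params: CrfParams
) -> tuple[np.ndarray, float]:
    """Maximum-score label path and its score (single sentence, (T, k)).

    Ties resolve deterministically toward the lowest label id.  With the
    BIOES constraint mask enabled the returned path is grammar-valid.
    """
    r = np.asarray(emissions, dtype=np.float64)
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite emissions")
    T, k = r.shape
    W, b_start, b_end = params.effective()
    delta = b_start + r[0]
    back = np.zeros((T, k), dtype=np.intp)
    for t in range(1, T):
        cand = delta[:, None] + W  # (prev, next)
        back[t] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + r[t]
    delta = delta + b_end
    best = float(delta.max())
    if best <= NEG:
        raise ValueError("all label paths forbidden by the constraint mask")
    path = np.zeros(T, dtype=np.intp)
    path[-1] = int(delta.argmax())
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, best


def crf_viterbi_batch(emissions: np.ndarray, params: CrfParams) -> np.ndarray:
    """Viterbi over a (B, T, k) batch of equal-length sentences."""
    r = np.asarray(emissions, dtype=np.float64)
    B, T, k = r.shape
    W, b_start, b_end = params.effective()
    delta = b_start[None, :] + r[:, 0, :]
    back = np.zeros((B, T, k), dtype=np.intp)
    for t in range(1, T):
        cand = delta[:, :, None] + W[None, :, :]
        back[:, t, :] = cand.argmax(axis=1)
        delta = cand.max(axis=1) + r[:, t, :]
    delta = delta + b_end[None, :]
    paths = np.zeros((B, T), dtype=np.intp)
    paths[:, -1] = delta.argmax(axis=1)
    bi = np.arange(B)
    for t in range(T - 1, 0, -1):
        paths[:, t - 1] = back[bi, t, paths[:, t]]
    return paths


# ---------------------------------------------------------------------------
# recall-weighted loss
# ---------------------------------------------------------------------------

def recall_penalty(fn_count: int, tp_count: int, delta_p: float) -> float:
    """ρ = FNR × [(δ_p − 1) + 1] with FNR = FN / (1 + FN + TP)."""
    if delta_p < 1:
        raise ValueError("delta_p must be >= 1")
    if fn_count < 0 or tp_count < 0:
        raise ValueError("counts must be non-negative")
    fnr = fn_count / (1.0 + fn_count + tp_count)
    return fnr * ((delta_p - 1.0) + 1.0)


def recall_weighted_loss(
    base_loss: Tensor | float, fn_count: int, tp_count: int, config: LossConfig
) -> tuple[Tensor | float, float]:
    """Apply the recall penalty to a base loss; returns (loss, ρ).

    ``literal`` multiplies by ρ exactly as formulated (zero when the
    batch has no false negatives); ``one_plus_rho`` multiplies by 1 + ρ,
    which preserves the base gradient signal; ``off`` passes through.
    """
    rho = recall_penalty(fn_count, tp_count, config.delta_p)
    if config.recall_weight_mode == "off":
        return base_loss, rho
    if config.recall_weight_mode == "literal":
        return base_loss * rho, rho
    return base_loss * (1.0 + rho), rho


def count_fn_tp(
    predicted: np.ndarray, gold: np.ndarray, o_id: int = 0
) -> tuple[int, int]:
    """Binary PHI reduction: any label other than O counts as PHI.

    Returns (FN, TP) where FN are gold-PHI tokens predicted O and TP are
    tokens PHI in both sequences.
    """
    predicted = np.asarray(predicted)
    gold = np.asarray(gold)
    if predicted.shape != gold.shape:
        raise ValueError("predicted and gold shapes differ")
    gold_phi = gold != o_id
    pred_phi = predicted != o_id
    tp = int(np.sum(gold_phi & pred_phi))
    fn = int(np.sum(gold_phi & ~pred_phi))
    return fn, tp
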
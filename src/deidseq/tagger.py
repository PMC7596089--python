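"""The PHI sequence tagger: a scikit-learn-style estimator over the neural stack.

``DeidTagger`` wires the embedding layer (character BiGRU plus word
vectors, or dynamic embeddings with positional encoding), one of four
context models (``gru``, ``gru_gru``, ``lstm_gru``, ``self_attention``)
and a softmax or linear-chain-CRF label decoder into a single
fit/predict estimator:

>>> tagger = DeidTagger(model="gru", decoder="crf", seed=7)
>>> tagger.fit(train_sentences, train_tags)            # doctest: +SKIP
>>> predicted = tagger.predict(test_sentences)         # doctest: +SKIP

``X`` is a list of tokenized sentences (lists of token strings), ``y``
the aligned BIOES tag sequences.  Training uses Adam on mini-batches
bucketed by sentence length (so no padding or masking is ever needed),
early-stops on validation binary-PHI F1, and restores the best
checkpoint.  All randomness flows from the single ``seed`` parameter.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from ._autograd import Adam, Tensor
from ._nn import Embedding, Linear, dropout
from .context import make_context_model
from .corpus_io import LabelIndex, Vocabulary
from .decoding import (
    CrfParams,
    LossConfig,
    bioes_transition_mask,
    count_fn_tp,
    crf_log_likelihood,
    crf_viterbi_batch,
    recall_weighted_loss,
    softmax_cross_entropy,
)
from .embeddings import (
    CharEncoder,
    CharVocabulary,
    WordVectorTable,
    embed_sentence_dynamic,
)

__all__ = ["DeidTagger"]

_RNN_MODELS = ("gru", "gru_gru", "lstm_gru")


def _binary_f1(pred_tags, gold_tags) -> tuple[float, float, float]:
    tp = fp = fn = 0
    for p_sent, g_sent in zip(pred_tags, gold_tags):
        for p, g in zip(p_sent, g_sent):
            pp, gg = p != "O", g != "O"
            tp += pp and gg
            fp += pp and not gg
            fn += gg and not pp
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1


class DeidTagger(BaseEstimator):
    """Neural PHI tagger with interchangeable context models and decoders.

    Parameters
    ----------
    model : one of "gru", "gru_gru", "lstm_gru", "self_attention".
    decoder : "crf" (joint path decoding, default) or "softmax".
    use_char : include the character-level BiGRU on the recurrent paths.
    word_vectors : optional :class:`~deidseq.embeddings.WordVectorTable`
        of frozen pretrained vectors; when ``None`` a trainable table of
        width ``d_word`` is learned instead.
    dropout : dropout rate on embeddings and between stacked layers.
    delta_p, recall_weight_mode : recall-weighted loss settings; the
        penalty ρ is computed per mini-batch from its own predictions.
    crf_constrained : forbid BIOES-invalid transitions in the CRF.
    learning_rate : ``None`` selects 5e-3 for recurrent models and 3e-3
        for the self-attention model (Adam).
    """

    def __init__(
        self,
        model: str = "gru",
        decoder: str = "crf",
        use_char: bool = True,
        d_char: int = 25,
        d_char_hidden: int = 25,
        d_word: int = 50,
        hidden: int = 64,
        d_model: int = 64,
        n_heads: int = 4,
        n_layers: int = 2,
        d_ff: int = 256,
        dropout: float = 0.5,
        word_vectors: WordVectorTable | None = None,
        delta_p: float = 1.0,
        recall_weight_mode: str = "off",
        crf_constrained: bool = True,
        learning_rate: float | None = None,
        epochs: int = 20,
        batch_size: int = 32,
        patience: int = 3,
        validation_fraction: float = 0.2,
        grad_clip: float = 25.0,
        max_len: int = 512,
        seed: int = 0,
        verbose: bool = False,
    ):
        self.model = model
        self.decoder = decoder
        self.use_char = use_char
        self.d_char = d_char
        self.d_char_hidden = d_char_hidden
        self.d_word = d_word
        self.hidden = hidden
        self.d_model = d_model
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.d_ff = d_ff
        self.dropout = dropout
        self.word_vectors = word_vectors
        self.delta_p = delta_p
        self.recall_weight_mode = recall_weight_mode
        self.crf_constrained = crf_constrained
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.grad_clip = grad_clip
        self.max_len = max_len
        self.seed = seed
        self.verbose = verbose

    # ------------------------------------------------------------------
    def _build(self, train_tokens, categories):
        rng = np.random.default_rng(self.seed)
        self._rng = rng
        self.label_index_ = LabelIndex(categories)
        k = self.label_index_.k
        all_tokens = [t for sent in train_tokens for t in sent]
        self.vocab_ = Vocabulary(all_tokens)
        self._modules = []

        if self.model == "self_attention":
            self._dyn_embedding = Embedding(rng, len(self.vocab_), self.d_model)
            self._modules.append(self._dyn_embedding)
            d_in = self.d_model
        else:
            if self.word_vectors is not None:
                self._word_embedding = None
                d_w = self.word_vectors.dim
            else:
                self._word_embedding = Embedding(rng, len(self.vocab_), self.d_word)
                self._modules.append(self._word_embedding)
                d_w = self.d_word
            if self.use_char:
                self.char_vocab_ = CharVocabulary(all_tokens)
                self._char_encoder = CharEncoder(
                    rng, len(self.char_vocab_), self.d_char, self.d_char_hidden
                )
                self._modules.append(self._char_encoder)
                d_in = d_w + 2 * self.d_char_hidden
            else:
                self._char_encoder = None
                d_in = d_w

        self._context = make_context_model(
            self.model,
            rng,
            d_in,
            hidden=self.hidden,
            dropout_rate=self.dropout,
            d_model=self.d_model,
            n_heads=self.n_heads,
            n_layers=self.n_layers,
            d_ff=self.d_ff,
        )
        self._modules.append(self._context)
        self._proj = Linear(rng, self._context.d_out, k)
        self._modules.append(self._proj)
        if self.decoder == "crf":
            mask = (
                bioes_transition_mask(self.label_index_)
                if self.crf_constrained
                else None
            )
            self._crf = CrfParams(k, rng, constraint_mask=mask)
            self._modules.append(self._crf)
        else:
            self._crf = None
        self.loss_config_ = LossConfig(
            decoder=self.decoder,
            delta_p=self.delta_p,
            recall_weight_mode=self.recall_weight_mode,
        )

    def _parameters(self):
        return [p for m in self._modules for p in m.parameters()]

    # ------------------------------------------------------------------
    def _forward(self, batch_tokens, training: bool) -> Tensor:
        """Emission scores (B, T, k) for a batch of equal-length sentences."""
        B, T = len(batch_tokens), len(batch_tokens[0])
        rng = self._rng
        if self.model == "self_attention":
            ids = np.array([self.vocab_.encode(s) for s in batch_tokens], dtype=np.intp)
            e = embed_sentence_dynamic(ids, self._dyn_embedding, self.max_len)
        else:
            if self._word_embedding is None:
                w = np.stack(
                    [self.word_vectors.lookup_many(s) for s in batch_tokens]
                )
                word_part = Tensor(w)
            else:
                ids = np.array(
                    [self.vocab_.encode(s) for s in batch_tokens], dtype=np.intp
                )
                word_part = self._word_embedding(ids)
            if self._char_encoder is not None:
                flat = [t for sent in batch_tokens for t in sent]
                ch = self._char_encoder.encode_tokens(flat, self.char_vocab_)
                ch = ch.reshape(B, T, 2 * self.d_char_hidden)
                from ._autograd import concatenate

                e = concatenate([word_part, ch], axis=2)
            else:
                e = word_part
        e = dropout(e, self.dropout, rng, training)
        r = self._context(e, rng=rng, training=training)
        return self._proj(r)

    def _decode_batch(self, emissions: np.ndarray) -> np.ndarray:
        if self._crf is not None:
            return crf_viterbi_batch(emissions, self._crf)
        return emissions.argmax(axis=-1)

    # ------------------------------------------------------------------
    @staticmethod
    def _bucket(indices, X, batch_size, rng=None):
        by_len: dict[int, list[int]] = {}
        for i in indices:
            if len(X[i]) > 0:
                by_len.setdefault(len(X[i]), []).append(i)
        batches = []
        for _, idxs in sorted(by_len.items()):
            for j in range(0, len(idxs), batch_size):
                batches.append(idxs[j : j + batch_size])
        if rng is not None:
            rng.shuffle(batches)
        return batches

    def fit(self, X, y, validation_data=None):
        """Train on sentences ``X`` with BIOES tag sequences ``y``.

        ``validation_data=(X_val, y_val)`` overrides the internal
        validation split used for early stopping.
        """
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        categories = sorted(
            {t.split("-", 1)[1] for tags in y for t in tags if t != "O"}
        )
        if validation_data is not None:
            X_tr, y_tr = list(X), list(y)
            X_val, y_val = validation_data
        else:
            order = np.random.default_rng(self.seed).permutation(len(X))
            n_val = int(round(self.validation_fraction * len(X)))
            val_idx, tr_idx = order[:n_val], order[n_val:]
            X_tr = [X[i] for i in tr_idx]
            y_tr = [y[i] for i in tr_idx]
            X_val = [X[i] for i in val_idx]
            y_val = [y[i] for i in val_idx]

        self._build(X_tr, categories)
        lr = self.learning_rate
        if lr is None:
            lr = 3e-3 if self.model == "self_attention" else 5e-3
        opt = Adam(self._parameters(), lr=lr)
        y_tr_ids = [np.array(self.label_index_.encode(t), dtype=np.intp) for t in y_tr]

        self.history_ = []
        best_f1, best_snapshot, stall = -1.0, None, 0
        shuffle_rng = np.random.default_rng(self.seed + 1)
        for epoch in range(self.epochs):
            batches = self._bucket(
                range(len(X_tr)), X_tr, self.batch_size, rng=shuffle_rng
            )
            losses, rhos = [], []
            for batch in batches:
                toks = [X_tr[i] for i in batch]
                gold = np.stack([y_tr_ids[i] for i in batch])
                emis = self._forward(toks, training=True)
                if self.decoder == "crf":
                    base = crf_log_likelihood(emis, gold, self._crf)
                else:
                    base = softmax_cross_entropy(emis, gold)
                if self.loss_config_.recall_weight_mode != "off":
                    pred = self._decode_batch(emis.data)
                    fn, tp = count_fn_tp(pred, gold)
                    loss, rho = recall_weighted_loss(base, fn, tp, self.loss_config_)
                    rhos.append(rho)
                else:
                    loss = base
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"training loss diverged at epoch {epoch + 1}"
                    )
                opt.zero_grad()
                loss.backward()
                self._clip_gradients()
                opt.step()
                losses.append(float(base.data))
            prec, rec, f1 = (
                _binary_f1(self.predict(X_val), y_val) if X_val else (0.0, 0.0, 0.0)
            )
            record = {
                "epoch": epoch + 1,
                "train_loss": float(np.mean(losses)) if losses else 0.0,
                "mean_rho": float(np.mean(rhos)) if rhos else 0.0,
                "val_precision": prec,
                "val_recall": rec,
                "val_f1": f1,
            }
            self.history_.append(record)
            if self.verbose:
                print(
                    f"epoch {record['epoch']:3d}  loss {record['train_loss']:.4f}"
                    f"  val P {prec:.4f} R {rec:.4f} F1 {f1:.4f}"
                )
            if f1 > best_f1:
                best_f1, stall = f1, 0
                best_snapshot = [p.data.copy() for p in self._parameters()]
            else:
                stall += 1
                if stall >= self.patience:
                    break
        if best_snapshot is not None:
            for p, saved in zip(self._parameters(), best_snapshot):
                p.data = saved
        self.best_val_f1_ = max(best_f1, 0.0)
        self.n_epochs_ = len(self.history_)
        return self

    def _clip_gradients(self):
        total = 0.0
        params = [p for p in self._parameters() if p.grad is not None]
        for p in params:
            total += float(np.sum(p.grad**2))
        norm = np.sqrt(total)
        if norm > self.grad_clip:
            scale = self.grad_clip / norm
            for p in params:
                p.grad *= scale

    # ------------------------------------------------------------------
    def predict(self, X) -> list[list[str]]:
        """Predicted BIOES tag sequences for a list of tokenized sentences."""
        if not hasattr(self, "label_index_"):
            raise RuntimeError("tagger is not fitted")
        out: dict[int, list[str]] = {}
        for batch in self._bucket(range(len(X)), X, self.batch_size):
            toks = [X[i] for i in batch]
            emis = self._forward(toks, training=False)
            paths = self._decode_batch(emis.data)
            for i, path in zip(batch, paths):
                out[i] = self.label_index_.decode(path)
        return [out.get(i, []) for i in range(len(X))]

    def score(self, X, y) -> float:
        """Token-level binary-PHI F1 on (X, y)."""
        return _binary_f1(self.predict(X), y)[2]

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        """Persist the fitted tagger (configuration embedded) to ``path``."""
        import pickle

        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "DeidTagger":
        import pickle

        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, cls):
            raise TypeError(f"{path} is not a {cls.__name__} checkpoint")
        return obj
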
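"""Token embeddings: character-level BiGRU, fixed word vectors, dynamic path.

Two embedding schemes feed the context models:

* **Fixed** (recurrent path): each token ``s_i`` is represented as
  ``e_i = V_T(s_i) ⊕ b_i`` — a pretrained (frozen) word vector
  concatenated with a character-level representation ``b_i``.  The
  character representation runs a bidirectional GRU over the token's
  character embeddings and concatenates the *final* hidden states of the
  backward and forward directions, so spelling regularities (case,
  digits, affixes) transfer to out-of-vocabulary tokens.

* **Dynamic** (self-attention path): a trainable token embedding plus a
  fixed sinusoidal positional encoding, as in the Transformer encoder.

Word vectors load from GloVe text format (token followed by
whitespace-separated floats).  When no pretrained file is available the
tagger substitutes a trainable table with the same interface.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from ._autograd import Tensor, concatenate
from ._nn import Embedding, GRUCell, run_rnn

logger = logging.getLogger(__name__)

__all__ = [
    "CharVocabulary",
    "CharEncoder",
    "WordVectorTable",
    "load_word_vectors",
    "embed_sentence_fixed",
    "positional_encoding",
    "embed_sentence_dynamic",
]

CHAR_PAD = 0
CHAR_UNK = 1


class CharVocabulary:
    """Character-to-id map with reserved pad and unknown ids."""

    def __init__(self, corpus_tokens: Sequence[str]):
        chars = sorted({c for tok in corpus_tokens for c in tok})
        self.char_to_id = {c: i + 2 for i, c in enumerate(chars)}

    def __len__(self) -> int:
        return len(self.char_to_id) + 2

    def encode(self, token: str) -> list[int]:
        return [self.char_to_id.get(c, CHAR_UNK) for c in token]

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.char_to_id, ensure_ascii=False))

    @classmethod
    def load(cls, path: str | Path) -> "CharVocabulary":
        vocab = cls([])
        vocab.char_to_id = json.loads(Path(path).read_text())
        return vocab


class CharEncoder:
    """Character-level BiGRU producing one vector per token.

    The representation is the concatenation of the backward GRU's state at
    the first character and the forward GRU's state at the last character
    (final states of each direction), dimension ``2 * d_hidden``.
    """

    def __init__(
        self,
        rng: np.random.Generator,
        n_chars: int,
        d_char: int = 25,
        d_hidden: int = 25,
    ):
        self.d_hidden = d_hidden
        self.embedding = Embedding(rng, n_chars, d_char)
        self.fwd = GRUCell(rng, d_char, d_hidden)
        self.bwd = GRUCell(rng, d_char, d_hidden)

    def parameters(self):
        return self.embedding.parameters() + self.fwd.parameters() + self.bwd.parameters()

    def encode_tokens(self, tokens: Sequence[str], vocab: CharVocabulary) -> Tensor:
        """Encode a flat list of tokens to a (n_tokens, 2*d_hidden) tensor.

        Tokens are grouped by character length so each group runs the
        BiGRU without padding; rows are then restored to input order.
        """
        if any(len(t) == 0 for t in tokens):
            raise ValueError("cannot char-encode an empty token")
        by_len: dict[int, list[int]] = {}
        for i, tok in enumerate(tokens):
            by_len.setdefault(len(tok), []).append(i)
        chunks: list[Tensor] = []
        order: list[int] = []
        for length, idxs in sorted(by_len.items()):
            ids = np.array(
                [vocab.encode(tokens[i]) for i in idxs], dtype=np.intp
            )  # (g, length)
            emb = self.embedding(ids)  # (g, length, d_char)
            h_fwd = run_rnn(self.fwd, emb, reverse=False)[-1]  # final fwd state
            h_bwd = run_rnn(self.bwd, emb, reverse=True)[0]  # state at first char
            chunks.append(concatenate([h_bwd, h_fwd], axis=1))
            order.extend(idxs)
        stacked = concatenate(chunks, axis=0) if len(chunks) > 1 else chunks[0]
        inverse = np.empty(len(tokens), dtype=np.intp)
        inverse[np.array(order)] = np.arange(len(tokens))
        return stacked[inverse]

    def encode_token(self, token: str, vocab: CharVocabulary) -> Tensor:
        """Single-token convenience wrapper; returns a (2*d_hidden,) vector."""
        return self.encode_tokens([token], vocab).reshape(2 * self.d_hidden)


class WordVectorTable:
    """Frozen word-vector lookup with a single seeded unknown-word vector."""

    def __init__(
        self,
        vectors: dict[str, np.ndarray],
        dim: int,
        seed: int = 0,
        coverage: float = 1.0,
        n_duplicates: int = 0,
    ):
        self.vectors = vectors
        self.dim = dim
        self.coverage = coverage
        self.n_duplicates = n_duplicates
        # one draw per run, not per lookup, for reproducibility
        self.unknown_vector = np.random.default_rng(seed).normal(0.0, 0.1, size=dim)

    def lookup(self, token: str) -> np.ndarray:
        return self.vectors.get(token, self.unknown_vector)

    def lookup_many(self, tokens: Sequence[str]) -> np.ndarray:
        return np.stack([self.lookup(t) for t in tokens])


def load_word_vectors(
    path: str | Path,
    dimension: int = 100,
    corpus_vocabulary: set[str] | None = None,
    seed: int = 0,
) -> WordVectorTable:
    """Read a GloVe-format text file: one token then `dimension` floats per line.

    The table is restricted to ``corpus_vocabulary`` when given.  Duplicate
    token lines keep the first occurrence; a dimension mismatch on any
    line is a format error naming the line number.
    """
    vectors: dict[str, np.ndarray] = {}
    n_lines = n_dup = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split(" ")
            if len(parts) < 2:
                continue
            token, values = parts[0], parts[1:]
            if len(values) != dimension:
                raise ValueError(
                    f"{path}:{lineno}: expected {dimension} floats, got {len(values)}"
                )
            n_lines += 1
            if token in vectors:
                n_dup += 1
                continue
            if corpus_vocabulary is not None and token not in corpus_vocabulary:
                continue
            vectors[token] = np.array(values, dtype=np.float64)
    coverage = len(vectors) / n_lines if n_lines else 0.0
    if corpus_vocabulary is not None and not vectors:
        logger.warning("word-vector file %s has no overlap with the corpus", path)
    return WordVectorTable(
        vectors, dimension, seed=seed, coverage=coverage, n_duplicates=n_dup
    )


def embed_sentence_fixed(
    tokens: Sequence[str],
    word_table: WordVectorTable,
    char_encoder: CharEncoder | None,
    char_vocab: CharVocabulary | None,
) -> Tensor:
    """Fixed embedding e_i = V_T(s_i) ⊕ b_i for each token of one sentence.

    With ``char_encoder=None`` the character path is disabled and the
    embedding is the bare word vector (the word-vectors-only ablation).
    """
    word_part = Tensor(word_table.lookup_many(tokens))  # frozen
    if char_encoder is None:
        return word_part
    char_part = char_encoder.encode_tokens(tokens, char_vocab)
    return concatenate([word_part, char_part], axis=1)


def positional_encoding(max_len: int, d_model: int) -> np.ndarray:
    """Fixed sinusoidal positional encoding table of shape (max_len, d_model)."""
    pos = np.arange(max_len)[:, None]
    i = np.arange(d_model // 2)[None, :]
    angle = pos / np.power(10000.0, 2.0 * i / d_model)
    pe = np.zeros((max_len, d_model))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def embed_sentence_dynamic(
    ids: np.ndarray, embedding: Embedding, max_len: int
) -> Tensor:
    """Trainable token embeddings plus sinusoidal positions.

    ``ids`` has shape (B, T) or (T,); sequences longer than ``max_len``
    must be split upstream at sentence boundaries — a longer input here
    is a hard error.
    """
    ids = np.asarray(ids, dtype=np.intp)
    T = ids.shape[-1]
    if T > max_len:
        raise ValueError(f"sequence length {T} exceeds max_len {max_len}")
    emb = embedding(ids)
    d_model = embedding.table.shape[1]
    pe = positional_encoding(max_len, d_model)[:T]
    return emb + Tensor(pe)
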
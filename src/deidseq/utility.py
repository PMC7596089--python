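"""Utility metrics for de-identified corpora: BLEU, topic match, classification.

De-identification trades utility for privacy: every removed token —
whether true PHI or a false positive — changes the text that downstream
consumers see.  Three complementary measures quantify what remains:

* **BLEU-n** between each original document (reference) and its
  de-identified version with PHI tokens *removed* (candidate): modified
  n-gram precision with clipping, geometric mean over orders 1..n, and
  the brevity penalty exp(1 − ref_len/cand_len) when the candidate is
  shorter.  The ground-truth arm (gold PHI removed) marks the utility
  attainable at perfect privacy.
* **Topic match**: fit LDA with T topics on the original and the
  de-identified corpus separately (same seed and preprocessing), take
  the top words per topic, align topics across the two fits by maximal
  word overlap, and report the percentage of shared top words.
* **Paired classification**: train the same bag-of-words linear
  classifier on each corpus arm with identical document splits and
  compare test accuracies on a document-level label.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.decomposition import LatentDirichletAllocation
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression

from .corpus_io import AnnotatedDocument, tokenize

logger = logging.getLogger(__name__)

__all__ = [
    "BleuReport",
    "TopicMatchReport",
    "PairedClassificationReport",
    "bleu_n",
    "corpus_bleu",
    "topic_match",
    "paired_classification",
]


# ---------------------------------------------------------------------------
# BLEU
# ---------------------------------------------------------------------------

def _ngrams(tokens: Sequence[str], n: int) -> Counter:
    return Counter(tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1))


def bleu_n(
    reference_tokens: Sequence[str], candidate_tokens: Sequence[str], n: int
) -> float:
    """BLEU with n-gram orders 1..n against a single reference.

    Geometric mean of modified (clipped) n-gram precisions, times the
    brevity penalty exp(1 − ref_len/cand_len) when the candidate is
    shorter than the reference.  An empty candidate scores 0.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not candidate_tokens:
        logger.warning("empty candidate; BLEU = 0")
        return 0.0
    log_precisions = []
    for order in range(1, n + 1):
        cand = _ngrams(candidate_tokens, order)
        ref = _ngrams(reference_tokens, order)
        total = sum(cand.values())
        if total == 0:
            return 0.0
        clipped = sum(min(c, ref[g]) for g, c in cand.items())
        if clipped == 0:
            return 0.0
        log_precisions.append(np.log(clipped / total))
    score = float(np.exp(np.mean(log_precisions)))
    ref_len, cand_len = len(reference_tokens), len(candidate_tokens)
    if cand_len < ref_len:
        score *= float(np.exp(1.0 - ref_len / cand_len))
    return min(score, 1.0)


def _plain_tokens(text: str) -> list[str]:
    doc = AnnotatedDocument(doc_id="_", text=text)
    return [t for sent, _ in tokenize(doc) for t in sent.tokens]


@dataclass
class BleuReport:
    per_document: dict[str, dict[int, float]]
    aggregate: dict[int, float]

    def as_dict(self) -> dict:
        return {
            "aggregate": {f"bleu_{n}": v for n, v in self.aggregate.items()},
            "per_document": {
                d: {f"bleu_{n}": v for n, v in scores.items()}
                for d, scores in self.per_document.items()
            },
        }


def corpus_bleu(
    original: Sequence[AnnotatedDocument],
    deidentified: Mapping[str, str],
    orders: Sequence[int] = (1, 2, 3),
) -> BleuReport:
    """BLEU-n per document and macro-averaged over the corpus.

    ``deidentified`` maps document id to sanitized text (PHI removed).
    Documents must align by id; a missing id is an alignment error.
    """
    per_doc: dict[str, dict[int, float]] = {}
    for doc in original:
        if doc.doc_id not in deidentified:
            raise KeyError(f"no de-identified text for document {doc.doc_id}")
        ref = _plain_tokens(doc.text)
        cand = _plain_tokens(deidentified[doc.doc_id])
        per_doc[doc.doc_id] = {n: bleu_n(ref, cand, n) for n in orders}
    aggregate = {
        n: float(np.mean([s[n] for s in per_doc.values()])) for n in orders
    }
    return BleuReport(per_document=per_doc, aggregate=aggregate)


# ---------------------------------------------------------------------------
# LDA topic match
# ---------------------------------------------------------------------------

@dataclass
class TopicMatchReport:
    per_topic: list[float]  # match % per aligned topic pair
    overall: float  # matched words / (T * words_per_topic) * 100
    alignment: list[tuple[int, int]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "per_topic_percent": self.per_topic,
            "overall_percent": self.overall,
            "alignment": [list(p) for p in self.alignment],
        }


def _top_words(texts: Sequence[str], T: int, words_per_topic: int, seed: int):
    vec = CountVectorizer(lowercase=True, stop_words="english")
    counts = vec.fit_transform(texts)
    vocab = np.array(vec.get_feature_names_out())
    if len(vocab) < words_per_topic:
        raise ValueError(
            f"vocabulary after preprocessing has {len(vocab)} words, "
            f"fewer than words_per_topic={words_per_topic}"
        )
    lda = LatentDirichletAllocation(
        n_components=T, random_state=seed, learning_method="batch", max_iter=20
    )
    lda.fit(counts)
    return [
        set(vocab[np.argsort(row)[::-1][:words_per_topic]])
        for row in lda.components_
    ]


def topic_match(
    original_texts: Sequence[str],
    deidentified_texts: Sequence[str],
    T: int = 5,
    words_per_topic: int = 30,
    seed: int = 0,
    assignment: str = "greedy",
) -> TopicMatchReport:
    """Word overlap of aligned LDA topics between two corpus versions.

    Topics are aligned across the two fits by word overlap — greedy
    maximum matching by default, optimal (Hungarian) assignment with
    ``assignment="hungarian"``.  Preprocessing is identical for both
    corpora: lowercasing and English stopword removal.
    """
    if not original_texts or not deidentified_texts:
        raise ValueError("corpora must be non-empty")
    if T < 1:
        raise ValueError("T must be >= 1")
    topics_a = _top_words(original_texts, T, words_per_topic, seed)
    topics_b = _top_words(deidentified_texts, T, words_per_topic, seed)
    overlap = np.array(
        [[len(a & b) for b in topics_b] for a in topics_a], dtype=float
    )
    pairs: list[tuple[int, int]] = []
    if assignment == "hungarian":
        from scipy.optimize import linear_sum_assignment

        rows, cols = linear_sum_assignment(-overlap)
        pairs = list(zip(rows.tolist(), cols.tolist()))
    elif assignment == "greedy":
        free_a, free_b = set(range(T)), set(range(T))
        while free_a:
            i, j = max(
                ((i, j) for i in free_a for j in free_b),
                key=lambda ij: (overlap[ij], -ij[0], -ij[1]),
            )
            pairs.append((i, j))
            free_a.remove(i)
            free_b.remove(j)
        pairs.sort()
    else:
        raise ValueError(f"unknown assignment {assignment!r}")
    per_topic = [100.0 * overlap[i, j] / words_per_topic for i, j in pairs]
    overall = 100.0 * sum(overlap[i, j] for i, j in pairs) / (T * words_per_topic)
    return TopicMatchReport(per_topic=per_topic, overall=overall, alignment=pairs)


# ---------------------------------------------------------------------------
# paired downstream classification
# ---------------------------------------------------------------------------

@dataclass
class PairedClassificationReport:
    accuracies: dict[str, float]  # arm name -> test accuracy
    n_labels: int
    classes: list[int]

    def as_dict(self) -> dict:
        return {
            "accuracies": self.accuracies,
            "n_labels": self.n_labels,
            "classes": self.classes,
        }


def paired_classification(
    arms: Mapping[str, Mapping[str, str]],
    labels: Mapping[str, int],
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    n_labels: int = 3,
    seed: int = 0,
) -> PairedClassificationReport:
    """Test accuracy of one bag-of-words linear classifier per corpus arm.

    ``arms`` maps arm name (e.g. "original", "deidentified") to
    doc_id → text; every arm is trained and tested on the *same*
    document ids, so accuracy differences reflect only the texts.  The
    ``n_labels`` most frequent classes are kept; a kept class missing
    from the test split is a stratification error.
    """
    counts = Counter(labels[d] for d in train_ids)
    classes = [c for c, _ in counts.most_common(n_labels)]
    tr = [d for d in train_ids if labels[d] in classes]
    te = [d for d in test_ids if labels[d] in classes]
    missing = set(classes) - {labels[d] for d in te}
    if missing:
        raise ValueError(f"classes {sorted(missing)} absent from the test split")
    y_tr = [classes.index(labels[d]) for d in tr]
    y_te = [classes.index(labels[d]) for d in te]
    accuracies = {}
    for name, texts in arms.items():
        vec = CountVectorizer(lowercase=True)
        X_tr = vec.fit_transform([texts[d] for d in tr])
        X_te = vec.transform([texts[d] for d in te])
        clf = LogisticRegression(max_iter=2000, random_state=seed)
        clf.fit(X_tr, y_tr)
        accuracies[name] = float(clf.score(X_te, y_te))
    return PairedClassificationReport(
        accuracies=accuracies, n_labels=n_labels, classes=classes
    )
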
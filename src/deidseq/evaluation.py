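"""Token-level PHI evaluation: precision/recall/F1, dumps, corpus harness.

The primary metric is the binary HIPAA token-based evaluation: every
token is scored PHI vs non-PHI, collapsing sub-categories.  Formulas are
P = TP/(TP+FP), R = TP/(TP+FN), F1 = harmonic mean, with the convention
that a ratio with zero denominator is 0.  Per-category scoring and
entity-span scoring are reported secondarily.  Every report is
re-derivable from the per-token prediction dump (token, gold, predicted),
and ``evaluate_corpus`` checks that equivalence itself.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

from .corpus_io import (
    AnnotatedDocument,
    PhiAnnotation,
    bioes_decode,
    bioes_encode,
    spans_to_annotations,
    tokenize,
)
from .synthetic import GoldCorpus
from .tagger import DeidTagger

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "compute_metrics",
    "counts_from_tags",
    "evaluate_corpus",
    "evaluate_predictions",
    "recount_from_dump",
    "train_on_corpus",
    "corpus_to_sentences",
    "predict_document_annotations",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    precision: float
    recall: float
    f1: float
    counts: ConfusionCounts
    per_category: dict[str, dict] = field(default_factory=dict)
    span_f1: float | None = None
    repairs: int = 0

    def as_dict(self) -> dict:
        d = asdict(self)
        return d


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); 0 on empty denominators."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return MetricsReport(precision=p, recall=r, f1=f1, counts=counts)


def counts_from_tags(
    predicted: Sequence[Sequence[str]], gold: Sequence[Sequence[str]]
) -> ConfusionCounts:
    """Binary PHI/non-PHI confusion counts over aligned tag sequences."""
    tp = fp = fn = tn = 0
    for p_sent, g_sent in zip(predicted, gold):
        if len(p_sent) != len(g_sent):
            raise ValueError("prediction/gold length mismatch")
        for p, g in zip(p_sent, g_sent):
            pp, gg = p != "O", g != "O"
            tp += pp and gg
            fp += pp and not gg
            fn += gg and not pp
            tn += not pp and not gg
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _category_of(tag: str) -> str | None:
    return None if tag == "O" else tag.split("-", 1)[1]


def evaluate_predictions(
    predicted: Sequence[Sequence[str]],
    gold: Sequence[Sequence[str]],
    mode: str = "binary",
    dump_path: str | Path | None = None,
    tokens: Sequence[Sequence[str]] | None = None,
) -> MetricsReport:
    """Score predicted tag sequences against gold.

    Predictions pass through the BIOES repair policy (re-encoding the
    repaired spans) before counting, so ungrammatical model output is
    scored by the spans it would actually sanitize.  ``mode="category"``
    adds a per-category breakdown.  When ``dump_path`` and ``tokens`` are
    given, a CoNLL-style dump is written and independently recounted; a
    mismatch with the report raises.
    """
    repaired, repairs = [], 0
    for tags in predicted:
        spans, n_rep = bioes_decode(tags)
        repaired.append(bioes_encode(spans, len(tags)))
        repairs += n_rep
    report = compute_metrics(counts_from_tags(repaired, gold))
    report.repairs = repairs

    if mode == "category":
        cats = sorted(
            {c for tags in gold for t in tags if (c := _category_of(t)) is not None}
        )
        for cat in cats:
            tp = fp = fn = 0
            for p_sent, g_sent in zip(repaired, gold):
                for p, g in zip(p_sent, g_sent):
                    pc, gc = _category_of(p) == cat, _category_of(g) == cat
                    tp += pc and gc
                    fp += pc and not gc
                    fn += gc and not pc
            sub = compute_metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn))
            report.per_category[cat] = {
                "precision": sub.precision,
                "recall": sub.recall,
                "f1": sub.f1,
                "support": tp + fn,
            }

    # span-level (exact category+boundary match), secondary
    gold_spans = pred_spans = span_tp = 0
    for p_sent, g_sent in zip(repaired, gold):
        ps, _ = bioes_decode(p_sent)
        gs, _ = bioes_decode(g_sent)
        gold_spans += len(gs)
        pred_spans += len(ps)
        span_tp += len(set(ps) & set(gs))
    sp = span_tp / pred_spans if pred_spans else 0.0
    sr = span_tp / gold_spans if gold_spans else 0.0
    report.span_f1 = 2 * sp * sr / (sp + sr) if sp + sr else 0.0

    if dump_path is not None:
        if tokens is None:
            raise ValueError("dump requires the token sequences")
        with open(dump_path, "w", encoding="utf-8") as fh:
            for toks, g_sent, p_sent in zip(tokens, gold, repaired):
                for tok, g, p in zip(toks, g_sent, p_sent):
                    fh.write(f"{tok}\t{g}\t{p}\n")
                fh.write("\n")
        recount = recount_from_dump(dump_path)
        if asdict(recount.counts) != asdict(report.counts):
            raise AssertionError("report disagrees with dump recount")
    return report


def recount_from_dump(path: str | Path) -> MetricsReport:
    """Independent metric recomputation from a (token, gold, pred) dump."""
    gold, pred = [], []
    g_sent: list[str] = []
    p_sent: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                if g_sent:
                    gold.append(g_sent)
                    pred.append(p_sent)
                    g_sent, p_sent = [], []
                continue
            _, g, p = line.split("\t")
            g_sent.append(g)
            p_sent.append(p)
    if g_sent:
        gold.append(g_sent)
        pred.append(p_sent)
    return compute_metrics(counts_from_tags(pred, gold))


# ---------------------------------------------------------------------------
# corpus-level harness
# ---------------------------------------------------------------------------

def corpus_to_sentences(
    corpus: GoldCorpus, split: str
) -> tuple[list[list[str]], list[list[str]]]:
    """Tokenized sentences and gold tags for one split of a corpus."""
    X, y = [], []
    for doc in corpus.split(split):
        for sent, tags in tokenize(doc):
            X.append(sent.tokens)
            y.append(tags)
    return X, y


def evaluate_corpus(
    tagger: DeidTagger,
    corpus: GoldCorpus,
    split: str = "test",
    mode: str = "binary",
    dump_path: str | Path | None = None,
) -> MetricsReport:
    """Token-level evaluation of a fitted tagger on one corpus split."""
    X, y = corpus_to_sentences(corpus, split)
    if not X:
        raise ValueError(f"split {split!r} is empty")
    predicted = tagger.predict(X)
    return evaluate_predictions(
        predicted, y, mode=mode, dump_path=dump_path, tokens=X
    )


def train_on_corpus(corpus: GoldCorpus, **tagger_kwargs) -> DeidTagger:
    """Fit a :class:`DeidTagger` on a corpus's train split, early-stopping
    on its validation split."""
    X_tr, y_tr = corpus_to_sentences(corpus, "train")
    X_val, y_val = corpus_to_sentences(corpus, "validation")
    tagger = DeidTagger(**tagger_kwargs)
    tagger.fit(X_tr, y_tr, validation_data=(X_val, y_val))
    return tagger


def save_metrics(report: MetricsReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.as_dict(), indent=2))


def predict_document_annotations(
    tagger: DeidTagger, document: AnnotatedDocument
) -> list[PhiAnnotation]:
    """Character-offset PHI predictions for one document.

    Tokenizes, predicts tag sequences, repairs them to valid span sets
    and lifts token spans back to character offsets.
    """
    annotations: list[PhiAnnotation] = []
    pairs = tokenize(document)
    if not pairs:
        return annotations
    sentences = [sent for sent, _ in pairs]
    predicted = tagger.predict([s.tokens for s in sentences])
    for sent, tags in zip(sentences, predicted):
        spans, _ = bioes_decode(tags)
        annotations.extend(spans_to_annotations(spans, sent, document.text))
    return annotations
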
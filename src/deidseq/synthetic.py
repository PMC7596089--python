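"""Synthetic annotated clinical-note corpora with planted PHI.

Real de-identification corpora (i2b2 2014, nursing notes, MIMIC) are
access-restricted, so this module fabricates note-like documents from
sentence skeletons with typed slots: background clinical prose drawn from
a fixed vocabulary, interleaved with PHI fillers (names, dates, hospitals,
phone numbers, record IDs, ages, locations, professions) drawn from
category lexicons.  Every filler is annotated with its category and exact
character span, so the corpus is a fully labeled gold standard.

Properties the generator guarantees:

* byte-identical output for identical configuration (single seeded RNG,
  no global state);
* the expected number of PHI instances per sentence equals
  ``phi_per_sentence`` exactly (integer part plus one Bernoulli draw);
* no PHI filler string occurs in the background vocabulary, so gold
  labels are unambiguous;
* a configurable fraction of each lexicon is held out and appears only
  in test-split documents, to exercise out-of-vocabulary generalization;
* non-PHI tokens outnumber PHI tokens by at least an order of magnitude
  under the defaults, mirroring the heavy class imbalance of real notes.

Documents also carry a synthetic discharge-class label (planted
class-specific keywords in the background prose) so the downstream
classification utility metric has something to predict.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus_io import (
    AnnotatedDocument,
    PhiAnnotation,
    read_i2b2_xml,
    tokenize,
    write_i2b2_xml,
)

__all__ = [
    "GeneratorConfig",
    "GoldCorpus",
    "generate_corpus",
    "corpus_statistics",
    "write_corpus",
    "read_corpus",
]

DEFAULT_CATEGORIES = (
    "PATIENT",
    "DOCTOR",
    "DATE",
    "HOSPITAL",
    "PHONE",
    "ID",
    "AGE",
    "LOCATION",
    "PROFESSION",
)

_SYLLABLES = [
    "ba", "den", "fer", "gal", "hem", "jor", "kel", "lin", "mor", "nev",
    "pol", "quin", "ras", "sel", "tam", "ul", "ver", "wex", "yor", "zan",
    "bri", "cor", "dul", "eth", "fin",
]

_PROFESSIONS = [
    "carpenter", "electrician", "librarian", "plumber", "welder",
    "accountant", "barber", "florist", "janitor", "machinist",
    "tailor", "baker", "farmer", "painter", "mechanic",
    "waiter", "cashier", "locksmith", "glazier", "surveyor",
    "courier", "jeweler", "butcher", "roofer", "typist",
    "clerk", "mason", "porter", "weaver", "cooper",
]

# deliberately small, clinical-flavored background word stock; padded out to
# background_vocab_size with coined lowercase fillers
_CLINICAL_WORDS = """
the patient was admitted with complaints of chest pain and shortness of
breath on examination vitals were stable denies fever chills nausea
vomiting abdominal tenderness history significant for hypertension
diabetes hyperlipidemia asthma medications include daily aspirin insulin
continued during stay labs showed elevated white count normal electrolytes
renal function imaging revealed no acute process lungs clear to
auscultation heart regular rate rhythm without murmur abdomen soft
nontender bowel sounds present extremities warm well perfused neurologic
exam intact alert oriented discharged home in improved condition follow
up arranged as outpatient tolerated procedure well course uncomplicated
started empiric antibiotics symptoms resolved gradually over several days
blood pressure controlled oral agents glucose monitored closely remained
afebrile throughout wound healing appropriately instructed to return if
worsening repeat studies recommended prior results reviewed plan discussed
family understanding verbalized diet advanced tolerated ambulating without
assistance pain managed acetaminophen
""".split()


class ConfigurationError(ValueError):
    """Bad generator configuration (unknown category, invalid rate, ...)."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything that determines a generated corpus, seed included."""

    seed: int = 0
    n_documents: int = 100
    sentences_per_document: tuple[int, int] = (8, 12)
    phi_categories: tuple[str, ...] = DEFAULT_CATEGORIES
    phi_per_sentence: float = 0.8
    lexicon_sizes: dict[str, int] = field(default_factory=dict)
    background_vocab_size: int = 400
    multi_token_phi_fraction: float = 0.3
    heldout_lexicon_fraction: float = 0.2
    n_classes: int = 3

    def __post_init__(self):
        if self.phi_per_sentence < 0:
            raise ConfigurationError("phi_per_sentence must be >= 0")
        unknown = set(self.lexicon_sizes) - set(self.phi_categories)
        if unknown:
            raise ConfigurationError(f"unknown categories in lexicon_sizes: {sorted(unknown)}")
        for cat in self.phi_categories:
            if cat not in DEFAULT_CATEGORIES:
                raise ConfigurationError(f"unknown PHI category {cat!r}")
        if not 0 <= self.multi_token_phi_fraction <= 1:
            raise ConfigurationError("multi_token_phi_fraction must be in [0, 1]")


@dataclass
class GoldCorpus:
    """Generated documents plus train/validation/test assignment and labels."""

    documents: list[AnnotatedDocument]
    split_assignment: dict[str, str]
    labels: dict[str, int]
    config: GeneratorConfig

    def split(self, name: str) -> list[AnnotatedDocument]:
        if name not in ("train", "validation", "test"):
            raise ValueError(f"unknown split {name!r}")
        return [d for d in self.documents if self.split_assignment[d.doc_id] == name]


# ---------------------------------------------------------------------------
# lexicon construction
# ---------------------------------------------------------------------------

def _coin_words(rng: np.random.Generator, n: int, n_syl=(2, 3), taken=()) -> list[str]:
    words: list[str] = []
    seen = set(taken)
    while len(words) < n:
        k = rng.integers(n_syl[0], n_syl[1] + 1)
        w = "".join(rng.choice(_SYLLABLES) for _ in range(k))
        if w not in seen:
            seen.add(w)
            words.append(w)
    return words


def _build_lexicons(
    config: GeneratorConfig, rng: np.random.Generator, background: set[str]
) -> dict[str, list[str]]:
    sizes = {c: config.lexicon_sizes.get(c, 40) for c in config.phi_categories}
    for cat, size in sizes.items():
        if size <= 0:
            raise ConfigurationError(f"lexicon for {cat} must be non-empty")
    lex: dict[str, list[str]] = {}
    mt = config.multi_token_phi_fraction

    def names(n):
        pool = [w.capitalize() for w in _coin_words(rng, 2 * n)]
        first, last = pool[:n], pool[n:]
        out = []
        for i in range(n):
            multi = rng.random() < mt
            out.append(f"{first[i]} {last[i]}" if multi else first[i])
        return out

    for cat in config.phi_categories:
        n = sizes[cat]
        if cat in ("PATIENT", "DOCTOR"):
            lex[cat] = names(n)
        elif cat == "DATE":
            lex[cat] = [
                f"{rng.integers(1, 13):02d}/{rng.integers(1, 29):02d}/{rng.integers(1998, 2021)}"
                for _ in range(n)
            ]
        elif cat == "HOSPITAL":
            stems = [w.capitalize() for w in _coin_words(rng, n)]
            suffixes = ["Hospital", "Medical Center", "Clinic", "General Hospital"]
            lex[cat] = [
                f"{s} {suffixes[rng.integers(len(suffixes))]}" if rng.random() < mt else s
                for s in stems
            ]
        elif cat == "PHONE":
            lex[cat] = [
                f"{rng.integers(200, 1000)}-{rng.integers(200, 1000)}-{rng.integers(1000, 10000)}"
                for _ in range(n)
            ]
        elif cat == "ID":
            lex[cat] = [str(rng.integers(1_000_000, 10_000_000)) for _ in range(n)]
        elif cat == "AGE":
            ages = rng.permutation(np.arange(18, 96))[: min(n, 78)]
            lex[cat] = [str(a) for a in ages]
        elif cat == "LOCATION":
            stems = [w.capitalize() for w in _coin_words(rng, n)]
            prefixes = ["North", "South", "East", "West", "Lake", "Port"]
            lex[cat] = [
                f"{prefixes[rng.integers(len(prefixes))]} {s}" if rng.random() < mt else s
                for s in stems
            ]
        elif cat == "PROFESSION":
            perm = rng.permutation(len(_PROFESSIONS))
            lex[cat] = [_PROFESSIONS[i] for i in perm[: min(n, len(_PROFESSIONS))]]
        # uniqueness within a category
        lex[cat] = list(dict.fromkeys(lex[cat]))
        clash = {t for surf in lex[cat] for t in surf.split()} & background
        if clash:
            raise ConfigurationError(
                f"PHI lexicon for {cat} collides with background vocabulary: {sorted(clash)[:5]}"
            )
    return lex


# PHI slot phrasings per category: (before-words, after-words)
_SLOT_PHRASES = {
    "PATIENT": [("patient", ""), ("seen with", ""), ("regarding", "")],
    "DOCTOR": [("seen by Dr.", ""), ("attending Dr.", ""), ("referred by Dr.", "")],
    "DATE": [("admitted on", ""), ("on", ""), ("discharged on", "")],
    "HOSPITAL": [("transferred to", ""), ("at", ""), ("presented to", "")],
    "PHONE": [("contact number", ""), ("call", ""), ("reachable at", "")],
    "ID": [("record number", ""), ("mrn", ""), ("account", "")],
    "AGE": [("a", "year old"), ("aged", ""), ("age", "")],
    "LOCATION": [("resides in", ""), ("from", ""), ("lives near", "")],
    "PROFESSION": [("works as a", ""), ("employed as a", ""), ("occupation", "")],
}


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_corpus(config: GeneratorConfig) -> GoldCorpus:
    """Generate a reproducible gold-annotated corpus from ``config``.

    Splits follow the convention of holding out 20% of documents for test
    and re-splitting the remainder 80:20 into train and validation.
    """
    rng = np.random.default_rng(config.seed)

    bg_words = list(dict.fromkeys(_CLINICAL_WORDS))
    bg_words = [w for w in bg_words if w not in _PROFESSIONS]
    if config.background_vocab_size > len(bg_words):
        bg_words += _coin_words(
            rng,
            config.background_vocab_size - len(bg_words),
            taken=set(bg_words) | set(_PROFESSIONS),
        )
    background = set(bg_words)

    # class keyword sets: disjoint slices of the background vocabulary tail
    kw_per_class = 6
    n_kw = config.n_classes * kw_per_class
    keywords = [
        bg_words[-n_kw:][c * kw_per_class : (c + 1) * kw_per_class]
        for c in range(config.n_classes)
    ]

    lexicons = _build_lexicons(config, rng, background)
    heldout = {
        cat: max(1, int(round(config.heldout_lexicon_fraction * len(entries))))
        for cat, entries in lexicons.items()
    }
    train_pool = {cat: entries[h:] for cat, (entries, h) in
                  ((c, (lexicons[c], heldout[c])) for c in lexicons)}

    # split assignment first, so test documents can use held-out lexicon entries
    doc_ids = [f"doc-{i:05d}" for i in range(config.n_documents)]
    order = rng.permutation(config.n_documents)
    n_test = int(round(0.2 * config.n_documents))
    n_val = int(round(0.2 * 0.8 * config.n_documents))
    assignment = {}
    for rank, idx in enumerate(order):
        if rank < n_test:
            assignment[doc_ids[idx]] = "test"
        elif rank < n_test + n_val:
            assignment[doc_ids[idx]] = "validation"
        else:
            assignment[doc_ids[idx]] = "train"

    base = int(np.floor(config.phi_per_sentence))
    frac = config.phi_per_sentence - base

    def bg_fragment(lo: int, hi: int, label: int) -> str:
        k = int(rng.integers(lo, hi + 1))
        words = [bg_words[rng.integers(len(bg_words))] for _ in range(k)]
        if config.n_classes and rng.random() < 0.35:
            kws = keywords[label]
            words[rng.integers(len(words))] = kws[rng.integers(len(kws))]
        return " ".join(words)

    documents, labels = [], {}
    for doc_id in doc_ids:
        label = int(rng.integers(config.n_classes)) if config.n_classes else 0
        labels[doc_id] = label
        pools = lexicons if assignment[doc_id] == "test" else train_pool
        pieces: list[str] = []
        annotations: list[PhiAnnotation] = []
        pos = 0
        n_sent = int(rng.integers(*config.sentences_per_document))
        for _ in range(n_sent):
            n_phi = base + (1 if rng.random() < frac else 0)
            parts: list[str | tuple[str, str]] = [bg_fragment(4, 8, label)]
            for _ in range(n_phi):
                cat = config.phi_categories[rng.integers(len(config.phi_categories))]
                phr_before, phr_after = _SLOT_PHRASES[cat][
                    rng.integers(len(_SLOT_PHRASES[cat]))
                ]
                entries = pools[cat]
                surface = entries[rng.integers(len(entries))]
                if phr_before:
                    parts.append(phr_before)
                parts.append((cat, surface))
                if phr_after:
                    parts.append(phr_after)
            parts.append(bg_fragment(3, 6, label))
            # render the sentence, tracking filler offsets
            for part in parts:
                if isinstance(part, tuple):
                    cat, surface = part
                    annotations.append(
                        PhiAnnotation(cat, pos, pos + len(surface), surface)
                    )
                    pieces.append(surface)
                    pos += len(surface)
                else:
                    pieces.append(part)
                    pos += len(part)
                pieces.append(" ")
                pos += 1
            pieces.append(".\n")
            pos += 2
        text = "".join(pieces)
        doc = AnnotatedDocument(doc_id=doc_id, text=text, annotations=annotations)
        doc.validate()
        documents.append(doc)

    return GoldCorpus(
        documents=documents,
        split_assignment=assignment,
        labels=labels,
        config=config,
    )


def corpus_statistics(corpus: GoldCorpus) -> dict:
    """Per-category PHI counts plus token/sentence/document totals."""
    if not corpus.documents:
        raise ValueError("empty corpus")
    cats = {c: 0 for c in corpus.config.phi_categories}
    n_tokens = n_phi_tokens = n_sentences = 0
    for doc in corpus.documents:
        for ann in doc.annotations:
            cats[ann.category] += 1
        for sent, tags in tokenize(doc):
            n_sentences += 1
            n_tokens += sent.n
            n_phi_tokens += sum(1 for t in tags if t != "O")
    return {
        "per_category": cats,
        "total_annotations": sum(cats.values()),
        "documents": len(corpus.documents),
        "sentences": n_sentences,
        "tokens": n_tokens,
        "phi_tokens": n_phi_tokens,
        "non_phi_tokens": n_tokens - n_phi_tokens,
    }


# ---------------------------------------------------------------------------
# persistence: XML per document + JSON sidecar
# ---------------------------------------------------------------------------

def write_corpus(corpus: GoldCorpus, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for doc in corpus.documents:
        write_i2b2_xml(doc, out_dir / f"{doc.doc_id}.xml")
    sidecar = {
        "config": dataclasses.asdict(corpus.config),
        "split_assignment": corpus.split_assignment,
        "labels": corpus.labels,
    }
    (out_dir / "corpus.json").write_text(json.dumps(sidecar, indent=2))


def read_corpus(in_dir: str | Path) -> GoldCorpus:
    in_dir = Path(in_dir)
    sidecar = json.loads((in_dir / "corpus.json").read_text())
    cfg = sidecar["config"]
    cfg["phi_categories"] = tuple(cfg["phi_categories"])
    cfg["sentences_per_document"] = tuple(cfg["sentences_per_document"])
    config = GeneratorConfig(**cfg)
    documents = [
        read_i2b2_xml(p) for p in sorted(in_dir.glob("doc-*.xml"))
    ]
    return GoldCorpus(
        documents=documents,
        split_assignment=sidecar["split_assignment"],
        labels={k: int(v) for k, v in sidecar["labels"].items()},
        config=config,
    )
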
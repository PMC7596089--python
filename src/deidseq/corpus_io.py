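"""Corpus I/O: annotated documents, tokenization, BIOES tags, numeric indexing.

Conventions used throughout the package:

* Character offsets are 0-based with half-open ends, everywhere.
* The tokenizer is rule-based: whitespace split, then punctuation split off
  as separate tokens, except that runs of digits with internal ``/ - . :``
  (dates, phone numbers, record IDs) stay intact and a small set of
  clinical abbreviations ("Dr.", "Mr.", ...) keep their trailing period.
* PHI spans always cover whole tokens; a token that straddles an annotation
  boundary is split at that boundary rather than ever dropping a PHI token.
* Tag sequences follow the BIOES scheme: ``O`` for non-PHI, and
  ``B-cat I-cat ... E-cat`` for multi-token spans, ``S-cat`` for
  single-token spans.  Invalid model output is repaired, never discarded
  (an orphan ``I`` opens a span like ``B``; an orphan ``E`` closes a
  single-token span like ``S``; an unclosed span is closed at its last
  contiguous same-category token), and repairs are counted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from lxml import etree

__all__ = [
    "PhiAnnotation",
    "AnnotatedDocument",
    "Sentence",
    "Vocabulary",
    "LabelIndex",
    "IntegrityError",
    "tokenize",
    "bioes_encode",
    "bioes_decode",
    "spans_to_annotations",
    "read_i2b2_xml",
    "write_i2b2_xml",
    "read_conll",
    "write_conll",
    "write_deidentified",
]

PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"

_ABBREVIATIONS = frozenset(
    {"Dr.", "Mr.", "Mrs.", "Ms.", "St.", "Jr.", "Sr.", "Prof.", "vs.", "No."}
)
# digit-anchored runs (dates, phones, IDs) kept whole; otherwise words vs
# single punctuation marks
_TOKEN_RE = re.compile(r"\d[\w/\-.:]*\d|\w+|[^\w\s]")
_CHUNK_RE = re.compile(r"\S+")
_SENT_BREAK_RE = re.compile(r"(?<=[.!?])[ \t]+|\n+")


class IntegrityError(ValueError):
    """Raised when annotations and text disagree."""


@dataclass(frozen=True)
class PhiAnnotation:
    """One PHI span: category plus half-open character offsets."""

    category: str
    start: int
    end: int
    surface: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty span [{self.start}, {self.end})")


@dataclass
class AnnotatedDocument:
    """Raw note text with character-offset PHI annotations."""

    doc_id: str
    text: str
    annotations: list[PhiAnnotation] = field(default_factory=list)

    def validate(self) -> None:
        prev_end = -1
        for ann in sorted(self.annotations, key=lambda a: a.start):
            if ann.start < 0 or ann.end > len(self.text):
                raise IntegrityError(
                    f"{self.doc_id}: span [{ann.start}, {ann.end}) outside text"
                )
            if ann.start < prev_end:
                raise IntegrityError(f"{self.doc_id}: overlapping annotations")
            got = self.text[ann.start : ann.end]
            if got != ann.surface:
                raise IntegrityError(
                    f"{self.doc_id}: span [{ann.start}, {ann.end}) reads "
                    f"{got!r}, annotation says {ann.surface!r}"
                )
            prev_end = ann.end


@dataclass
class Sentence:
    """Tokenized sentence with per-token character spans into the document."""

    tokens: list[str]
    char_spans: list[tuple[int, int]]

    @property
    def n(self) -> int:
        return len(self.tokens)


# ---------------------------------------------------------------------------
# tokenization
# ---------------------------------------------------------------------------

def _sentence_ranges(text: str) -> list[tuple[int, int]]:
    ranges, pos = [], 0
    for m in _SENT_BREAK_RE.finditer(text):
        # don't break right after a known abbreviation
        head = text[pos : m.start()]
        last = head.rsplit(None, 1)[-1] if head.split() else ""
        if last in _ABBREVIATIONS and "\n" not in m.group():
            continue
        if m.start() > pos:
            ranges.append((pos, m.start()))
        pos = m.end()
    if pos < len(text) and text[pos:].strip():
        ranges.append((pos, len(text)))
    return ranges


def _raw_token_spans(text: str, lo: int, hi: int) -> list[tuple[int, int]]:
    spans = []
    for chunk in _CHUNK_RE.finditer(text, lo, hi):
        s = chunk.group()
        if s in _ABBREVIATIONS:
            spans.append((chunk.start(), chunk.end()))
            continue
        for m in _TOKEN_RE.finditer(s):
            spans.append((chunk.start() + m.start(), chunk.start() + m.end()))
    return spans


def _split_at_boundaries(
    spans: list[tuple[int, int]], boundaries: set[int]
) -> list[tuple[int, int]]:
    out = []
    for s, e in spans:
        cuts = sorted(b for b in boundaries if s < b < e)
        prev = s
        for c in cuts:
            out.append((prev, c))
            prev = c
        out.append((prev, e))
    return out


def tokenize(
    document: AnnotatedDocument,
) -> list[tuple[Sentence, list[str]]]:
    """Split a document into sentences with aligned BIOES tag sequences.

    Every annotation is covered by whole tokens: token boundaries are
    adjusted to honor annotation boundaries (a PHI token is never dropped).
    An annotation crossing a sentence boundary is an integrity error.
    """
    document.validate()
    text = document.text
    boundaries = {a.start for a in document.annotations} | {
        a.end for a in document.annotations
    }
    results = []
    for lo, hi in _sentence_ranges(text):
        spans = _split_at_boundaries(_raw_token_spans(text, lo, hi), boundaries)
        if not spans:
            continue
        tokens = [text[s:e] for s, e in spans]
        sent = Sentence(tokens=tokens, char_spans=spans)
        tags = ["O"] * len(tokens)
        for ann in document.annotations:
            if ann.end <= lo or ann.start >= hi:
                continue
            if ann.start < lo or ann.end > hi:
                raise IntegrityError(
                    f"{document.doc_id}: annotation [{ann.start}, {ann.end}) "
                    "crosses a sentence boundary"
                )
            idx = [
                i for i, (s, e) in enumerate(spans) if s < ann.end and e > ann.start
            ]
            if not idx:
                raise IntegrityError(
                    f"{document.doc_id}: annotation [{ann.start}, {ann.end}) "
                    "covers no token"
                )
            if len(idx) == 1:
                tags[idx[0]] = f"S-{ann.category}"
            else:
                tags[idx[0]] = f"B-{ann.category}"
                for i in idx[1:-1]:
                    tags[i] = f"I-{ann.category}"
                tags[idx[-1]] = f"E-{ann.category}"
        results.append((sent, tags))
    return results


# ---------------------------------------------------------------------------
# BIOES encode / decode
# ---------------------------------------------------------------------------

def bioes_encode(spans: Sequence[tuple[str, int, int]], n: int) -> list[str]:
    """Encode (category, first_token, last_token) spans as BIOES tags.

    Token indices are inclusive on both ends.  Spans must be disjoint.
    """
    tags = ["O"] * n
    for cat, i0, i1 in spans:
        if not (0 <= i0 <= i1 < n):
            raise ValueError(f"span ({i0}, {i1}) outside sentence of length {n}")
        if any(tags[i] != "O" for i in range(i0, i1 + 1)):
            raise ValueError("overlapping spans")
        if i0 == i1:
            tags[i0] = f"S-{cat}"
        else:
            tags[i0] = f"B-{cat}"
            for i in range(i0 + 1, i1):
                tags[i] = f"I-{cat}"
            tags[i1] = f"E-{cat}"
    return tags


def bioes_decode(
    tags: Sequence[str],
) -> tuple[list[tuple[str, int, int]], int]:
    """Decode BIOES tags to (category, first, last) token spans.

    Invalid transitions are repaired rather than dropped (privacy first);
    the second return value counts the repairs applied.
    """
    spans: list[tuple[str, int, int]] = []
    repairs = 0
    open_cat: str | None = None
    open_start = 0

    def close(last: int):
        nonlocal open_cat
        if open_cat is not None:
            spans.append((open_cat, open_start, last))
            open_cat = None

    for i, tag in enumerate(tags):
        if tag == "O":
            if open_cat is not None:
                close(i - 1)
                repairs += 1  # unclosed B/I run
            continue
        prefix, _, cat = tag.partition("-")
        if prefix == "S":
            if open_cat is not None:
                close(i - 1)
                repairs += 1
            spans.append((cat, i, i))
        elif prefix == "B":
            if open_cat is not None:
                close(i - 1)
                repairs += 1
            open_cat, open_start = cat, i
        elif prefix == "I":
            if open_cat == cat:
                continue
            if open_cat is not None:
                close(i - 1)
            open_cat, open_start = cat, i  # orphan I treated as B
            repairs += 1
        elif prefix == "E":
            if open_cat == cat:
                close(i)
            else:
                if open_cat is not None:
                    close(i - 1)
                spans.append((cat, i, i))  # orphan E treated as S
                repairs += 1
        else:
            raise ValueError(f"unknown tag {tag!r}")
    if open_cat is not None:
        close(len(tags) - 1)
        repairs += 1
    return spans, repairs


def spans_to_annotations(
    spans: Sequence[tuple[str, int, int]], sentence: Sentence, text: str
) -> list[PhiAnnotation]:
    """Lift token-index spans to character-offset annotations."""
    out = []
    for cat, i0, i1 in spans:
        start = sentence.char_spans[i0][0]
        end = sentence.char_spans[i1][1]
        out.append(PhiAnnotation(cat, start, end, text[start:end]))
    return out


# ---------------------------------------------------------------------------
# numeric indexing
# ---------------------------------------------------------------------------

class Vocabulary:
    """Token-to-id bijection with reserved pad and unknown ids."""

    def __init__(self, tokens: Iterable[str]):
        self.id_to_token = [PAD_TOKEN, UNK_TOKEN]
        self.token_to_id: dict[str, int] = {PAD_TOKEN: 0, UNK_TOKEN: 1}
        for tok in tokens:
            if tok not in self.token_to_id:
                self.token_to_id[tok] = len(self.id_to_token)
                self.id_to_token.append(tok)

    pad_id = 0
    unknown_id = 1

    def __len__(self) -> int:
        return len(self.id_to_token)

    def encode(self, tokens: Sequence[str]) -> list[int]:
        return [self.token_to_id.get(t, self.unknown_id) for t in tokens]

    def decode(self, ids: Sequence[int]) -> list[str]:
        return [self.id_to_token[i] for i in ids]


class LabelIndex:
    """BIOES label set over a fixed list of PHI categories.

    Total label count is ``4 * n_categories + 1`` (B/I/E/S per category
    plus O).  ``O`` always has id 0.
    """

    def __init__(self, categories: Sequence[str]):
        self.categories = list(categories)
        self.labels = ["O"] + [
            f"{p}-{c}" for c in self.categories for p in ("B", "I", "E", "S")
        ]
        self.label_to_id = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def k(self) -> int:
        return len(self.labels)

    def encode(self, tags: Sequence[str]) -> list[int]:
        try:
            return [self.label_to_id[t] for t in tags]
        except KeyError as err:
            raise KeyError(f"label {err.args[0]!r} not in label index") from None

    def decode(self, ids: Sequence[int]) -> list[str]:
        return [self.labels[i] for i in ids]


# ---------------------------------------------------------------------------
# i2b2-style XML
# ---------------------------------------------------------------------------

def write_i2b2_xml(document: AnnotatedDocument, path: str | Path) -> None:
    root = etree.Element("deIdi2b2")
    text_el = etree.SubElement(root, "TEXT")
    text_el.text = etree.CDATA(document.text)
    tags_el = etree.SubElement(root, "TAGS")
    for i, ann in enumerate(document.annotations):
        etree.SubElement(
            tags_el,
            ann.category,
            id=f"P{i}",
            start=str(ann.start),
            end=str(ann.end),
            text=ann.surface,
            TYPE=ann.category,
        )
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


def read_i2b2_xml(path: str | Path) -> AnnotatedDocument:
    """Read one note in i2b2-2014-style XML (TEXT + TAGS with offsets)."""
    path = Path(path)
    tree = etree.parse(str(path))
    root = tree.getroot()
    text_el = root.find("TEXT")
    if text_el is None:
        raise IntegrityError(f"{path}: missing TEXT element")
    text = text_el.text or ""
    annotations = []
    tags_el = root.find("TAGS")
    if tags_el is not None:
        for el in tags_el:
            start = int(el.get("start"))
            end = int(el.get("end"))
            category = el.get("TYPE") or el.tag
            surface = el.get("text", text[start:end])
            annotations.append(PhiAnnotation(category, start, end, surface))
    doc = AnnotatedDocument(doc_id=path.stem, text=text, annotations=annotations)
    doc.validate()
    return doc


# ---------------------------------------------------------------------------
# CoNLL-style TSV
# ---------------------------------------------------------------------------

def write_conll(
    sentences: Sequence[tuple[Sentence, list[str]]], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sent, tags in sentences:
            for tok, tag in zip(sent.tokens, tags):
                fh.write(f"{tok}\t{tag}\n")
            fh.write("\n")


def read_conll(path: str | Path) -> list[tuple[list[str], list[str]]]:
    sentences, tokens, tags = [], [], []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                if tokens:
                    sentences.append((tokens, tags))
                    tokens, tags = [], []
                continue
            tok, _, tag = line.partition("\t")
            tokens.append(tok)
            tags.append(tag)
    if tokens:
        sentences.append((tokens, tags))
    return sentences


# ---------------------------------------------------------------------------
# de-identified output
# ---------------------------------------------------------------------------

def _merge_spans(
    annotations: Sequence[PhiAnnotation], text: str
) -> list[PhiAnnotation]:
    if not annotations:
        return []
    anns = sorted(annotations, key=lambda a: a.start)
    merged = [anns[0]]
    for ann in anns[1:]:
        last = merged[-1]
        if ann.start < last.end:  # overlap: merge, keep first category
            end = max(last.end, ann.end)
            merged[-1] = PhiAnnotation(
                last.category, last.start, end, text[last.start : end]
            )
        else:
            merged.append(ann)
    return merged


def write_deidentified(
    document: AnnotatedDocument,
    predicted: Sequence[PhiAnnotation],
    mode: str = "placeholder",
) -> str:
    """Render the sanitized text of a document.

    ``mode="remove"`` deletes PHI spans outright (the form used by the
    utility metrics, where false positives and negatives change the token
    count); ``mode="placeholder"`` substitutes ``[CATEGORY]`` markers
    (the release format).  Overlapping predictions are merged first.
    """
    if mode not in ("remove", "placeholder"):
        raise ValueError(f"unknown mode {mode!r}")
    pieces = []
    pos = 0
    for ann in _merge_spans(predicted, document.text):
        pieces.append(document.text[pos : ann.start])
        if mode == "placeholder":
            pieces.append(f"[{ann.category}]")
        pos = ann.end
    pieces.append(document.text[pos:])
    text = "".join(pieces)
    if mode == "remove":
        # collapse doubled spaces left by deletions, preserving line structure
        text = "\n".join(re.sub(r"[ \t]{2,}", " ", ln).strip() for ln in text.split("\n"))
    return text
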
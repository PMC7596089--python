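"""Tokenization, BIOES coding, serialization round trips."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from deidseq.corpus_io import (
    AnnotatedDocument,
    IntegrityError,
    LabelIndex,
    PhiAnnotation,
    Sentence,
    Vocabulary,
    bioes_decode,
    bioes_encode,
    read_conll,
    read_i2b2_xml,
    tokenize,
    write_conll,
    write_deidentified,
    write_i2b2_xml,
)


def make_doc(text, spans):
    anns = [PhiAnnotation(cat, s, e, text[s:e]) for cat, s, e in spans]
    return AnnotatedDocument(doc_id="d", text=text, annotations=anns)


class TestTokenize:
    def test_multi_token_annotation_gets_begin_end_tags(self):
        text = "Seen by Dr. John Smith today"
        doc = make_doc(text, [("DOCTOR", text.index("John"), text.index("John") + 10)])
        [(sent, tags)] = tokenize(doc)
        assert sent.tokens == ["Seen", "by", "Dr.", "John", "Smith", "today"]
        assert tags == ["O", "O", "O", "B-DOCTOR", "E-DOCTOR", "O"]

    def test_single_token_annotation_gets_single_tag(self):
        text = "Discharged 03/04/09 home"
        doc = make_doc(text, [("DATE", 11, 19)])
        [(sent, tags)] = tokenize(doc)
        assert "03/04/09" in sent.tokens
        assert tags[sent.tokens.index("03/04/09")] == "S-DATE"

    def test_punctuation_split_off_but_digit_patterns_kept(self):
        doc = make_doc("Call (204) 555-0134 now.", [])
        [(sent, _)] = tokenize(doc)
        assert "(" in sent.tokens and ")" in sent.tokens
        assert "555-0134" in sent.tokens

    def test_annotation_boundary_inside_token_splits_token(self):
        text = "patientJohn was seen"
        doc = make_doc(text, [("PATIENT", 7, 11)])
        [(sent, tags)] = tokenize(doc)
        assert "John" in sent.tokens
        assert tags[sent.tokens.index("John")] == "S-PATIENT"

    def test_offsets_match_text(self):
        doc = make_doc("alpha beta\ngamma delta", [])
        for sent, _ in tokenize(doc):
            for tok, (s, e) in zip(sent.tokens, sent.char_spans):
                assert doc.text[s:e] == tok

    def test_span_text_mismatch_rejected(self):
        doc = AnnotatedDocument(
            doc_id="d",
            text="hello world",
            annotations=[PhiAnnotation("PATIENT", 0, 5, "nope!")],
        )
        with pytest.raises(IntegrityError):
            tokenize(doc)


class TestBioes:
    @pytest.mark.parametrize(
        "tags, spans, repairs",
        [
            (["O", "S-DATE", "O"], [("DATE", 1, 1)], 0),
            (["B-DOCTOR", "E-DOCTOR"], [("DOCTOR", 0, 1)], 0),
            (["I-DATE", "E-DATE"], [("DATE", 0, 1)], 1),
            (["E-DATE"], [("DATE", 0, 0)], 1),
            (["B-DATE", "O"], [("DATE", 0, 0)], 1),
            (["B-AGE", "I-AGE", "S-ID"], [("AGE", 0, 1), ("ID", 2, 2)], 1),
            (["O", "O"], [], 0),
        ],
    )
    def test_decode_with_repair_policy(self, tags, spans, repairs):
        got_spans, got_repairs = bioes_decode(tags)
        assert got_spans == spans
        assert got_repairs == repairs

    @given(
        st.lists(
            st.tuples(st.sampled_from(["DATE", "PATIENT", "ID"]), st.integers(1, 4)),
            max_size=6,
        )
    )
    def test_encode_decode_identity_on_valid_span_sets(self, pieces):
        # lay spans out left to right, sometimes adjacent
        spans, pos = [], 0
        for cat, width in pieces:
            spans.append((cat, pos, pos + width - 1))
            pos += width
        n = max(pos, 1) + 2
        tags = bioes_encode(spans, n)
        decoded, repairs = bioes_decode(tags)
        assert repairs == 0
        assert decoded == spans

    @given(
        st.lists(
            st.sampled_from(
                ["O", "B-DATE", "I-DATE", "E-DATE", "S-DATE", "B-ID", "I-ID", "E-ID", "S-ID"]
            ),
            min_size=1,
            max_size=12,
        )
    )
    def test_repair_always_yields_valid_span_set(self, tags):
        spans, _ = bioes_decode(tags)
        reencoded = bioes_encode(spans, len(tags))
        again, repairs = bioes_decode(reencoded)
        assert repairs == 0
        assert again == spans


class TestRoundTrips:
    def test_i2b2_xml_round_trip(self, small_corpus, tmp_path):
        for doc in small_corpus.documents[:5]:
            path = tmp_path / f"{doc.doc_id}.xml"
            write_i2b2_xml(doc, path)
            back = read_i2b2_xml(path)
            assert back.text == doc.text
            assert back.annotations == doc.annotations

    def test_xml_without_tags_reads_empty_annotations(self, tmp_path):
        doc = make_doc("plain note text", [])
        path = tmp_path / "x.xml"
        write_i2b2_xml(doc, path)
        assert read_i2b2_xml(path).annotations == []

    def test_conll_round_trip(self, small_corpus, tmp_path):
        sentences = tokenize(small_corpus.documents[0])
        path = tmp_path / "c.tsv"
        write_conll(sentences, path)
        back = read_conll(path)
        assert [(s.tokens, t) for s, t in sentences] == back

    def test_tokenize_decode_recovers_annotation_spans(self, small_corpus):
        for doc in small_corpus.documents[:20]:
            recovered = []
            for sent, tags in tokenize(doc):
                spans, repairs = bioes_decode(tags)
                assert repairs == 0
                for cat, i0, i1 in spans:
                    recovered.append(
                        (cat, sent.char_spans[i0][0], sent.char_spans[i1][1])
                    )
            expected = [(a.category, a.start, a.end) for a in doc.annotations]
            assert sorted(recovered) == sorted(expected)


class TestIndexing:
    def test_vocabulary_fixed_ids_and_unknowns(self):
        vocab = Vocabulary(["the", "cat", "the"])
        ids = vocab.encode(["the", "cat", "dog", "the"])
        assert ids[0] == ids[3]
        assert ids[2] == vocab.unknown_id
        assert vocab.decode(vocab.encode(["the", "cat"])) == ["the", "cat"]

    def test_label_index_size(self):
        idx = LabelIndex(["DATE", "DOCTOR", "PATIENT"])
        assert idx.k == 4 * 3 + 1
        assert idx.label_to_id["O"] == 0
        with pytest.raises(KeyError):
            idx.encode(["B-NOPE"])


class TestDeidentifiedOutput:
    def test_no_predictions_is_identity(self):
        doc = make_doc("nothing secret here", [])
        assert write_deidentified(doc, [], "placeholder") == doc.text

    def test_placeholder_substitution(self):
        text = "Seen by John today"
        doc = make_doc(text, [])
        pred = [PhiAnnotation("PATIENT", 8, 12, "John")]
        assert write_deidentified(doc, pred, "placeholder") == "Seen by [PATIENT] today"

    def test_remove_everything_empties_token_stream(self):
        text = "John Smith"
        doc = make_doc(text, [])
        pred = [PhiAnnotation("PATIENT", 0, 10, text)]
        assert write_deidentified(doc, pred, "remove").strip() == ""

    def test_overlapping_predictions_merged(self):
        text = "x John Smith y"
        doc = make_doc(text, [])
        pred = [
            PhiAnnotation("PATIENT", 2, 9, "John Sm"),
            PhiAnnotation("DOCTOR", 7, 12, "Smith"),
        ]
        assert write_deidentified(doc, pred, "placeholder") == "x [PATIENT] y"
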
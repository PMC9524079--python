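"""Corpus data model: tokenization, EntitiesTsv IO, BIO conversion, splits."""

import pytest
from hypothesis import given, settings, strategies as stst

from picoextract.corpus import (
    AlignmentError, EntitySpan, EntityType, InvalidTransitionError,
    OverlapError, ParseError, TAG_VOCAB, Token, bio_to_spans,
    document_from_tokens, is_valid_bio, make_splits, parse_entities_tsv,
    spans_to_bio, tokenize_words, validate_annotations, write_entities_tsv,
)


class TestTokenizer:
    @pytest.mark.parametrize("text,expected", [
        ("C57BL/6 mice", [("C57BL/6", 0, 7), ("mice", 8, 12)]),
        ("", []),
        ("   ", []),
        ("fed a high-fat diet (HFD)",
         [("fed", 0, 3), ("a", 4, 5), ("high-fat", 6, 14), ("diet", 15, 19),
          ("(", 20, 21), ("HFD", 21, 24), (")", 24, 25)]),
        ("mice.", [("mice", 0, 4), (".", 4, 5)]),
        ("--", [("-", 0, 1), ("-", 1, 2)]),
        (".", [(".", 0, 1)]),
    ])
    def test_examples(self, text, expected):
        tokens = tokenize_words(text)
        assert [(t.text, t.start, t.end) for t in tokens] == expected

    @given(stst.text(max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_offsets_reconstruct_surfaces(self, text):
        for tok in tokenize_words(text):
            assert text[tok.start:tok.end] == tok.text


class TestEntitiesTsv:
    def test_parse_single_species(self):
        doc = parse_entities_tsv(["mice\tB-Species", "were\tO"])
        assert len(doc.gold_spans) == 1
        span = doc.gold_spans[0]
        assert span.type is EntityType.Species and span.text == "mice"

    def test_parse_multiword_intervention(self):
        doc = parse_entities_tsv([
            "aerobic\tB-Intervention",
            "exercise\tI-Intervention",
            "training\tI-Intervention",
        ])
        assert [s.text for s in doc.gold_spans] == ["aerobic exercise training"]

    def test_unknown_tag_named_in_error(self):
        with pytest.raises(ParseError, match="B-Animal"):
            parse_entities_tsv(["mice\tB-Animal"])

    def test_malformed_line_reports_line_number(self):
        with pytest.raises(ParseError, match="line 2"):
            parse_entities_tsv(["mice\tB-Species", "too\tmany\tfields"])

    def test_blank_lines_delimit_sentences(self):
        doc = parse_entities_tsv(["a\tO", "b\tO", "", "c\tO"])
        assert len(doc.sentences) == 2
        assert doc.sentences[1].token_start == 2

    def test_write_all_outside(self):
        doc = parse_entities_tsv(["alpha\tO", "beta\tO"])
        assert write_entities_tsv(doc) == ["alpha\tO", "beta\tO"]

    def test_write_pred_selector(self):
        doc = parse_entities_tsv(["mice\tO", "ran\tO"])
        doc.pred_spans = [EntitySpan(0, 4, EntityType.Species, "mice")]
        lines = write_entities_tsv(doc, which="pred")
        assert lines[0] == "mice\tB-Species"

    def test_round_trip_worked_example(self, worked_example):
        lines = write_entities_tsv(worked_example)
        doc2 = parse_entities_tsv(lines)
        assert doc2.text == worked_example.text
        assert [s.key for s in doc2.gold_spans] == \
            [s.key for s in worked_example.gold_spans]
        assert len(doc2.sentences) == len(worked_example.sentences)


class TestBioConversion:
    def test_tag_vocabulary_has_13_symbols(self):
        assert len(TAG_VOCAB) == 13
        assert TAG_VOCAB[0] == "O"
        assert len(set(TAG_VOCAB)) == 13

    def test_single_token_comparator(self):
        tokens = [Token("sedentary", 0, 9)]
        span = EntitySpan(0, 9, EntityType.Comparator, "sedentary")
        assert spans_to_bio(tokens, [span]) == ["B-Comparator"]

    def test_no_spans_all_outside(self):
        tokens = tokenize_words("nothing here")
        assert spans_to_bio(tokens, []) == ["O", "O"]

    def test_multiword_induction(self):
        tokens = tokenize_words("fed normal chow")
        span = EntitySpan(0, 15, EntityType.Induction, "fed normal chow")
        assert spans_to_bio(tokens, [span]) == \
            ["B-Induction", "I-Induction", "I-Induction"]

    def test_overlap_rejected(self):
        tokens = tokenize_words("fed normal chow")
        spans = [EntitySpan(0, 10, EntityType.Induction),
                 EntitySpan(4, 15, EntityType.Outcome)]
        with pytest.raises(OverlapError):
            spans_to_bio(tokens, spans)

    def test_unaligned_span_rejected(self):
        tokens = tokenize_words("streptozotocin injection")
        with pytest.raises(AlignmentError):
            spans_to_bio(tokens, [EntitySpan(0, 6, EntityType.Induction)])

    def test_bio_to_spans_basic(self):
        tokens = [Token("mice", 0, 4)]
        spans = bio_to_spans(tokens, ["B-Species"])
        assert spans[0].key == (EntityType.Species, 0, 4)

    def test_repair_promotes_stray_inside_tag(self):
        tokens = tokenize_words("a b")
        spans = bio_to_spans(tokens, ["O", "I-Outcome"], repair=True)
        assert [s.key for s in spans] == [(EntityType.Outcome, 2, 3)]

    def test_strict_mode_raises_with_index(self):
        tokens = tokenize_words("a b")
        with pytest.raises(InvalidTransitionError, match="index 1"):
            bio_to_spans(tokens, ["O", "I-Outcome"], repair=False)

    def test_adjacent_begin_tags_start_new_spans(self):
        tokens = tokenize_words("x y")
        spans = bio_to_spans(tokens, ["B-Outcome", "B-Outcome"])
        assert len(spans) == 2

    def test_type_switch_without_begin_is_invalid(self):
        tokens = tokenize_words("x y")
        with pytest.raises(InvalidTransitionError):
            bio_to_spans(tokens, ["B-Outcome", "I-Species"], repair=False)


@stst.composite
def _tagged_document(draw):
    """Random tokens with random non-overlapping token-aligned spans."""
    n = draw(stst.integers(min_value=1, max_value=12))
    words = [draw(stst.text(alphabet="abcxyz", min_size=1, max_size=4))
             for _ in range(n)]
    doc = document_from_tokens("hyp", [words])
    spans = []
    i = 0
    while i < n:
        if draw(stst.booleans()):
            width = draw(stst.integers(min_value=1, max_value=min(3, n - i)))
            etype = draw(stst.sampled_from(list(EntityType)))
            spans.append((0, i, i + width - 1, etype))
            i += width
        else:
            i += 1
    return document_from_tokens("hyp", [words], spans)


class TestRoundTripProperty:
    @given(_tagged_document())
    @settings(max_examples=200, deadline=None)
    def test_spans_bio_spans_identity(self, doc):
        tags = spans_to_bio(doc.tokens, doc.gold_spans)
        assert is_valid_bio(tags)
        back = bio_to_spans(doc.tokens, tags, text=doc.text)
        assert [s.key for s in back] == [s.key for s in sorted(doc.gold_spans)]
        assert all(s.text == doc.text[s.start:s.end] for s in back)


class TestValidation:
    def test_overlap_is_error(self):
        doc = document_from_tokens("d", [["alpha", "beta"]])
        doc.gold_spans = [EntitySpan(0, 5, EntityType.Outcome, "alpha"),
                          EntitySpan(0, 10, EntityType.Species, "alpha beta")]
        issues = validate_annotations(doc)
        assert [i.code for i in issues if i.level == "error"] == ["overlap"]

    def test_flanking_whitespace_is_warning(self):
        doc = document_from_tokens("d", [["x", "mice", "y"]])
        doc.gold_spans = [EntitySpan(1, 7, EntityType.Species, " mice ")]
        codes = [i.code for i in validate_annotations(doc)]
        assert "whitespace" in codes

    def test_boundary_punctuation_is_warning(self):
        doc = document_from_tokens("d", [["(", "HFD", ")"]])
        doc.gold_spans = [EntitySpan(0, 7, EntityType.Induction, "( HFD )")]
        codes = [i.code for i in validate_annotations(doc)]
        assert "boundary-punctuation" in codes

    def test_clean_worked_example(self, worked_example):
        assert validate_annotations(worked_example) == []


class TestSplits:
    def test_exact_fractions(self):
        train, val, test = make_splits(list(range(10)), (0.8, 0.1, 0.1), seed=7)
        assert (len(train), len(val), len(test)) == (8, 1, 1)
        assert sorted(train + val + test) == list(range(10))

    def test_400_gives_320_40_40(self):
        train, val, test = make_splits(list(range(400)), (0.8, 0.1, 0.1), seed=1)
        assert (len(train), len(val), len(test)) == (320, 40, 40)

    def test_deterministic(self):
        a = make_splits(list(range(50)), (0.8, 0.1, 0.1), seed=3)
        b = make_splits(list(range(50)), (0.8, 0.1, 0.1), seed=3)
        assert a == b

    def test_invariant_to_input_order(self):
        items = [f"doc-{i}" for i in range(30)]
        a = make_splits(items, (0.8, 0.1, 0.1), seed=5)
        b = make_splits(list(reversed(items)), (0.8, 0.1, 0.1), seed=5)
        assert a == b

    def test_remainder_goes_to_train(self):
        train, val, test = make_splits(list(range(7)), (0.8, 0.1, 0.1), seed=0)
        assert (len(train), len(val), len(test)) == (7, 0, 0)

    def test_too_few_items(self):
        with pytest.raises(ValueError):
            make_splits([1, 2], (0.4, 0.3, 0.3), seed=0)

    def test_bad_fractions(self):
        with pytest.raises(ValueError):
            make_splits(list(range(10)), (0.5, 0.2, 0.2), seed=0)
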
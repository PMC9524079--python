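"""PICO sentence labelling, classification and truncation."""

import numpy as np
import pytest

from picoextract.corpus import EntityType, document_from_tokens, spans_to_bio
from picoextract.sentence import (
    ClassifierConfig, SentenceExample, classify_sentences,
    label_pico_sentences, train_sentence_classifier, truncate_to_pico,
)
from picoextract.splitter import split_sentences


def make_training_data(n=120, seed=0):
    """Linearly separable synthetic sentences with lexical cues."""
    rng = np.random.default_rng(seed)
    cues = ["treated", "with", "velartinib", "injected", "mice", "received",
            "dosed", "randomised", "saline", "infusion"]
    background = ["this", "study", "shows", "background", "mechanisms",
                  "remain", "unclear", "implications", "overall", "future"]
    examples = []
    for i in range(n):
        pool = cues if i % 2 == 0 else background
        words = [pool[int(rng.integers(len(pool)))] for _ in range(6)]
        examples.append(SentenceExample(" ".join(words), i % 2 == 0))
    return examples


class TestLabeling:
    def test_no_spans_all_false(self):
        doc = document_from_tokens("d", [["a", "b"], ["c", "d"]])
        assert [ex.label for ex in label_pico_sentences(doc)] == [False, False]

    def test_single_sentence_with_span(self):
        doc = document_from_tokens("d", [["mice", "ran"]],
                                   [(0, 0, 0, EntityType.Species)])
        assert [ex.label for ex in label_pico_sentences(doc)] == [True]

    def test_worked_example_boundaries(self, worked_example):
        labels = [ex.label for ex in label_pico_sentences(worked_example)]
        # introduction and conclusion sentences carry no annotation
        assert labels == [False, True, True, True, False]

    def test_label_iff_sentence_has_non_outside_tag(self, worked_example):
        doc = worked_example
        tags = spans_to_bio(doc.tokens, doc.gold_spans)
        for sent, ex in zip(doc.sentences, label_pico_sentences(doc)):
            sent_tags = tags[sent.token_start:sent.token_end]
            assert ex.label == any(t != "O" for t in sent_tags)


class TestTraining:
    def test_learns_separable_data(self):
        data = make_training_data()
        model = train_sentence_classifier(
            data[:90], data[90:], ClassifierConfig.baseline_preset(seed=0))
        assert model.run_log["best_val_f1"] >= 0.95

    def test_deterministic_trajectories(self):
        data = make_training_data()
        config = ClassifierConfig.baseline_preset(seed=5)
        log_a = train_sentence_classifier(data[:90], data[90:], config).run_log
        log_b = train_sentence_classifier(data[:90], data[90:], config).run_log
        assert [r.get("val_f1") for r in log_a["history"]] == \
            [r.get("val_f1") for r in log_b["history"]]

    def test_paper_defaults_recorded_in_run_log(self):
        data = make_training_data(n=40)
        config = ClassifierConfig(seed=0)
        model = train_sentence_classifier(data[:30], data[30:], config)
        log = model.run_log
        assert (log["max_lr"], log["epochs"], log["clip_norm"],
                log["accumulation_steps"]) == (5e-5, 10, 0.1, 16)
        assert log["scheduler"] == "slanted_triangular"

    def test_single_class_rejected(self):
        data = [SentenceExample("a b", True)] * 5
        with pytest.raises(ValueError, match="single class"):
            train_sentence_classifier(data, [], ClassifierConfig())

    def test_empty_validation_warns_and_keeps_final(self):
        data = make_training_data(n=20)
        with pytest.warns(UserWarning, match="validation"):
            model = train_sentence_classifier(
                data, [], ClassifierConfig.baseline_preset(seed=0, epochs=2))
        assert model.run_log["best_epoch"] == 1

    def test_unknown_encoder_rejected(self):
        with pytest.raises(ValueError, match="encoder"):
            train_sentence_classifier(
                make_training_data(n=10), [],
                ClassifierConfig(encoder_name="bert-base-uncased"))

    def test_save_load_round_trip(self, tmp_path):
        data = make_training_data(n=40)
        model = train_sentence_classifier(
            data[:30], data[30:], ClassifierConfig.baseline_preset(seed=2))
        model.save(tmp_path)
        from picoextract.sentence import SentenceModel
        loaded = SentenceModel.load(tmp_path)
        sents = [ex.text for ex in data[:5]]
        assert np.allclose(model.predict_proba(sents),
                           loaded.predict_proba(sents))


class TestClassification:
    def test_empty_input(self, trained_pipeline):
        assert classify_sentences(trained_pipeline["sentence_model"], []) == []

    def test_probability_bounds_and_decision_rule(self, trained_pipeline):
        model = trained_pipeline["sentence_model"]
        doc = trained_pipeline["test"][0]
        results = classify_sentences(
            model, [doc.sentence_text(s) for s in doc.sentences])
        for label, prob in results:
            assert 0.0 <= prob <= 1.0
            assert label == (prob >= 0.5)

    def test_empty_sentence_flagged_false(self, trained_pipeline):
        with pytest.warns(UserWarning, match="empty"):
            results = classify_sentences(
                trained_pipeline["sentence_model"], ["", "   "])
        assert results == [(False, 0.0), (False, 0.0)]


class TestTruncation:
    def test_all_true_is_identity_up_to_rebasing(self, worked_example):
        doc = worked_example
        trunc = truncate_to_pico(doc, [True] * len(doc.sentences))
        assert trunc.document.text == doc.text
        assert [s.key for s in trunc.document.gold_spans] == \
            [s.key for s in sorted(doc.gold_spans)]
        assert not trunc.no_pico

    def test_all_false_sets_flag(self, worked_example):
        trunc = truncate_to_pico(worked_example, [False] * 5)
        assert trunc.no_pico
        assert trunc.document.text == ""
        assert trunc.document.tokens == []

    def test_gold_labels_drop_conclusion(self, worked_example):
        doc = worked_example
        labels = [ex.label for ex in label_pico_sentences(doc)]
        trunc = truncate_to_pico(doc, labels)
        assert "growing health burden" not in trunc.document.text
        assert "may protect against" not in trunc.document.text
        assert "C57BL/6" in trunc.document.text

    def test_spans_preserved_verbatim(self, worked_example):
        doc = worked_example
        labels = [ex.label for ex in label_pico_sentences(doc)]
        trunc = truncate_to_pico(doc, labels)
        assert len(trunc.document.gold_spans) == len(doc.gold_spans)
        for span in trunc.document.gold_spans:
            assert trunc.document.text[span.start:span.end] == span.text

    def test_offset_map_round_trip(self, worked_example):
        doc = worked_example
        labels = [ex.label for ex in label_pico_sentences(doc)]
        trunc = truncate_to_pico(doc, labels)
        originals = {(s.start, s.end) for s in doc.gold_spans}
        for span in trunc.document.gold_spans:
            orig = trunc.to_original(span.start, span.end)
            assert orig in originals
            assert doc.text[orig[0]:orig[1]] == span.text

    def test_label_count_mismatch_rejected(self, worked_example):
        with pytest.raises(ValueError):
            truncate_to_pico(worked_example, [True])


class TestSplitter:
    def test_basic_boundaries(self):
        text = "Mice were fed. Outcomes were measured. Results follow."
        spans = split_sentences(text)
        assert [text[a:b] for a, b in spans] == [
            "Mice were fed.", "Outcomes were measured.", "Results follow."]

    def test_abbreviation_guard(self):
        text = "Groups (e.g. controls) were used. Fig. 2 shows results."
        spans = split_sentences(text)
        assert len(spans) == 2
        assert text[spans[1][0]:spans[1][1]].startswith("Fig.")

    def test_empty_text(self):
        assert split_sentences("") == []
        assert split_sentences("   ") == []

    def test_anycase_mode_splits_lowercase_text(self):
        text = "mice were fed . outcomes were measured ."
        assert len(split_sentences(text, require_capital=False)) == 2
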
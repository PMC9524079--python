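import functools

import pytest

from picoextract.corpus import EntityType, document_from_tokens, make_splits
from picoextract.ner import NERConfig, train_ner
from picoextract.sentence import (
    ClassifierConfig, label_pico_sentences, train_sentence_classifier,
    truncate_to_pico,
)
from picoextract.simulate import SyntheticConfig, generate_corpus


@pytest.fixture
def worked_example():
    """Hand-built annotated abstract covering all six entity types.

    Mirrors the shape of a real annotated abstract: an introduction sentence
    and a conclusion sentence without annotations, method sentences carrying
    the entities.
    """
    return document_from_tokens(
        "example",
        [
            ["obesity", "is", "a", "growing", "health", "burden", "."],
            ["C57BL/6", "mice", "were", "fed", "normal", "chow", "or",
             "fed", "a", "high-fat", "diet", "."],
            ["mice", "received", "aerobic", "exercise", "training", "or",
             "remained", "sedentary", "."],
            ["we", "quantified", "protein", "spots", "by", "proteomics", "."],
            ["exercise", "may", "protect", "against", "obesity", "."],
        ],
        [
            (1, 0, 0, EntityType.Strain),          # C57BL/6
            (1, 1, 1, EntityType.Species),         # mice
            (1, 3, 5, EntityType.Induction),       # fed normal chow
            (1, 7, 10, EntityType.Induction),      # fed a high-fat diet
            (2, 0, 0, EntityType.Species),         # mice
            (2, 2, 4, EntityType.Intervention),    # aerobic exercise training
            (2, 7, 7, EntityType.Comparator),      # sedentary
            (3, 2, 3, EntityType.Outcome),         # protein spots
        ],
    )


from picoextract.experiments import truncate_gold  # noqa: E402 (shared helper)


@functools.lru_cache(maxsize=1)
def _shared_training_artifacts():
    """Small trained pipeline shared by slow tests (computed once)."""
    docs = generate_corpus(SyntheticConfig(n_documents=60, seed=11))
    train_docs, val_docs, test_docs = make_splits(docs, (0.8, 0.1, 0.1), seed=11)
    sent_train = [ex for d in train_docs for ex in label_pico_sentences(d)]
    sent_val = [ex for d in val_docs for ex in label_pico_sentences(d)]
    sentence_model = train_sentence_classifier(
        sent_train, sent_val, ClassifierConfig.baseline_preset(seed=11))
    ner_train = truncate_gold(train_docs)
    ner_val = truncate_gold(val_docs)
    ner_model = train_ner(ner_train, ner_val, NERConfig.preset(
        "recurrent+crf", hidden_dim=64, embedding_dim=32, epochs=10,
        seed=11, freeze_embeddings=False))
    return {
        "docs": docs, "train": train_docs, "val": val_docs, "test": test_docs,
        "sentence_model": sentence_model, "ner_model": ner_model,
    }


@pytest.fixture(scope="session")
def trained_pipeline():
    return _shared_training_artifacts()
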
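"""Reference experiments: end-to-end pipeline benchmarks on synthetic corpora.

These drive the whole workflow under controlled conditions — corpus
generation, both training stages, prediction on raw held-out text, and
entity-level evaluation — and return the measured quantities.  They are used
by the acceptance checks and are convenient for profiling changes to the
models.
"""

from __future__ import annotations

from dataclasses import dataclass

from .corpus import make_splits
from .metrics import aggregate, entity_prf
from .ner import NERConfig, train_ner
from .pipeline import run_pipeline
from .selftrain import SelfTrainConfig, self_train_loop
from .sentence import (
    ClassifierConfig, label_pico_sentences, train_sentence_classifier,
    truncate_to_pico,
)
from .simulate import SyntheticConfig, generate_corpus
from .splitter import split_sentences


def _synthetic_splitter(text: str):
    # synthetic abstracts are lowercase; don't require a capital opener
    return split_sentences(text, require_capital=False)


def truncate_gold(docs):
    """Truncate documents to their gold PICO sentences, dropping empties."""
    out = []
    for doc in docs:
        trunc = truncate_to_pico(
            doc, [ex.label for ex in label_pico_sentences(doc)])
        if not trunc.no_pico:
            out.append(trunc.document)
    return out


@dataclass
class ClosedLoopResult:
    n_documents: int
    n_test: int
    sentence_val_f1: float
    f1_recurrent_crf: float
    f1_recurrent: float

    @property
    def crf_gain(self) -> float:
        return self.f1_recurrent_crf - self.f1_recurrent


def closed_loop(seed: int, n_documents: int = 200, hidden_dim: int = 64,
                embedding_dim: int = 32) -> ClosedLoopResult:
    """Full two-stage benchmark on a lexically separable synthetic corpus.

    Generates ``n_documents`` abstracts (cue strength 1), splits 80/10/10 at
    document level, trains the baseline sentence classifier and two entity
    recognisers (plain recurrent and recurrent+CRF under their published
    regimes), then extracts entities from the *raw text* of held-out
    abstracts through the full pipeline and scores them against gold.
    """
    docs = generate_corpus(SyntheticConfig(
        n_documents=n_documents, seed=seed, cue_strength=1.0))
    train_docs, val_docs, test_docs = make_splits(docs, (0.8, 0.1, 0.1), seed)

    sent_train = [ex for d in train_docs for ex in label_pico_sentences(d)]
    sent_val = [ex for d in val_docs for ex in label_pico_sentences(d)]
    sentence_model = train_sentence_classifier(
        sent_train, sent_val, ClassifierConfig.baseline_preset(seed=seed))

    ner_train = truncate_gold(train_docs)
    ner_val = truncate_gold(val_docs)
    f1 = {}
    for arch in ("recurrent+crf", "recurrent"):
        model = train_ner(ner_train, ner_val, NERConfig.preset(
            arch, hidden_dim=hidden_dim, embedding_dim=embedding_dim,
            seed=seed, freeze_embeddings=False))
        scored = []
        for doc in test_docs:
            result = run_pipeline(doc.text, sentence_model, model,
                                  doc_id=doc.doc_id,
                                  splitter=_synthetic_splitter)
            scored.append(entity_prf(result.entities, doc.gold_spans))
        f1[arch] = aggregate(scored).overall.f1

    return ClosedLoopResult(
        n_documents=n_documents, n_test=len(test_docs),
        sentence_val_f1=sentence_model.run_log["best_val_f1"],
        f1_recurrent_crf=f1["recurrent+crf"], f1_recurrent=f1["recurrent"])


@dataclass
class SelfTrainBenchmark:
    accepted_at_strict: int          # silver records accepted at 0.99
    rounds_at_strict: int            # prediction rounds before the loop halted
    initial_f1: float                # gold-validation F1 before self-training
    best_f1: float                   # best gold-validation F1 across rounds
    silver_pool: int


def self_training_benchmark(seed: int, n_gold: int = 30,
                            n_silver: int = 12) -> SelfTrainBenchmark:
    """Two self-training runs on small synthetic pools.

    The strict run uses threshold 0.99 against a deliberately ambiguous
    silver pool (mentions drawn from a vocabulary that is untagged half the
    time in gold), so every document confidence stays below threshold and
    the loop must halt after one empty round.  The permissive run uses
    threshold 0.5 against cue-bearing silver documents whose pseudo-labels
    are correct by construction, measuring the directional gain.
    """
    gold = truncate_gold(generate_corpus(SyntheticConfig(
        n_documents=n_gold, seed=seed, cue_strength=0.6)))
    g_train, g_val, g_test = make_splits(gold, (0.8, 0.1, 0.1), seed)
    base = NERConfig.preset("recurrent+crf", hidden_dim=32, embedding_dim=16,
                            epochs=4, seed=seed, freeze_embeddings=False)

    ambiguous_silver = truncate_gold(generate_corpus(SyntheticConfig(
        n_documents=n_silver, seed=seed + 1, cue_strength=0.0,
        entities_per_doc=6, sentences_per_doc=4, pico_sentences_per_doc=2,
        doc_prefix="silver")))
    _, strict_history = self_train_loop(
        g_train, g_val, g_test, ambiguous_silver, base,
        SelfTrainConfig(threshold=0.99, seed=seed))
    accepted = sum(len(r.accepted_ids) for r in strict_history.iterations)

    cue_silver = truncate_gold(generate_corpus(SyntheticConfig(
        n_documents=n_silver, seed=seed + 2, cue_strength=1.0,
        entities_per_doc=6, sentences_per_doc=4, pico_sentences_per_doc=2,
        doc_prefix="silver")))
    _, perm_history = self_train_loop(
        g_train, g_val, g_test, cue_silver, base,
        SelfTrainConfig(threshold=0.5, seed=seed))
    f1s = [r.val_f1 for r in perm_history.iterations]

    return SelfTrainBenchmark(
        accepted_at_strict=accepted,
        rounds_at_strict=len(strict_history.iterations) - 1,
        initial_f1=f1s[0], best_f1=max(f1s),
        silver_pool=len(ambiguous_silver))
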
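"""Synthetic annotated corpora with the structure of the annotated dataset.

The generator emulates the published corpus statistics — about 11 sentences
per abstract of which about 5 are PICO sentences, about 17.5 entities per
abstract, and the imbalanced type mix (Intervention 24.1%, Comparator 1.8%,
Outcome 40.6%, Induction 10.6%, Species 19.6%, Strain 3.3%) — using small
synthetic per-type lexicons rather than real biomedical dictionaries.
Per-document counts are Poisson around the configured means.

``cue_strength`` controls lexical separability: at 1.0 every entity phrase
is drawn from its type's private vocabulary, so a memorising tagger can
reach F1 1.0 (the ceiling check for the learning pipelines); below 1.0 some
mentions are replaced by words from an ambiguous pool that also shows up,
untagged, in filler sentences.

The text is not linguistically realistic and is not meant to be: it gives
every module a deterministic, annotation-consistent workload.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import Document, EntityType, document_from_tokens, parse_entities_tsv, write_entities_tsv

#: Default type mix of the annotated corpus.
DEFAULT_TYPE_DISTRIBUTION: dict[EntityType, float] = {
    EntityType.Intervention: 0.241,
    EntityType.Comparator: 0.018,
    EntityType.Outcome: 0.406,
    EntityType.Induction: 0.106,
    EntityType.Species: 0.196,
    EntityType.Strain: 0.033,
}

# Per-type lexicons; word pools are pairwise disjoint and disjoint from the
# filler vocabulary so that cue_strength=1 corpora are lexically separable.
SPECIES = ["mice", "rats", "rabbits", "zebrafish", "piglets", "ferrets",
           "marmosets", "voles"]
STRAINS = ["C57BL/6", "BALB/c", "Wistar", "Sprague-Dawley", "FVB/N",
           "Lewis-2", "CD-1", "129S1/J"]
INDUCTION_HEAD = ["streptozotocin", "ligation", "hypoxia", "ovariectomy",
                  "collagenase", "cuprizone"]
INDUCTION_TAIL = ["injection", "occlusion", "exposure", "induction",
                  "puncture", "immunization"]
INTERVENTION_MOD = ["low-dose", "high-dose", "intermittent", "combined"]
INTERVENTION_HEAD = ["velartinib", "moxefin", "treadmill-running",
                     "quercetol", "sitagrelin", "exosome-infusion"]
INTERVENTION_TAIL = ["therapy", "supplementation", "administration"]
COMPARATORS = ["sedentary", "vehicle", "saline", "sham", "placebo", "untreated"]
OUTCOME_HEAD = ["glucose", "corticosterone", "infarct", "apoptosis",
                "locomotor", "cytokine"]
OUTCOME_TAIL = ["volume", "concentration", "index", "score", "density", "titre"]
AMBIGUOUS = ["factor", "signal", "response", "marker", "pathway", "activity"]

FILLER = ["the", "animals", "were", "randomised", "and", "received", "then",
          "assessed", "after", "eight", "weeks", "of", "housing", "under",
          "standard", "conditions", "we", "evaluated", "in", "each", "cohort"]
BACKGROUND = ["this", "study", "suggests", "previous", "reports", "indicate",
              "findings", "background", "mechanisms", "remain", "unclear",
              "overall", "conclusions", "have", "important", "implications",
              "for", "future", "research", "directions"]


@dataclass
class SyntheticConfig:
    n_documents: int = 100
    sentences_per_doc: float = 11.0
    pico_sentences_per_doc: float = 5.0
    entities_per_doc: float = 17.5
    type_distribution: dict[EntityType, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_DISTRIBUTION))
    cue_strength: float = 1.0
    seed: int = 0
    doc_prefix: str = "synth"

    def __post_init__(self) -> None:
        if self.n_documents < 1:
            raise ValueError("n_documents must be >= 1")
        total = sum(self.type_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"type_distribution sums to {total}, expected 1")
        if not (0.0 <= self.cue_strength <= 1.0):
            raise ValueError("cue_strength must lie in [0, 1]")


def _pick(rng: np.random.Generator, pool: list[str]) -> str:
    return pool[int(rng.integers(len(pool)))]


def _entity_phrase(rng: np.random.Generator, etype: EntityType,
                   cue_strength: float) -> list[str]:
    if rng.random() > cue_strength:
        return [_pick(rng, AMBIGUOUS)]
    if etype is EntityType.Species:
        return [_pick(rng, SPECIES)]
    if etype is EntityType.Strain:
        return [_pick(rng, STRAINS)]
    if etype is EntityType.Comparator:
        return [_pick(rng, COMPARATORS)]
    if etype is EntityType.Induction:
        words = [_pick(rng, INDUCTION_HEAD), _pick(rng, INDUCTION_TAIL)]
        if rng.random() < 0.3:
            words.insert(1, _pick(rng, INDUCTION_HEAD))
        return words
    if etype is EntityType.Intervention:
        words = [_pick(rng, INTERVENTION_HEAD)]
        if rng.random() < 0.5:
            words.insert(0, _pick(rng, INTERVENTION_MOD))
        if rng.random() < 0.5:
            words.append(_pick(rng, INTERVENTION_TAIL))
        return words
    # Outcome
    words = [_pick(rng, OUTCOME_HEAD)]
    if rng.random() < 0.7:
        words.append(_pick(rng, OUTCOME_TAIL))
    return words


def _filler(rng: np.random.Generator, n: int) -> list[str]:
    return [_pick(rng, FILLER) for _ in range(n)]


def _background_sentence(rng: np.random.Generator, cue_strength: float) -> list[str]:
    words = [_pick(rng, BACKGROUND) for _ in range(int(rng.integers(4, 9)))]
    if cue_strength < 1.0 and rng.random() < 0.3:
        words.insert(int(rng.integers(len(words))), _pick(rng, AMBIGUOUS))
    words.append(".")
    return words


def generate_document(rng: np.random.Generator, config: SyntheticConfig,
                      doc_id: str) -> Document:
    n_sent = max(2, int(rng.poisson(config.sentences_per_doc)))
    if config.entities_per_doc <= 0 or config.pico_sentences_per_doc <= 0:
        n_pico = 0
    else:
        n_pico = int(np.clip(rng.poisson(config.pico_sentences_per_doc), 1,
                             n_sent))
    n_entities = 0
    if n_pico:
        n_entities = max(n_pico, int(rng.poisson(config.entities_per_doc)))
    pico_idx = set(
        int(i) for i in rng.choice(n_sent, size=n_pico, replace=False))

    # every PICO sentence hosts >= 1 entity; the rest spread at random
    per_sentence = {i: 1 for i in pico_idx}
    pico_list = sorted(pico_idx)
    for _ in range(n_entities - n_pico):
        per_sentence[pico_list[int(rng.integers(len(pico_list)))]] += 1

    types = list(config.type_distribution)
    probs = np.array([config.type_distribution[t] for t in types])
    sentence_words: list[list[str]] = []
    spans: list[tuple[int, int, int, EntityType]] = []
    for si in range(n_sent):
        if si not in pico_idx:
            sentence_words.append(_background_sentence(rng, config.cue_strength))
            continue
        words = _filler(rng, int(rng.integers(2, 5)))
        for _ in range(per_sentence[si]):
            etype = types[int(rng.choice(len(types), p=probs))]
            phrase = _entity_phrase(rng, etype, config.cue_strength)
            w0 = len(words)
            words.extend(phrase)
            spans.append((si, w0, len(words) - 1, etype))
            words.extend(_filler(rng, int(rng.integers(1, 3))))
        words.append(".")
        sentence_words.append(words)
    doc = document_from_tokens(doc_id, sentence_words, spans)
    for sent in doc.sentences:
        sent.is_pico = sent.index in pico_idx
    return doc


def generate_corpus(config: SyntheticConfig) -> list[Document]:
    """Deterministically generate ``config.n_documents`` annotated abstracts."""
    rng = np.random.default_rng(config.seed)
    width = len(str(config.n_documents - 1))
    return [
        generate_document(rng, config, f"{config.doc_prefix}-{i:0{width}d}")
        for i in range(config.n_documents)
    ]


@dataclass
class CorpusStats:
    n_documents: int
    mean_sentences: float
    mean_pico_sentences: float
    mean_entities: float
    total_entities: int
    type_distribution: dict[EntityType, float]


def corpus_stats(docs: list[Document]) -> CorpusStats:
    """Exact per-document means and realized entity-type proportions."""
    if not docs:
        raise ValueError("cannot summarize an empty corpus")
    n = len(docs)
    total_sents = sum(len(d.sentences) for d in docs)
    total_pico = sum(
        1 for d in docs for s in d.sentences
        if any(sp.start < s.end and s.start < sp.end for sp in d.gold_spans))
    counts = {t: 0 for t in EntityType}
    for d in docs:
        for span in d.gold_spans:
            counts[span.type] += 1
    total = sum(counts.values())
    dist = {t: (c / total if total else 0.0) for t, c in counts.items()}
    return CorpusStats(
        n_documents=n,
        mean_sentences=total_sents / n,
        mean_pico_sentences=total_pico / n,
        mean_entities=total / n,
        total_entities=total,
        type_distribution=dist,
    )


def write_corpus(docs: list[Document], directory: str | Path,
                 config: SyntheticConfig | None = None) -> None:
    """Emit one EntitiesTsv file per document plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        path = directory / f"{doc.doc_id}.tsv"
        path.write_text("\n".join(write_entities_tsv(doc)) + "\n",
                        encoding="utf-8")
    manifest: dict = {"documents": [d.doc_id for d in docs]}
    if config is not None:
        manifest["config"] = {
            "n_documents": config.n_documents,
            "sentences_per_doc": config.sentences_per_doc,
            "pico_sentences_per_doc": config.pico_sentences_per_doc,
            "entities_per_doc": config.entities_per_doc,
            "type_distribution": {t.value: p for t, p in
                                  config.type_distribution.items()},
            "cue_strength": config.cue_strength,
            "seed": config.seed,
        }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_corpus(directory: str | Path) -> list[Document]:
    """Read every ``*.tsv`` document in a corpus directory (sorted by name)."""
    directory = Path(directory)
    docs = []
    for path in sorted(directory.glob("*.tsv")):
        with open(path, encoding="utf-8") as fh:
            docs.append(parse_entities_tsv(fh, doc_id=path.stem))
    if not docs:
        raise ValueError(f"no .tsv documents in {directory}")
    return docs
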
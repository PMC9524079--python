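"""End-to-end PICO extraction from raw abstract text.

Prediction mirrors the two-stage workflow: split the abstract into
sentences, classify each sentence, drop non-PICO sentences, run the entity
recogniser over the remaining text, and map the extracted spans back to
offsets in the original abstract through the truncation provenance map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .corpus import Document, EntitySpan, Sentence, Token, bio_to_spans, tokenize_words
from .ner import NERModel, predict_tags
from .sentence import SentenceModel, classify_sentences, truncate_to_pico
from .splitter import split_sentences


@dataclass
class PicoResult:
    """Extracted PICO entities for one abstract.

    Entity offsets refer to the original (untruncated) text; confidence per
    entity is the mean posterior of its tokens' predicted tags.
    """

    doc_id: str
    kept_sentences: list[int]
    entities: list[EntitySpan] = field(default_factory=list)
    confidences: list[float] = field(default_factory=list)
    no_pico: bool = False

    def to_dict(self, text: str | None = None) -> dict:
        record = {
            "doc_id": self.doc_id,
            "kept_sentences": self.kept_sentences,
            "no_pico_sentences": self.no_pico,
            "entities": [
                {"type": e.type.value, "start": e.start, "end": e.end,
                 "text": e.text, "confidence": round(c, 6)}
                for e, c in zip(self.entities, self.confidences)
            ],
        }
        if text is not None:
            record["text"] = text
        return record


def document_from_text(
    text: str, doc_id: str = "doc",
    splitter: Callable[[str], list[tuple[int, int]]] = split_sentences,
) -> Document:
    """Tokenize raw text into a Document with splitter-derived sentences."""
    tokens = tokenize_words(text)
    sentences: list[Sentence] = []
    for i, (lo, hi) in enumerate(splitter(text)):
        token_start = next(
            (ti for ti, t in enumerate(tokens) if t.start >= lo), len(tokens))
        token_end = token_start
        while token_end < len(tokens) and tokens[token_end].end <= hi:
            token_end += 1
        if token_end > token_start:
            sentences.append(Sentence(
                index=len(sentences),
                start=tokens[token_start].start,
                end=tokens[token_end - 1].end,
                token_start=token_start, token_end=token_end))
    if not sentences and tokens:
        sentences = [Sentence(0, tokens[0].start, tokens[-1].end, 0, len(tokens))]
    return Document(doc_id=doc_id, text=text, tokens=tokens, sentences=sentences)


def run_pipeline(
    text: str, sentence_model: SentenceModel, ner_model: NERModel,
    doc_id: str = "doc",
    splitter: Callable[[str], list[tuple[int, int]]] = split_sentences,
) -> PicoResult:
    """Extract PICO entities from one abstract.

    Returns an empty result (``no_pico`` set) when no sentence is classified
    as a PICO sentence, and an empty result for empty input text.
    """
    doc = document_from_text(text, doc_id, splitter)
    if not doc.tokens:
        return PicoResult(doc_id=doc_id, kept_sentences=[], no_pico=True)
    sentence_texts = [doc.sentence_text(s) for s in doc.sentences]
    labels = [lab for lab, _prob in classify_sentences(sentence_model,
                                                       sentence_texts)]
    truncation = truncate_to_pico(doc, labels)
    if truncation.no_pico:
        return PicoResult(doc_id=doc_id, kept_sentences=[], no_pico=True)
    trunc_doc = truncation.document
    tags, token_conf = predict_tags(ner_model, trunc_doc)
    spans = bio_to_spans(trunc_doc.tokens, tags, repair=True,
                         text=trunc_doc.text)
    entities: list[EntitySpan] = []
    confidences: list[float] = []
    for span in spans:
        token_idx = [i for i, t in enumerate(trunc_doc.tokens)
                     if span.start <= t.start and t.end <= span.end]
        conf = (sum(token_conf[i] for i in token_idx) / len(token_idx)
                if token_idx else 0.0)
        orig_start, orig_end = truncation.to_original(span.start, span.end)
        entities.append(EntitySpan(orig_start, orig_end, span.type,
                                   text[orig_start:orig_end]))
        confidences.append(conf)
    return PicoResult(doc_id=doc_id, kept_sentences=truncation.kept_sentences,
                      entities=entities, confidences=confidences)
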
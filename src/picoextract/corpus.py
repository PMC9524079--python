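"""Corpus data model and EntitiesTsv input/output.

The annotation scheme covers six preclinical PICO entity types: the animal
Species and Strain, the method of Induction of the disease model, the
Intervention, the Comparator and the Outcome.  Token-level labels follow the
BIO convention (``B-Type`` for the first token of a mention, ``I-Type`` for
continuation tokens, ``O`` elsewhere), giving a 13-symbol tag vocabulary.

Annotated documents travel as EntitiesTsv: one ``token<TAB>tag`` line per
token, a blank line between sentences, one document per file — the
tab-separated layout produced by tagtog and by the Stanford NER tool.

Offsets throughout are 0-based, half-open character intervals into the
document text.  Entity spans never overlap and always align to token
boundaries.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Iterable, Sequence


class EntityType(Enum):
    """The six preclinical PICO entity types."""

    Species = "Species"
    Strain = "Strain"
    Induction = "Induction"
    Intervention = "Intervention"
    Comparator = "Comparator"
    Outcome = "Outcome"


#: Canonical tag ordering. ``O`` sits at index 0 so that an all-tie decode
#: falls back to the outside tag under lowest-index tie-breaking.
TAG_VOCAB: tuple[str, ...] = ("O",) + tuple(
    f"{prefix}-{etype.value}" for etype in EntityType for prefix in ("B", "I")
)

TAG_TO_INDEX: dict[str, int] = {tag: i for i, tag in enumerate(TAG_VOCAB)}

OUTSIDE = "O"


class CorpusError(Exception):
    """Base class for corpus-level failures."""


class ParseError(CorpusError):
    """Malformed EntitiesTsv input."""


class AlignmentError(CorpusError):
    """An entity span does not align to token boundaries."""


class OverlapError(CorpusError):
    """Two entity spans overlap (forbidden by the annotation rules)."""


class InvalidTransitionError(CorpusError):
    """A BIO tag sequence contains an illegal transition."""


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad token offsets [{self.start},{self.end})")
        if not self.text or any(c.isspace() for c in self.text):
            raise ValueError(f"token text {self.text!r} empty or has whitespace")


@dataclass(frozen=True, order=True)
class EntitySpan:
    """One typed PICO mention, anchored by character offsets."""

    start: int
    end: int
    type: EntityType
    text: str = field(compare=False, default="")

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"bad span offsets [{self.start},{self.end})")

    @property
    def key(self) -> tuple[EntityType, int, int]:
        return (self.type, self.start, self.end)

    def overlaps(self, other: "EntitySpan") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class Sentence:
    index: int
    start: int
    end: int
    token_start: int
    token_end: int  # exclusive token index
    is_pico: bool | None = None


@dataclass
class Document:
    doc_id: str
    text: str
    tokens: list[Token]
    sentences: list[Sentence]
    gold_spans: list[EntitySpan] = field(default_factory=list)
    pred_spans: list[EntitySpan] = field(default_factory=list)

    def spans(self, which: str = "gold") -> list[EntitySpan]:
        if which == "gold":
            return self.gold_spans
        if which == "pred":
            return self.pred_spans
        raise ValueError(f"unknown span set {which!r}; expected 'gold' or 'pred'")

    def sentence_text(self, sentence: Sentence) -> str:
        return self.text[sentence.start:sentence.end]

    def sentence_tokens(self, sentence: Sentence) -> list[Token]:
        return self.tokens[sentence.token_start:sentence.token_end]


@dataclass
class Issue:
    """One finding from :func:`validate_annotations`."""

    level: str  # "error" | "warning"
    code: str
    message: str


_PUNCT = set(string.punctuation)


def tokenize_words(text: str) -> list[Token]:
    """Split *text* into offset-bearing word tokens.

    Whitespace-delimited chunks are split further by peeling leading and
    trailing punctuation into single-character tokens; internal punctuation
    (hyphens, slashes) stays attached, so surface forms such as ``C57BL/6``
    and ``high-fat`` survive as single tokens.
    """
    tokens: list[Token] = []
    i = 0
    n = len(text)
    while i < n:
        if text[i].isspace():
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace():
            j += 1
        lo, hi = i, j
        # peel leading punctuation
        while lo < hi and text[lo] in _PUNCT and hi - lo > 1:
            tokens.append(Token(text[lo], lo, lo + 1))
            lo += 1
        # collect trailing punctuation (emitted after the core token)
        trail: list[Token] = []
        while hi - 1 > lo and text[hi - 1] in _PUNCT:
            trail.append(Token(text[hi - 1], hi - 1, hi))
            hi -= 1
        tokens.append(Token(text[lo:hi], lo, hi))
        tokens.extend(reversed(trail))
        i = j
    return tokens


def _span_token_range(tokens: Sequence[Token], span: EntitySpan) -> tuple[int, int]:
    """Token index range [i, j) exactly covering *span*, or raise AlignmentError."""
    starts = [t.start for t in tokens]
    ends = [t.end for t in tokens]
    try:
        i = starts.index(span.start)
        j = ends.index(span.end) + 1
    except ValueError:
        raise AlignmentError(
            f"span {span.type.value} [{span.start},{span.end}) does not align "
            f"to token boundaries"
        ) from None
    if j <= i:
        raise AlignmentError(
            f"span {span.type.value} [{span.start},{span.end}) covers no tokens"
        )
    return i, j


def spans_to_bio(tokens: Sequence[Token], spans: Sequence[EntitySpan]) -> list[str]:
    """Convert entity spans to a BIO tag sequence aligned with *tokens*.

    Raises :class:`OverlapError` for overlapping spans and
    :class:`AlignmentError` for spans not aligned to token boundaries.
    """
    ordered = sorted(spans)
    for a, b in zip(ordered, ordered[1:]):
        if a.overlaps(b):
            raise OverlapError(f"spans {a} and {b} overlap")
    tags = [OUTSIDE] * len(tokens)
    for span in ordered:
        i, j = _span_token_range(tokens, span)
        tags[i] = f"B-{span.type.value}"
        for k in range(i + 1, j):
            tags[k] = f"I-{span.type.value}"
    return tags


def bio_to_spans(
    tokens: Sequence[Token],
    tags: Sequence[str],
    *,
    repair: bool = False,
    text: str | None = None,
) -> list[EntitySpan]:
    """Convert a BIO tag sequence back to entity spans.

    Maximal ``B-T (I-T)*`` runs become spans.  A stray ``I-T`` (not preceded
    by ``B-T``/``I-T`` of the same type) is promoted to ``B-T`` when
    ``repair`` is true, otherwise :class:`InvalidTransitionError` is raised.
    Span surfaces are sliced from *text* when given, else joined from token
    surfaces with single spaces.
    """
    if len(tokens) != len(tags):
        raise ValueError(f"{len(tags)} tags for {len(tokens)} tokens")
    spans: list[EntitySpan] = []
    open_type: EntityType | None = None
    open_start = 0
    open_end = 0

    def close() -> None:
        nonlocal open_type
        if open_type is not None:
            surface = (
                text[open_start:open_end]
                if text is not None
                else " ".join(t.text for t in tokens if open_start <= t.start and t.end <= open_end)
            )
            spans.append(EntitySpan(open_start, open_end, open_type, surface))
            open_type = None

    for idx, (token, tag) in enumerate(zip(tokens, tags)):
        if tag == OUTSIDE:
            close()
            continue
        if tag not in TAG_TO_INDEX:
            raise ParseError(f"unknown tag symbol {tag!r}")
        prefix, type_name = tag.split("-", 1)
        etype = EntityType(type_name)
        if prefix == "B":
            close()
            open_type, open_start, open_end = etype, token.start, token.end
        else:  # I-
            if open_type is etype:
                open_end = token.end
            elif repair:
                close()
                open_type, open_start, open_end = etype, token.start, token.end
            else:
                raise InvalidTransitionError(
                    f"I-{type_name} at token index {idx} not preceded by "
                    f"B-{type_name}/I-{type_name}"
                )
    close()
    return spans


def is_valid_bio(tags: Sequence[str]) -> bool:
    """True iff every I-T is preceded by B-T or I-T of the same type."""
    prev = OUTSIDE
    for tag in tags:
        if tag.startswith("I-"):
            if prev not in (f"B-{tag[2:]}", tag):
                return False
        prev = tag
    return True


def _split_sentences_on_blank(
    lines: Iterable[str],
) -> tuple[list[tuple[str, str]], list[int]]:
    """Parse token/tag pairs and sentence-final token counts from TSV lines."""
    pairs: list[tuple[str, str]] = []
    breaks: list[int] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            if pairs and (not breaks or breaks[-1] != len(pairs)):
                breaks.append(len(pairs))
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(
                f"line {lineno}: expected 'token<TAB>tag', got {line!r}"
            )
        token_text, tag = fields[0].strip(), fields[1].strip()
        if not token_text:
            raise ParseError(f"line {lineno}: empty token field")
        if tag not in TAG_TO_INDEX:
            raise ParseError(f"line {lineno}: unknown tag symbol {tag!r}")
        pairs.append((token_text, tag))
    if pairs and (not breaks or breaks[-1] != len(pairs)):
        breaks.append(len(pairs))
    return pairs, breaks


def parse_entities_tsv(lines: Iterable[str], doc_id: str = "doc") -> Document:
    """Read one EntitiesTsv document.

    Document text is rebuilt by joining tokens with single spaces (original
    spacing is not recoverable from the format), so the resulting offsets are
    canonical rather than original.  Stray ``I-`` tags are repaired to ``B-``.
    """
    pairs, breaks = _split_sentences_on_blank(lines)
    tokens: list[Token] = []
    cursor = 0
    for text_piece, _tag in pairs:
        # multi-word annotation surfaces never occur in the token column, but
        # a token containing internal whitespace would corrupt offsets
        for word in text_piece.split():
            tokens.append(Token(word, cursor, cursor + len(word)))
            cursor += len(word) + 1
    if len(tokens) != len(pairs):
        raise ParseError("token fields must not contain internal whitespace")
    text = " ".join(p[0] for p in pairs)
    sentences: list[Sentence] = []
    prev = 0
    for si, brk in enumerate(breaks):
        sent_tokens = tokens[prev:brk]
        sentences.append(
            Sentence(
                index=si,
                start=sent_tokens[0].start,
                end=sent_tokens[-1].end,
                token_start=prev,
                token_end=brk,
            )
        )
        prev = brk
    tags = [p[1] for p in pairs]
    spans = bio_to_spans(tokens, tags, repair=True, text=text)
    return Document(doc_id=doc_id, text=text, tokens=tokens, sentences=sentences,
                    gold_spans=spans)


def write_entities_tsv(doc: Document, which: str = "gold") -> list[str]:
    """Serialize *doc* to EntitiesTsv lines (round-trip safe with the parser)."""
    tags = spans_to_bio(doc.tokens, doc.spans(which))
    lines: list[str] = []
    for si, sent in enumerate(doc.sentences):
        if si > 0:
            lines.append("")
        for ti in range(sent.token_start, sent.token_end):
            lines.append(f"{doc.tokens[ti].text}\t{tags[ti]}")
    return lines


def validate_annotations(doc: Document, which: str = "gold") -> list[Issue]:
    """Check a document against the annotation rules.

    Overlapping spans are errors (the format cannot represent them); spans
    with flanking whitespace or boundary punctuation, and spans crossing
    sentence boundaries, are warnings.
    """
    issues: list[Issue] = []
    spans = sorted(doc.spans(which))
    for a, b in zip(spans, spans[1:]):
        if a.overlaps(b):
            issues.append(Issue(
                "error", "overlap",
                f"spans [{a.start},{a.end}) {a.type.value} and "
                f"[{b.start},{b.end}) {b.type.value} overlap",
            ))
    for span in spans:
        surface = span.text or doc.text[span.start:span.end]
        if surface != surface.strip():
            issues.append(Issue(
                "warning", "whitespace",
                f"span [{span.start},{span.end}) has flanking whitespace",
            ))
        else:
            stripped = surface.strip(string.punctuation)
            if surface and stripped != surface:
                issues.append(Issue(
                    "warning", "boundary-punctuation",
                    f"span [{span.start},{span.end}) {surface!r} starts or "
                    f"ends with punctuation",
                ))
        for sent in doc.sentences:
            if sent.start <= span.start < sent.end and span.end > sent.end:
                issues.append(Issue(
                    "warning", "cross-sentence",
                    f"span [{span.start},{span.end}) crosses a sentence boundary",
                ))
    return issues


def make_splits(
    items: Sequence,
    fractions: tuple[float, float, float],
    seed: int,
    key: Callable | None = None,
) -> tuple[list, list, list]:
    """Random train/validation/test partition.

    Validation and test sizes are floored; the remainder goes to training
    (400 items at 80/10/10 give 320/40/40).  Items are ordered under *key*
    (``doc_id`` when present, else ``str``) before the seeded shuffle, so the
    partition is invariant to the input order.
    """
    f_train, f_val, f_test = fractions
    if min(fractions) < 0:
        raise ValueError("fractions must be non-negative")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    n_parts = sum(1 for f in fractions if f > 0)
    if len(items) < n_parts:
        raise ValueError(f"{len(items)} items cannot fill {n_parts} non-empty parts")
    if key is None:
        key = lambda x: getattr(x, "doc_id", None) or str(x)
    ordered = sorted(items, key=key)
    random.Random(seed).shuffle(ordered)
    n = len(ordered)
    n_val = int(n * f_val)
    n_test = int(n * f_test)
    n_train = n - n_val - n_test
    train = ordered[:n_train]
    val = ordered[n_train:n_train + n_val]
    test = ordered[n_train + n_val:]
    return train, val, test


def document_from_tokens(
    doc_id: str,
    sentence_words: Sequence[Sequence[str]],
    spans: Sequence[tuple[int, int, int, EntityType]] = (),
) -> Document:
    """Build a Document from per-sentence word lists.

    ``spans`` are (sentence index, first word, last word inclusive, type)
    records over the word lists; offsets are computed canonically (single
    spaces).  Convenience for generators and tests.
    """
    words: list[str] = []
    sent_bounds: list[tuple[int, int]] = []
    for sent in sentence_words:
        sent_bounds.append((len(words), len(words) + len(sent)))
        words.extend(sent)
    text = " ".join(words)
    offsets: list[tuple[int, int]] = []
    cursor = 0
    for w in words:
        offsets.append((cursor, cursor + len(w)))
        cursor += len(w) + 1
    tokens = [Token(w, s, e) for w, (s, e) in zip(words, offsets)]
    sentences = [
        Sentence(index=i, start=offsets[ts][0], end=offsets[te - 1][1],
                 token_start=ts, token_end=te)
        for i, (ts, te) in enumerate(sent_bounds)
    ]
    gold: list[EntitySpan] = []
    for si, w0, w1, etype in spans:
        ts = sent_bounds[si][0]
        start = offsets[ts + w0][0]
        end = offsets[ts + w1][1]
        gold.append(EntitySpan(start, end, etype, text[start:end]))
    return Document(doc_id=doc_id, text=text, tokens=tokens,
                    sentences=sentences, gold_spans=sorted(gold))


def with_pred_as_gold(doc: Document) -> Document:
    """Copy of *doc* whose predictions become the (pseudo-)gold annotation."""
    return replace(doc, gold_spans=list(doc.pred_spans), pred_spans=[])
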
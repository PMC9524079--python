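"""Rule-based sentence splitting for abstract text.

Training corpora carry gold sentence boundaries inside EntitiesTsv, so this
splitter only matters at prediction time, when raw abstract text arrives
without annotation.  It splits after ``.``, ``!`` or ``?`` followed by
whitespace and an uppercase letter or digit, with a guard list of common
scientific abbreviations (``e.g.``, ``et al.``, ``Fig.``, single initials)
that do not end sentences.  The pipeline accepts any callable with the same
signature, so a different splitter can be plugged in.
"""

from __future__ import annotations

import re

_ABBREVIATIONS = {
    "e.g", "i.e", "etc", "cf", "vs", "al", "fig", "figs", "ref", "refs",
    "no", "dr", "mr", "ms", "approx", "ca", "resp", "wk", "hr", "min",
}

_BOUNDARY = re.compile(r"[.!?]+(?=\s+[A-Z0-9(])")
_BOUNDARY_ANYCASE = re.compile(r"[.!?]+(?=\s+\S)")


def _is_abbreviation(text: str, punct_index: int) -> bool:
    head = text[:punct_index]
    match = re.search(r"([A-Za-z][\w.]*)$", head)
    if match is None:
        return False
    word = match.group(1).rstrip(".")
    if word.lower() in _ABBREVIATIONS:
        return True
    # single capital initial, as in author names ("J. Smith")
    return len(word) == 1 and word.isupper()


def split_sentences(text: str, *, require_capital: bool = True) -> list[tuple[int, int]]:
    """Character ranges [start, end) of sentences, whitespace-trimmed.

    Returns an empty list for empty/whitespace input; a text with no
    boundary punctuation is a single sentence.  ``require_capital=False``
    drops the requirement that a new sentence open with an uppercase letter
    or digit (useful for lowercased or synthetic text).
    """
    boundary = _BOUNDARY if require_capital else _BOUNDARY_ANYCASE
    spans: list[tuple[int, int]] = []
    cursor = 0
    for m in boundary.finditer(text):
        if _is_abbreviation(text, m.start()):
            continue
        spans.append((cursor, m.end()))
        cursor = m.end()
    if cursor < len(text):
        spans.append((cursor, len(text)))
    trimmed = []
    for lo, hi in spans:
        while lo < hi and text[lo].isspace():
            lo += 1
        while hi > lo and text[hi - 1].isspace():
            hi -= 1
        if hi > lo:
            trimmed.append((lo, hi))
    return trimmed
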
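"""Sentence extraction and normalization.

Sentences are the unit of identity for all reuse analysis, and they are
compared by *exact* string equality after a deliberately minimal
normalization: lower-casing and whitespace collapsing, nothing else — no
stemming, no stop-word removal, no punctuation change.  Exact matching
trades recall for precision: when two normalized sentences are identical
it is very likely they share a history, whereas any edit (even a
typographical correction) breaks the trail.

Segmentation is the one genuinely underdetermined step.  The default
splitter breaks after ``.``, ``!`` or ``?`` when followed by whitespace
and a letter or digit, unless the token before the terminator is a known
abbreviation ("E. coli", "et al.", "i.e." ...).  Biological text is
abbreviation-dense, so every published count is sensitive to this choice;
the splitter is therefore pluggable (pass any callable with the same
signature to :func:`extract_sentences`).

Splitting runs on the raw text *before* lower-casing, because
capitalization is a useful segmentation cue.
"""

from __future__ import annotations

import re
from typing import Callable, Iterable

from .errors import BlankSentenceError

__all__ = [
    "DEFAULT_ABBREVIATIONS",
    "normalize",
    "split_sentences",
    "extract_sentences",
]

#: Tokens that, when immediately preceding a terminator, suppress a split.
#: Matched case-insensitively against the alphanumeric run before the dot;
#: dotted forms like "i.e." and "e.g." are covered by their final letter.
DEFAULT_ABBREVIATIONS: frozenset[str] = frozenset(
    {
        "e", "g", "i", "sp", "spp", "subsp", "approx", "al", "cf", "fig",
        "figs", "ca", "vs", "var", "cv", "st", "nov", "etc", "no", "min",
        "max", "mol", "wt", "ref", "refs",
    }
)

_WS_RE = re.compile(r"\s+")
# terminator followed by whitespace and a letter/digit opens a boundary
_BOUNDARY_RE = re.compile(r"[.!?](?=\s+[0-9A-Za-zÀ-ɏ])")
_PARA_RE = re.compile(r"\n[ \t]*\n+")
_TRAILING_TOKEN_RE = re.compile(r"([0-9A-Za-z]+)$")


def normalize(raw: str) -> str:
    """Normalize one raw sentence to its canonical key.

    Lower-cases with the simple per-character mapping and collapses every
    whitespace run (spaces, tabs, newlines) to a single space, trimming the
    ends.  Idempotent.  Raises :class:`BlankSentenceError` on all-whitespace
    input — callers filter empties rather than storing them.
    """
    collapsed = _WS_RE.sub(" ", raw).strip()
    if not collapsed:
        raise BlankSentenceError("cannot normalize an all-whitespace string")
    return collapsed.lower()


def split_sentences(
    text: str, abbreviations: Iterable[str] = DEFAULT_ABBREVIATIONS
) -> list[str]:
    """Split plain annotation text into raw sentence strings.

    Paragraph breaks (blank lines) are hard boundaries — annotation topic
    blocks are independent statements and must never be fused.  Within a
    paragraph, a split opens after ``.``/``!``/``?`` followed by whitespace
    and an alphanumeric, unless the preceding token is in ``abbreviations``.
    Terminator punctuation stays attached to its sentence, and no character
    other than inter-sentence whitespace is invented or dropped.
    """
    abbrevs = {a.lower() for a in abbreviations}
    out: list[str] = []
    for block in _PARA_RE.split(text):
        if not block.strip():
            continue
        start = 0
        for m in _BOUNDARY_RE.finditer(block):
            tok = _TRAILING_TOKEN_RE.search(block, 0, m.start())
            if tok and tok.end() == m.start():
                word = tok.group(1)
                # single letters are initials (genus names, middle initials)
                if word.lower() in abbrevs or (len(word) == 1 and word.isalpha()):
                    continue
            fragment = block[start : m.end()].strip()
            if fragment:
                out.append(fragment)
            start = m.end()
        tail = block[start:].strip()
        if tail:
            out.append(tail)
    return out


def extract_sentences(
    text: str,
    splitter: Callable[[str], list[str]] = split_sentences,
    min_chars: int = 0,
) -> list[str]:
    """Split then normalize; the full extraction pipeline for one text.

    Returns the ordered list of normalized sentence keys.  Duplicates
    within one text are preserved (multiset semantics — within-entry
    repetition is real redundancy).  ``min_chars`` optionally drops
    sentences shorter than the threshold; default keeps everything.
    """
    keys = []
    for raw in splitter(text):
        if not raw.strip():
            continue
        key = normalize(raw)
        if len(key) >= min_chars:
            keys.append(key)
    return keys
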
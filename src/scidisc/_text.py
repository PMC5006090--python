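"""Low-level text utilities shared by the document model and the segmenter.

Offsets are 0-based, half-open ``[start, end)`` character intervals into the
string they were computed from; every public function in the package uses
this convention.
"""

from __future__ import annotations

import re

# Tokens that end with a period without ending the sentence.  Single capital
# letters (initials) are handled separately.
ABBREVIATIONS = frozenset(
    {
        "fig", "figs", "al", "e.g", "i.e", "g", "e", "vs", "cf", "ca",
        "etc", "approx", "no", "resp", "dr", "st",
    }
)

_TERMINATOR = re.compile(r"[.!?]+")
_WORD_BEFORE = re.compile(r"[A-Za-z.]+$")


def _is_abbreviation(prefix: str) -> bool:
    m = _WORD_BEFORE.search(prefix)
    if not m:
        return False
    word = m.group(0).rstrip(".")
    if not word:
        return False
    return word.lower() in ABBREVIATIONS


def _trimmed(text: str, start: int, end: int) -> tuple[int, int] | None:
    while start < end and text[start].isspace():
        start += 1
    while end > start and text[end - 1].isspace():
        end -= 1
    if start == end:
        return None
    return start, end


def sentence_spans(text: str) -> list[tuple[int, int]]:
    """Split *text* into sentence spans.

    Returns ordered, non-overlapping, whitespace-trimmed spans that jointly
    cover every non-whitespace character.  Periods after known abbreviations
    ("Fig.", "et al.", "e.g.", "i.e.", "vs.") and single-letter initials do
    not terminate a sentence.  Newlines are hard boundaries, so headings on
    their own line ("RESULTS") come out as their own sentence.
    """
    spans: list[tuple[int, int]] = []
    for line_start, line in _line_spans(text):
        cursor = 0
        for m in _TERMINATOR.finditer(line):
            end = m.end()
            if end < len(line) and not line[end].isspace():
                continue  # "3.5", "a.b" — not a boundary
            nxt = line[end:].lstrip()
            if nxt and not (nxt[0].isupper() or nxt[0].isdigit() or nxt[0] in "(["):
                continue
            if _is_abbreviation(line[: m.start()]):
                continue
            span = _trimmed(line, cursor, end)
            if span:
                spans.append((line_start + span[0], line_start + span[1]))
            cursor = end
        span = _trimmed(line, cursor, len(line))
        if span:
            spans.append((line_start + span[0], line_start + span[1]))
    return spans


def _line_spans(text: str) -> list[tuple[int, str]]:
    out = []
    pos = 0
    for line in text.split("\n"):
        out.append((pos, line))
        pos += len(line) + 1
    return out


def is_heading(text: str) -> bool:
    """A heading is a short line whose alphabetic characters are all caps."""
    stripped = text.strip()
    letters = [c for c in stripped if c.isalpha()]
    return bool(letters) and all(c.isupper() for c in letters) and len(stripped) < 80
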
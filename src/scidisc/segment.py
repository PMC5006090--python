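"""Sentence and clause segmentation of section text.

The classification unit of the discourse labeler is the *clause*: an
epistemically coherent fragment of a sentence.  Sentences are split with an
abbreviation-safe rule segmenter (:func:`split_sentences`), then divided at a
configurable set of clause delimiters — semicolons, non-restrictive
relatives (", which"), participial connectives (", suggesting",
", indicating"), subordinators ("whereas", "while", "because") and
coordinations ("and" / "but") when a finite verb phrase follows
(:func:`split_clauses`).  The splitter is deliberately rule-based and
deterministic; a full syntactic parser can be substituted through the
``splitter`` argument wherever clauses are produced.

Headings (all-caps lines) become single clauses flagged ``is_heading``; these
are the clauses eligible for the reserved 'none' discourse label.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from typing import IO, Callable, Iterable, Sequence

from ._text import is_heading, sentence_spans
from .doc_model import Document
from .postag import PosTagger, RuleTagger, tokenize

DISCOURSE_LABELS = ("problem", "fact", "hypothesis", "goal", "method", "result", "implication")
NONE_LABEL = "none"
ALL_LABELS = DISCOURSE_LABELS + (NONE_LABEL,)


@dataclass
class Clause:
    """One clause-level classification unit within a document."""

    doc_id: str
    section_index: int
    sentence_index: int
    clause_index: int
    start: int
    end: int
    text: str
    gold_label: str | None = None
    is_heading: bool = False

    def __post_init__(self) -> None:
        if self.gold_label is not None and self.gold_label not in ALL_LABELS:
            raise ValueError(f"unknown discourse label {self.gold_label!r}")


# Delimiters that start a new clause.  Leading punctuation stays with the
# preceding clause; the delimiter word itself starts the new one.
_PHRASE_DELIMITERS = (
    ", which",
    ", suggesting",
    ", indicating",
    "; ",
    ", whereas",
    " whereas ",
    ", while",
    " while ",
    ", because",
    " because ",
)
_COORD = re.compile(r",?\s+(and|but)\s+", re.IGNORECASE)


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Sentence spans of *text*; see :func:`scidisc._text.sentence_spans`."""
    return sentence_spans(text)


class RuleSplitter:
    """Deterministic clause splitter over a fixed delimiter set.

    ``and`` / ``but`` split only when followed by a finite verb phrase,
    approximated as: the next token (or the one after an adverb) is tagged
    as a finite verb by the POS tagger.
    """

    def __init__(self, tagger: PosTagger | None = None,
                 phrase_delimiters: Sequence[str] = _PHRASE_DELIMITERS) -> None:
        self.tagger = tagger or RuleTagger()
        self.phrase_delimiters = tuple(phrase_delimiters)

    def boundaries(self, sentence: str) -> list[int]:
        """Offsets (relative to the sentence) where new clauses begin."""
        cuts: set[int] = set()
        lowered = sentence.lower()
        for delim in self.phrase_delimiters:
            start = 0
            while True:
                i = lowered.find(delim, start)
                if i < 0:
                    break
                # the new clause starts at the first word of the delimiter
                word_at = i + len(delim) - len(delim.lstrip(" ,;"))
                cuts.add(word_at)
                start = i + 1
        for m in _COORD.finditer(sentence):
            # a coordination starts a new clause when a finite clause precedes
            # it and a finite verb follows within a few tokens
            before = [t for _, t in self.tagger.tag(tokenize(sentence[: m.start()]))]
            if not any(t.startswith("VB") or t == "MD" for t in before):
                continue
            after = [t for _, t in self.tagger.tag(tokenize(sentence[m.end():])[:3])]
            if any(t.startswith("VB") or t == "MD" for t in after):
                cuts.add(m.start(1))
        return sorted(c for c in cuts if 0 < c < len(sentence))


def split_clauses(
    sentence_span: tuple[int, int],
    document: Document,
    *,
    section_index: int = 0,
    sentence_index: int = 0,
    splitter: RuleSplitter | Callable[[str], list[int]] | None = None,
) -> list[Clause]:
    """Split one sentence of *document* into ordered, non-overlapping clauses.

    Every non-empty sentence yields at least one clause; the clause spans
    jointly cover the sentence's non-whitespace characters.  All-caps
    headings are returned whole and flagged ``is_heading``.
    """
    start, end = sentence_span
    sentence = document.text[start:end]
    if not sentence.strip():
        return []
    if is_heading(sentence):
        return [
            Clause(document.doc_id, section_index, sentence_index, 0,
                   start, end, sentence.strip(), is_heading=True)
        ]
    if splitter is None:
        splitter = _default_splitter()
    cuts = splitter.boundaries(sentence) if isinstance(splitter, RuleSplitter) else splitter(sentence)
    edges = [0, *cuts, len(sentence)]
    clauses = []
    for ci, (a, b) in enumerate(zip(edges, edges[1:])):
        piece = sentence[a:b]
        pad = len(piece) - len(piece.lstrip())
        a2 = a + pad
        b2 = a + pad + len(piece.strip())
        if b2 <= a2:
            continue
        clauses.append(
            Clause(document.doc_id, section_index, sentence_index, ci,
                   start + a2, start + b2, piece.strip())
        )
    for ci, c in enumerate(clauses):
        c.clause_index = ci
    return clauses


_SPLITTER: RuleSplitter | None = None


def _default_splitter() -> RuleSplitter:
    global _SPLITTER
    if _SPLITTER is None:
        _SPLITTER = RuleSplitter()
    return _SPLITTER


def segment_document(document: Document, *, kinds: tuple[str, ...] = ("results",),
                     splitter: RuleSplitter | None = None) -> list[Clause]:
    """Segment every section of the given kinds into clauses, in text order."""
    out: list[Clause] = []
    for si, section in enumerate(document.sections):
        if section.kind not in kinds:
            continue
        text = document.text[section.start: section.end]
        for sent_i, (a, b) in enumerate(split_sentences(text)):
            out.extend(
                split_clauses(
                    (section.start + a, section.start + b),
                    document,
                    section_index=si,
                    sentence_index=sent_i,
                    splitter=splitter,
                )
            )
    return out


# ---------------------------------------------------------------------------
# CoNLL-style TSV export / import
# ---------------------------------------------------------------------------

TSV_COLUMNS = ("doc_id", "sentence_idx", "clause_idx", "start", "end", "gold_label", "text")


def write_clause_tsv(clauses: Iterable[Clause], stream: IO,
                     predictions: Sequence[str] | None = None) -> None:
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    header = list(TSV_COLUMNS) + (["predicted_label"] if predictions is not None else [])
    writer.writerow(header)
    for i, c in enumerate(clauses):
        row = [c.doc_id, c.sentence_index, c.clause_index, c.start, c.end,
               c.gold_label or "", c.text]
        if predictions is not None:
            row.append(predictions[i])
        writer.writerow(row)


def read_clause_tsv(stream: IO) -> list[Clause]:
    reader = csv.reader(stream, delimiter="\t")
    header = next(reader, None)
    if header is None:
        return []
    out = []
    for row in reader:
        rec = dict(zip(header, row))
        out.append(
            Clause(
                doc_id=rec["doc_id"],
                section_index=0,
                sentence_index=int(rec["sentence_idx"]),
                clause_index=int(rec["clause_idx"]),
                start=int(rec["start"]),
                end=int(rec["end"]),
                text=rec["text"],
                gold_label=rec["gold_label"] or None,
            )
        )
    return out
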
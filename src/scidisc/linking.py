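"""Linking Results-section text and caption sentences to subfigure experiments.

The working assumption of the pipeline is one figure ≙ one experiment, one
subfigure ≙ one sub-experiment.  Narrative text is linked at paragraph
granularity: every Results paragraph that mentions at least one figure
becomes an :class:`ExperimentPassage` linked to all subfigures it cites.
Caption text is linked at subfigure-sentence granularity via
:func:`scidisc.doc_model.extract_caption_subfigures`.

Because a paragraph may cite subfigures curated with different experiment
types, :func:`filter_single_type` keeps only passages whose cited
subfigures map to exactly one distinct type code — the unambiguous training
material for the type classifier — and returns the discarded and unmapped
remainder alongside, so counts are conserved.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

from .doc_model import Document, extract_caption_subfigures


@dataclass
class ExperimentPassage:
    doc_id: str
    source: str  # "narrative" | "caption"
    text: str
    subfigures: list[tuple[int, str | None]]
    type_codes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.source not in ("narrative", "caption"):
            raise ValueError(f"unknown passage source {self.source!r}")
        if self.source == "caption" and len(self.subfigures) != 1:
            raise ValueError("caption passages link exactly one subfigure")
        if self.source == "narrative" and not self.subfigures:
            raise ValueError("narrative passages need at least one linked subfigure")


@dataclass
class ExperimentType:
    code: str
    label: str
    parent: str | None = None


def _paragraph_spans(text: str, start: int, end: int) -> list[tuple[int, int]]:
    spans = []
    pos = start
    while pos < end:
        nxt = text.find("\n\n", pos, end)
        if nxt < 0:
            nxt = end
        if text[pos:nxt].strip():
            spans.append((pos, nxt))
        pos = nxt + 2
    return spans


def link_paragraphs(document: Document) -> list[ExperimentPassage]:
    """One passage per Results paragraph containing >= 1 figure reference.

    Linked subfigures are the distinct (figure, letter) pairs referenced in
    the paragraph, in first-mention order.  Citations are irrelevant here.
    """
    passages = []
    for section in document.sections_of_kind("results"):
        for a, b in _paragraph_spans(document.text, section.start, section.end):
            seen: dict[tuple[int, str | None], None] = {}
            for ref in document.figure_refs:
                if a <= ref.start < b:
                    seen.setdefault(ref.key)
            if seen:
                passages.append(
                    ExperimentPassage(
                        doc_id=document.doc_id,
                        source="narrative",
                        text=document.text[a:b].strip(),
                        subfigures=list(seen),
                    )
                )
    return passages


def caption_passages(document: Document) -> list[ExperimentPassage]:
    """One passage per well-defined '(A) ...' subfigure caption sentence.

    The figure number is taken from the caption section's heading when it
    parses as an integer, else sequentially by caption order.
    """
    passages = []
    for i, section in enumerate(document.sections_of_kind("caption")):
        try:
            figure = int(section.heading) if section.heading else i + 1
        except ValueError:
            figure = i + 1
        caption = document.text[section.start: section.end]
        for letter, sentence in extract_caption_subfigures(caption):
            passages.append(
                ExperimentPassage(
                    doc_id=document.doc_id,
                    source="caption",
                    text=sentence,
                    subfigures=[(figure, letter)],
                )
            )
    return passages


GoldCodeTable = Mapping[tuple[str, int, str | None], str]


@dataclass
class FilterResult:
    kept: list[ExperimentPassage]
    discarded: list[ExperimentPassage]
    unmapped: list[ExperimentPassage]


def filter_single_type(passages: Sequence[ExperimentPassage],
                       gold: GoldCodeTable) -> FilterResult:
    """Partition passages by type ambiguity against the curated gold table.

    kept: all linked subfigures map to exactly one distinct code (assigned
    to ``type_codes``); discarded: more than one distinct code; unmapped:
    a linked subfigure absent from the gold table (logged).
    ``|kept| + |discarded| + |unmapped| == |input|``.
    """
    kept, discarded, unmapped = [], [], []
    for p in passages:
        codes = []
        missing = False
        for figure, letter in p.subfigures:
            code = gold.get((p.doc_id, figure, letter))
            if code is None:
                missing = True
            else:
                codes.append(code)
        if missing:
            logger.warning("passage in %s cites a subfigure missing from the gold table",
                           p.doc_id)
            unmapped.append(p)
        elif len(set(codes)) == 1:
            p.type_codes = [codes[0]]
            kept.append(p)
        else:
            p.type_codes = sorted(set(codes))
            discarded.append(p)
    return FilterResult(kept, discarded, unmapped)


def merge_categories(codes: Iterable[str], merge_map: Mapping[str, str],
                     top_k: int, counts: Mapping[str, int]) -> dict[str, str]:
    """Merge leaf codes into retained categories and keep the top_k by count.

    Returns a mapping leaf code -> merged code restricted to leaves whose
    merged category ranks in the ``top_k`` most frequent after merging;
    frequency ties break by code string order.  Codes absent from the merge
    map merge to themselves.
    """
    if top_k < 1:
        raise ValueError("top_k must be positive")
    merged_counts: dict[str, int] = {}
    resolved: dict[str, str] = {}
    for code in codes:
        target = merge_map.get(code, code)
        resolved[code] = target
        merged_counts[target] = merged_counts.get(target, 0) + counts.get(code, 0)
    ranked = sorted(merged_counts, key=lambda c: (-merged_counts[c], c))
    if top_k > len(ranked):
        logger.warning("top_k=%d exceeds the %d distinct merged codes; keeping all",
                       top_k, len(ranked))
    retained = set(ranked[:top_k])
    return {leaf: tgt for leaf, tgt in resolved.items() if tgt in retained}


def read_gold_codes(stream: IO) -> dict[tuple[str, int, str | None], str]:
    """Read the curated code table: TSV doc_id, figure, subfigure, code."""
    table = {}
    for row in csv.reader(stream, delimiter="\t"):
        if not row or row[0].startswith("#") or row[0] == "doc_id":
            continue
        doc_id, figure, subfigure, code = row[:4]
        letter = subfigure.upper() or None if subfigure else None
        table[(doc_id, int(figure), letter)] = code
    return table


def write_gold_codes(table: GoldCodeTable, stream: IO) -> None:
    w = csv.writer(stream, delimiter="\t", lineterminator="\n")
    w.writerow(["doc_id", "figure", "subfigure", "code"])
    for (doc_id, figure, letter), code in sorted(
        table.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2] or "")
    ):
        w.writerow([doc_id, figure, letter or "", code])


def read_merge_map(stream: IO) -> dict[str, str]:
    out = {}
    for row in csv.reader(stream, delimiter="\t"):
        if not row or row[0].startswith("#"):
            continue
        out[row[0]] = row[1]
    return out
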
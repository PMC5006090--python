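"""Document data model and readers/writers.

A :class:`Document` is the unit every other module consumes: the full text of
an article (or a fragment of one, typically a Results section plus figure
captions) together with stand-off annotations — sections, figure references
and citations — expressed as 0-based half-open character spans.

Three input dialects are supported by :func:`read_document`:

``plain``
    Raw UTF-8 text; the whole text becomes a single ``results`` section.
``jsonl``
    One JSON object per document with keys ``doc_id``, ``text``,
    ``sections``, ``figure_refs`` and ``citations``.  This dialect
    round-trips bit-exactly through :func:`write_document`.
``bioc-xml-subset``
    A minimal passage-oriented XML dialect: ``<document>`` elements holding
    ``<passage>`` elements, each with a ``<text>`` child whose inline
    ``<xref type="fig">`` / ``<xref type="bibr">`` elements become
    :class:`FigureRef` / :class:`Citation` annotations at the character
    offset the element occupies once markup is stripped.  Any other inline
    element is ignored with a logged warning.
"""

from __future__ import annotations

import io
import json
import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable

from lxml import etree

from ._text import sentence_spans

logger = logging.getLogger(__name__)

SECTION_KINDS = ("results", "caption", "other")
CITATION_STYLES = ("numeric-bracket", "author-year", "markup")


class ParseError(ValueError):
    """Raised when an input document cannot be parsed."""


@dataclass
class Section:
    kind: str
    start: int
    end: int
    heading: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in SECTION_KINDS:
            raise ValueError(f"unknown section kind {self.kind!r}")
        if not self.start < self.end:
            raise ValueError("section span must be non-empty")


@dataclass
class FigureRef:
    """A mention of a (sub)figure, e.g. 'Fig. 2B' -> figure 2, subfigure B."""

    figure: int
    subfigure: str | None
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.subfigure is not None:
            self.subfigure = self.subfigure.upper()
            if not re.fullmatch(r"[A-Z]", self.subfigure):
                raise ValueError("subfigure must be a single letter")
        if self.figure < 1:
            raise ValueError("figure numbers are positive")

    @property
    def key(self) -> tuple[int, str | None]:
        return (self.figure, self.subfigure)


@dataclass
class Citation:
    start: int
    end: int
    style: str

    def __post_init__(self) -> None:
        if self.style not in CITATION_STYLES:
            raise ValueError(f"unknown citation style {self.style!r}")
        if not self.start < self.end:
            raise ValueError("citation span must be non-empty")


@dataclass
class Document:
    doc_id: str
    text: str
    sections: list[Section] = field(default_factory=list)
    figure_refs: list[FigureRef] = field(default_factory=list)
    citations: list[Citation] = field(default_factory=list)

    def validate(self) -> "Document":
        n = len(self.text)
        for ann in [*self.sections, *self.figure_refs, *self.citations]:
            if not (0 <= ann.start < ann.end <= n):
                raise ValueError(f"span ({ann.start},{ann.end}) outside document of length {n}")
        ordered = sorted(self.sections, key=lambda s: s.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end:
                raise ValueError("sections overlap")
        return self

    def sections_of_kind(self, kind: str) -> list[Section]:
        return [s for s in self.sections if s.kind == kind]


# ---------------------------------------------------------------------------
# figure-reference and citation detection
# ---------------------------------------------------------------------------

_ANCHOR = re.compile(r"\b(?:Figures?|Figs?\.?)\s*", re.IGNORECASE)
_ITEM = re.compile(r"(\d+)\s*([A-Za-z])?\b")
_LIST_SEP = re.compile(r"\s*(?:,|;|and\b|or\b|&|[–—-])\s*", re.IGNORECASE)
_LETTER_ITEM = re.compile(r"([A-Za-z])\b")
_PAREN = re.compile(r"\(([^()]*)\)")
_PAREN_TOKEN = re.compile(r"(\d+)([A-Za-z])\b")


def _consume_item_list(text: str, pos: int, refs: list[FigureRef]) -> int:
    """Consume 'N[L] (, N[L] | , L)*' starting at *pos*; append refs."""
    current_figure: int | None = None
    while True:
        m = _ITEM.match(text, pos)
        if m:
            current_figure = int(m.group(1))
            letter = m.group(2)
            refs.append(FigureRef(current_figure, letter, m.start(), m.end()))
            pos = m.end()
        elif current_figure is not None:
            lm = _LETTER_ITEM.match(text, pos)
            if not lm:
                break
            refs.append(FigureRef(current_figure, lm.group(1), lm.start(), lm.end()))
            pos = lm.end()
        else:
            break
        sep = _LIST_SEP.match(text, pos)
        if not sep:
            break
        pos = sep.end()
    return pos


def detect_figure_refs(text: str) -> list[FigureRef]:
    """Find figure mentions in running text.

    The grammar: an anchor token (Fig. / Fig / Figs. / Figure / Figures)
    followed by a list of ``<number><letter?>`` items, with conjunctions and
    commas expanded so "Figs. 2B, 2C and 2E" yields one reference per listed
    subfigure; after such an item, bare letters inherit the figure number
    ("Fig. 3A and B").  Bare ``2B``-style tokens with no adjacent anchor are
    accepted only inside parentheses in a sentence that contains an anchor
    earlier on — this keeps gene-name-like tokens out.
    """
    refs: list[FigureRef] = []
    anchored_regions: list[tuple[int, int]] = []
    for m in _ANCHOR.finditer(text):
        start = len(refs)
        end_pos = _consume_item_list(text, m.end(), refs)
        if len(refs) > start:
            anchored_regions.append((m.start(), end_pos))

    # bare parenthesised lists such as "(2B, 2C, 2E, 3A, 3B)"
    for s_start, s_end in sentence_spans(text):
        sentence = text[s_start:s_end]
        first_anchor = _ANCHOR.search(sentence)
        if not first_anchor:
            continue
        for pm in _PAREN.finditer(sentence, first_anchor.end()):
            inner = pm.group(1)
            tokens = _PAREN_TOKEN.findall(inner)
            stripped = _LIST_SEP.sub("", _PAREN_TOKEN.sub("", inner)).strip()
            if not tokens or stripped:
                continue  # content is not purely a subfigure list
            for tm in _PAREN_TOKEN.finditer(inner):
                offset = s_start + pm.start(1)
                refs.append(
                    FigureRef(int(tm.group(1)), tm.group(2), offset + tm.start(), offset + tm.end())
                )

    refs.sort(key=lambda r: (r.start, r.end))
    out: list[FigureRef] = []
    for r in refs:
        if out and r.start < out[-1].end:
            continue  # overlapping duplicate from the two passes
        out.append(r)
    return out


_NUMERIC_BRACKET = re.compile(r"\[\d+(?:\s*[,–-]\s*\d+)*\]")
_NUMERIC_PAREN = re.compile(r"\((?:19|20)?\d+(?:\s*[,–-]\s*\d+)*\)")
_AUTHOR_YEAR = re.compile(r"\([^()]*[A-Za-z][^()]*\b(?:19|20)\d{2}[a-z]?\)")


def detect_citations(text: str) -> list[Citation]:
    """Find textual citation spans: numeric brackets and author-year parens.

    Figure-like parentheticals such as "(2B)" are never citations; any match
    overlapping a detected figure reference is dropped, so the two detectors
    return disjoint spans on the same text.
    """
    fig_spans = [(r.start, r.end) for r in detect_figure_refs(text)]
    cites: list[Citation] = []
    for pat, style in (
        (_NUMERIC_BRACKET, "numeric-bracket"),
        (_NUMERIC_PAREN, "numeric-bracket"),
        (_AUTHOR_YEAR, "author-year"),
    ):
        for m in pat.finditer(text):
            if any(m.start() < fe and fs < m.end() for fs, fe in fig_spans):
                continue
            if cites and any(m.start() < c.end and c.start < m.end() for c in cites):
                continue
            cites.append(Citation(m.start(), m.end(), style))
    cites.sort(key=lambda c: c.start)
    return cites


_CAPTION_MARKER = re.compile(r"\(\s*([A-Za-z])\s*\)")


def extract_caption_subfigures(caption_text: str) -> list[tuple[str, str]]:
    """Split a figure caption into per-subfigure sentences.

    A subfigure caption starts with a single letter in parentheses —
    "(A) Lysates were blotted." — and runs to the next such marker or the
    end of the caption.  Markers are recognised at the start of the caption
    or after whitespace; text before the first marker is not returned.
    Duplicate letters are preserved in order (policy is the caller's).
    """
    markers = [
        m
        for m in _CAPTION_MARKER.finditer(caption_text)
        if m.start() == 0 or caption_text[m.start() - 1].isspace()
    ]
    out = []
    for i, m in enumerate(markers):
        end = markers[i + 1].start() if i + 1 < len(markers) else len(caption_text)
        out.append((m.group(1).upper(), caption_text[m.end(): end].strip()))
    return out


def annotate(document: Document) -> Document:
    """Populate figure_refs/citations from the text when a document has none."""
    if not document.figure_refs:
        document.figure_refs = detect_figure_refs(document.text)
    if not document.citations:
        document.citations = detect_citations(document.text)
    return document


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _doc_from_json(obj: dict) -> Document:
    return Document(
        doc_id=obj["doc_id"],
        text=obj["text"],
        sections=[Section(**s) for s in obj.get("sections", [])],
        figure_refs=[FigureRef(**f) for f in obj.get("figure_refs", [])],
        citations=[Citation(**c) for c in obj.get("citations", [])],
    ).validate()


def _doc_to_json(doc: Document) -> dict:
    return {
        "doc_id": doc.doc_id,
        "text": doc.text,
        "sections": [
            {"kind": s.kind, "start": s.start, "end": s.end, "heading": s.heading}
            for s in doc.sections
        ],
        "figure_refs": [
            {"figure": f.figure, "subfigure": f.subfigure, "start": f.start, "end": f.end}
            for f in doc.figure_refs
        ],
        "citations": [{"start": c.start, "end": c.end, "style": c.style} for c in doc.citations],
    }


def _as_text(source: IO | str) -> str:
    if isinstance(source, str):
        return source
    data = source.read()
    if isinstance(data, bytes):
        data = data.decode("utf-8")
    return data


def read_documents(source: IO | str, format: str) -> list[Document]:
    """Read zero or more documents from a stream (or a raw string)."""
    if format == "plain":
        text = _as_text(source)
        sections = [Section("results", 0, len(text))] if text.strip() else []
        return [Document(doc_id="doc", text=text, sections=sections).validate()]
    if format == "jsonl":
        text = _as_text(source)
        return [_doc_from_json(json.loads(line)) for line in text.splitlines() if line.strip()]
    if format == "bioc-xml-subset":
        return _read_bioc(source)
    raise ParseError(f"unknown format {format!r}; expected plain, jsonl or bioc-xml-subset")


def read_document(source: IO | str, format: str) -> Document:
    docs = read_documents(source, format)
    if not docs:
        raise ParseError("no document found in input")
    return docs[0]


def write_document(doc: Document, stream: IO) -> None:
    """Write one document as a jsonl line (inverse of the jsonl reader)."""
    stream.write(json.dumps(_doc_to_json(doc), ensure_ascii=False) + "\n")


def write_documents(docs: Iterable[Document], stream: IO) -> None:
    for doc in docs:
        write_document(doc, stream)


def _read_bioc(source: IO | str) -> list[Document]:
    data = _as_text(source)
    try:
        root = etree.fromstring(data.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed XML: {exc}") from exc
    doc_elems = root.findall(".//document") if root.tag != "document" else [root]
    docs = []
    for i, delem in enumerate(doc_elems):
        docs.append(_bioc_document(delem, default_id=f"doc{i}"))
    return docs


def _bioc_document(delem: etree._Element, default_id: str) -> Document:
    doc_id = delem.get("id") or default_id
    parts: list[str] = []
    sections: list[Section] = []
    figure_refs: list[FigureRef] = []
    citations: list[Citation] = []
    offset = 0
    for passage in delem.findall("passage"):
        if parts:
            parts.append("\n\n")
            offset += 2
        start = offset
        text_elem = passage.find("text")
        if text_elem is None:
            continue
        offset = _flatten(text_elem, parts, offset, figure_refs, citations)
        kind = passage.get("kind", "other")
        if kind not in SECTION_KINDS:
            logger.warning("unknown passage kind %r in %s; treating as 'other'", kind, doc_id)
            kind = "other"
        if offset > start:
            sections.append(Section(kind, start, offset, heading=passage.get("heading")))
    return Document(doc_id, "".join(parts), sections, figure_refs, citations).validate()


def _flatten(elem, parts, offset, figure_refs, citations) -> int:
    if elem.text:
        parts.append(elem.text)
        offset += len(elem.text)
    for child in elem:
        if child.tag == "xref":
            content = "".join(child.itertext())
            start = offset
            parts.append(content)
            offset += len(content)
            xtype = child.get("type")
            if xtype == "fig":
                figure_refs.append(_xref_figure(child, content, start, offset))
            elif xtype == "bibr":
                citations.append(Citation(start, offset, "markup"))
            else:
                logger.warning("ignoring xref of unknown type %r", xtype)
        else:
            logger.warning("ignoring unsupported element <%s>", child.tag)
        if child.tail:
            parts.append(child.tail)
            offset += len(child.tail)
    return offset


def _xref_figure(child, content: str, start: int, end: int) -> FigureRef:
    if child.get("figure"):
        return FigureRef(int(child.get("figure")), child.get("subfigure"), start, end)
    found = detect_figure_refs(content) or [
        FigureRef(int(m.group(1)), m.group(2), 0, 1)
        for m in [_ITEM.search(content)]
        if m
    ]
    if not found:
        raise ParseError(f"cannot interpret figure xref content {content!r}")
    f = found[0]
    return FigureRef(f.figure, f.subfigure, start, end)
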
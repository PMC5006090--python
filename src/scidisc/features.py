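"""Clause feature extraction: the four feature families of the labelers.

Each clause becomes a sparse vector over four namespaces:

``pos:T``
    count of Penn tag ``T`` in the clause (pluggable tagger);
``lex:w``
    binary indicator for each lowercased token tagged as a verb (``VB*``)
    or adverb (``RB*``) — these carry most of the epistemic signal;
``link:figure`` / ``link:citation``
    binary flags set when a figure reference / citation annotation
    intersects the clause span (internal links mark the article's own
    results; external links mark reported prior work);
``cue:phrase``
    binary indicator for each cue-lexicon phrase found in the clause by
    case-insensitive substring match.

Extraction is a pure function of (clause text, document annotations,
lexicon, tagger); identical inputs give identical vectors.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import IO, Mapping

from .doc_model import Document
from .postag import PosTagger, RuleTagger, tokenize
from .segment import ALL_LABELS, Clause

SCHEMA_VERSION = "1"


@dataclass
class FeatureVector:
    features: dict[str, float]
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self) -> None:
        for name, value in self.features.items():
            if value < 0:
                raise ValueError(f"negative feature value for {name!r}")


class CueLexicon:
    """Phrase -> hinted discourse label, matched case-insensitively."""

    def __init__(self, entries: Mapping[str, str] | None = None) -> None:
        self._entries: dict[str, str] = {}
        for phrase, label in (entries or {}).items():
            self.add(phrase, label)

    def add(self, phrase: str, label: str) -> None:
        if label not in ALL_LABELS:
            raise ValueError(f"unknown label {label!r} for cue {phrase!r}")
        self._entries[phrase.lower()] = label

    def lookup(self, phrase: str) -> str | None:
        return self._entries.get(phrase.lower())

    def hits(self, text: str) -> list[tuple[str, str]]:
        """All (phrase, label) entries occurring as substrings of *text*."""
        lowered = text.lower()
        return [(p, l) for p, l in sorted(self._entries.items()) if p in lowered]

    def merged_with(self, other: "CueLexicon") -> "CueLexicon":
        """New lexicon where *other*'s entries override key-by-key."""
        merged = dict(self._entries)
        merged.update(other._entries)
        return CueLexicon(merged)

    def __len__(self) -> int:
        return len(self._entries)

    def items(self):
        return self._entries.items()

    @classmethod
    def from_tsv(cls, stream: IO) -> "CueLexicon":
        lex = cls()
        for row in csv.reader(stream, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            lex.add(row[0], row[1])
        return lex


def default_lexicon() -> CueLexicon:
    """The shipped cue lexicon (see ``data/default_lexicon.tsv``).

    Kept deliberately small — a couple of dozen high-precision phrases; a
    user lexicon loaded from file overrides entries key-by-key via
    :meth:`CueLexicon.merged_with`.
    """
    ref = resources.files("scidisc.data").joinpath("default_lexicon.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        return CueLexicon.from_tsv(fh)


def _slug(phrase: str) -> str:
    return phrase.replace(" ", "_")


def extract_features(
    clause: Clause,
    document: Document | None = None,
    *,
    lexicon: CueLexicon | None = None,
    tagger: PosTagger | None = None,
) -> FeatureVector:
    """Compute the four-family feature vector for one clause.

    ``document`` supplies the figure-reference and citation annotations for
    the ``link:*`` flags; pass None when no annotations are available (the
    flags are then simply absent).
    """
    if lexicon is None:
        lexicon = default_lexicon()
    if tagger is None:
        tagger = _default_tagger()
    feats: dict[str, float] = {}
    tokens = tokenize(clause.text)
    for token, tag in tagger.tag(tokens):
        feats[f"pos:{tag}"] = feats.get(f"pos:{tag}", 0.0) + 1.0
        if tag.startswith(("VB", "RB")):
            feats[f"lex:{token.lower()}"] = 1.0
    if document is not None:
        if any(r.start < clause.end and clause.start < r.end for r in document.figure_refs):
            feats["link:figure"] = 1.0
        if any(c.start < clause.end and clause.start < c.end for c in document.citations):
            feats["link:citation"] = 1.0
    for phrase, _hint in lexicon.hits(clause.text):
        feats[f"cue:{_slug(phrase)}"] = 1.0
    return FeatureVector(feats)


_TAGGER: RuleTagger | None = None


def _default_tagger() -> RuleTagger:
    global _TAGGER
    if _TAGGER is None:
        _TAGGER = RuleTagger()
    return _TAGGER
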
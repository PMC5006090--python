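"""A pluggable part-of-speech tagging interface with a rule-based default.

Feature extraction needs Penn-Treebank-style tags only to (a) count tag
occurrences and (b) pick out verbs (``VB*``) and adverbs (``RB*``).  Any
callable satisfying :class:`PosTagger` can be plugged in; the shipped
:class:`RuleTagger` combines a closed-class lexicon, a verb lexicon of
common scientific-English verbs, and morphological suffix rules.  It is not
a general-purpose tagger, but it is deterministic, dependency-free and
accurate on the verb/adverb distinctions the feature scheme relies on.
"""

from __future__ import annotations

import re
from typing import Protocol, Sequence

_TOKEN = re.compile(r"[A-Za-z]+(?:['’][a-z]+)?|\d+(?:\.\d+)?|[^\sA-Za-z0-9]")


def tokenize(text: str) -> list[str]:
    return _TOKEN.findall(text)


class PosTagger(Protocol):
    def tag(self, tokens: Sequence[str]) -> list[tuple[str, str]]:
        """Return (token, Penn tag) pairs, one per input token."""
        ...


_CLOSED = {
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "these": "DT",
    "that": "IN", "those": "DT", "each": "DT", "no": "DT",
    "of": "IN", "in": "IN", "on": "IN", "at": "IN", "by": "IN", "with": "IN",
    "from": "IN", "to": "TO", "for": "IN", "as": "IN", "into": "IN",
    "after": "IN", "before": "IN", "during": "IN", "between": "IN",
    "through": "IN", "under": "IN", "upon": "IN", "via": "IN",
    "whether": "IN", "because": "IN", "while": "IN", "whereas": "IN",
    "although": "IN", "if": "IN", "than": "IN", "since": "IN",
    "and": "CC", "but": "CC", "or": "CC", "nor": "CC",
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD", "be": "VB",
    "been": "VBN", "being": "VBG", "am": "VBP",
    "has": "VBZ", "have": "VBP", "had": "VBD", "having": "VBG",
    "do": "VBP", "does": "VBZ", "did": "VBD", "done": "VBN",
    "can": "MD", "could": "MD", "may": "MD", "might": "MD", "must": "MD",
    "shall": "MD", "should": "MD", "will": "MD", "would": "MD",
    "not": "RB", "also": "RB", "however": "RB", "thus": "RB", "then": "RB",
    "therefore": "RB", "moreover": "RB", "furthermore": "RB", "here": "RB",
    "there": "EX", "very": "RB", "further": "RB", "together": "RB",
    "we": "PRP", "it": "PRP", "they": "PRP", "its": "PRP$", "our": "PRP$",
    "their": "PRP$", "which": "WDT", "what": "WP", "who": "WP", "how": "WRB",
    "when": "WRB", "where": "WRB", "why": "WRB",
    "more": "JJR", "most": "JJS", "less": "JJR", "least": "JJS",
    "previously": "RB", "recently": "RB", "markedly": "RB",
    "significantly": "RB", "strongly": "RB", "only": "RB",
}

# Base forms of verbs common in experimental narrative; inflections are
# derived morphologically at tag time.
_VERB_STEMS = {
    "suggest", "demonstrate", "indicate", "show", "observe", "find", "found",
    "reveal", "confirm", "examine", "test", "determine", "investigate",
    "ask", "measure", "perform", "treat", "incubate", "transfect", "express",
    "purify", "immunoprecipitate", "precipitate", "blot", "probe", "stain",
    "lyse", "analyze", "analyse", "quantify", "detect", "bind", "bound",
    "increase", "decrease", "reduce", "enhance", "abolish", "block",
    "require", "remain", "appear", "seem", "report", "describe", "propose",
    "hypothesize", "hypothesized", "conclude", "support", "establish",
    "know", "known", "shown", "sought", "use", "used", "assess", "compare",
    "induce", "inhibit", "activate", "phosphorylate", "interact",
    "colocalize", "localize", "associate", "coprecipitate", "depend",
}


def _verb_tag(lower: str) -> str | None:
    if lower in _VERB_STEMS:
        if lower.endswith(("ed", "wn", "ne", "ght")) and lower not in ("need",):
            return "VBD"
        return "VBP"
    for stem in _VERB_STEMS:
        if lower == stem + "s" or (stem.endswith("e") and lower == stem[:-1] + "es"):
            return "VBZ"
        if lower == stem + "ed" or (stem.endswith("e") and lower == stem[:-1] + "ed"):
            return "VBD"
        if lower == stem + "ing" or (stem.endswith("e") and lower == stem[:-1] + "ing"):
            return "VBG"
        if stem.endswith("y") and lower in (stem[:-1] + "ies", stem[:-1] + "ied"):
            return "VBZ" if lower.endswith("ies") else "VBD"
    return None


class RuleTagger:
    """Deterministic lexicon + suffix Penn-style tagger."""

    def tag(self, tokens: Sequence[str]) -> list[tuple[str, str]]:
        return [(tok, self.tag_one(tok)) for tok in tokens]

    def tag_one(self, token: str) -> str:
        lower = token.lower()
        if not token[:1].isalnum():
            return token if token in ",.:;()[]" else "SYM"
        if token[:1].isdigit():
            return "CD"
        if lower in _CLOSED:
            return _CLOSED[lower]
        verb = _verb_tag(lower)
        if verb:
            return verb
        if lower.endswith("ly"):
            return "RB"
        if lower.endswith(("ous", "ive", "able", "ible", "ic", "al", "ful", "ent", "ant")):
            return "JJ"
        if lower.endswith("ing"):
            return "VBG"
        if lower.endswith("ed"):
            return "VBN"
        if token[:1].isupper():
            return "NNP"
        if lower.endswith("s") and not lower.endswith(("ss", "us", "is")):
            return "NNS"
        return "NN"
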
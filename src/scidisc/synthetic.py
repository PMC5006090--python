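"""Synthetic labeled corpora with the statistical structure the models assume.

Two generators, both fully reproducible from their spec's seed:

* :func:`generate_discourse_corpus` emits Results-section documents whose
  clause labels follow a first-order Markov chain encoding the archetypal
  narrative order (context: problem/fact/hypothesis -> goal -> method ->
  result -> implication).  Clauses are rendered from stylized label-specific
  templates; with configurable probability a clause instead uses a generic,
  label-ambiguous template, carries a cue-lexicon phrase, a figure reference
  (result clauses) or a numeric citation (fact clauses).  Realism of the
  prose is a non-goal; the statistical structure — label ordering, cue
  emission, link placement, class priors — is the contract.

* :func:`generate_exptype_corpus` emits experiment-type passages (narrative
  paragraphs and "(A) ..." caption sentences) over a configurable class
  inventory of assay vocabularies (two-hybrid, coimmunoprecipitation,
  pull-down, fluorescence and confocal microscopy by default), with a
  term-bleed probability that replaces class terms by draws from the union
  vocabulary, and a caption/narrative cue-density ratio.

Default class priors for the discourse generator are the gold supports of
the reference discourse evaluation (2, 53, 36, 30, 98, 182, 44 over 445);
default experiment-type supports are apportioned to (57, 332, 125, 34, 33)
out of 581.  Both are the corpus conditions the evaluation layer reports
against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .doc_model import Document, Section, annotate
from .features import default_lexicon
from .linking import ExperimentPassage
from .segment import Clause, DISCOURSE_LABELS

# Gold supports of the reference discourse evaluation, used as class priors.
REFERENCE_DISCOURSE_SUPPORTS = {
    "problem": 2, "fact": 53, "hypothesis": 36, "goal": 30,
    "method": 98, "result": 182, "implication": 44,
}

_END = len(DISCOURSE_LABELS)  # virtual end state index


@dataclass
class CorpusSpec:
    """Parameters of the discourse-corpus generator.

    ``transition`` is a (7, 8) row-stochastic matrix over the seven labels
    plus a virtual end state (column 7); ``start`` is the distribution over
    the seven labels for the first clause of a paragraph.  When left None,
    both are built by :meth:`archetypal` so that expected label frequencies
    match ``label_priors`` at the given mean paragraph length.
    """

    n_documents: int = 25
    paragraphs_per_document: int = 10
    label_priors: dict[str, float] = field(
        default_factory=lambda: {
            k: v / sum(REFERENCE_DISCOURSE_SUPPORTS.values())
            for k, v in REFERENCE_DISCOURSE_SUPPORTS.items()
        }
    )
    mean_paragraph_length: float = 8.0
    transition: np.ndarray | None = None
    start: np.ndarray | None = None
    cue_emission: dict[str, float] = field(
        default_factory=lambda: {label: 0.6 for label in DISCOURSE_LABELS}
    )
    cue_dropout: float = 0.1
    figure_ref_rate: float = 0.6
    citation_rate: float = 0.5
    generic_template_rate: float = 0.35
    include_headings: bool = True
    max_paragraph_length: int = 50
    seed: int = 1

    def __post_init__(self) -> None:
        if self.transition is None or self.start is None:
            t, s = self._archetypal_matrices()
            if self.transition is None:
                self.transition = t
            if self.start is None:
                self.start = s
        self.transition = np.asarray(self.transition, dtype=float)
        self.start = np.asarray(self.start, dtype=float)
        self.validate()

    def _archetypal_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """Stage-skip chain matching the label priors in expectation.

        Expected clause count of label i per paragraph is m_i = L * prior_i,
        realised as an inclusion probability q_i (visit the stage at all)
        and a self-loop s_i (dwell once there): q_i / (1 - s_i) = m_i.
        """
        L = len(DISCOURSE_LABELS)
        priors = np.array([self.label_priors[l] for l in DISCOURSE_LABELS], dtype=float)
        if not np.isclose(priors.sum(), 1.0):
            raise ValueError("label priors must sum to 1")
        m = self.mean_paragraph_length * priors / priors.sum()
        q = np.minimum(m, 0.95)
        s = np.where(m > 0.95, 1.0 - 0.95 / np.maximum(m, 1e-12), 0.0)
        trans = np.zeros((L, L + 1))
        for i in range(L):
            trans[i, i] = s[i]
            skip = 1.0 - s[i]
            for j in range(i + 1, L):
                trans[i, j] = skip * q[j]
                skip *= 1.0 - q[j]
            trans[i, _END] = skip
        start = np.zeros(L)
        skip = 1.0
        for j in range(L):
            start[j] = skip * q[j]
            skip *= 1.0 - q[j]
        start /= start.sum()  # condition on a non-empty paragraph
        return trans, start

    def validate(self) -> "CorpusSpec":
        if self.transition.shape != (len(DISCOURSE_LABELS), len(DISCOURSE_LABELS) + 1):
            raise ValueError("transition matrix must be 7 x 8 (seven labels + end)")
        if (self.transition < 0).any() or (self.transition > 1).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(self.transition.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.start.sum(), 1.0) or (self.start < 0).any():
            raise ValueError("start distribution must be a distribution over the labels")
        for name in ("cue_dropout", "figure_ref_rate", "citation_rate",
                     "generic_template_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        return self


_ENTITIES = (
    "RAF1", "MEK1", "AKT1", "ERK2", "STAT3", "GRB2", "SRC", "PTEN",
    "CDK2", "BRCA1", "SMAD3", "JAK2", "MDM2", "CCND1", "EGFR", "KRAS",
)

# Base templates deliberately avoid every phrase of the shipped cue lexicon,
# so cue presence is governed solely by the emission/dropout parameters.
_TEMPLATES: dict[str, tuple[str, ...]] = {
    "problem": (
        "The mechanism linking {a} to {b} has not been resolved .",
        "How {a} regulates {b} is an open question .",
        "The basis of {a} dependence in {b} signaling has not been defined .",
    ),
    "fact": (
        "{a} is a core component of the {b} pathway .",
        "{a} binds {b} in many cell types .",
        "{a} acts as a scaffold for {b} in this cascade .",
    ),
    "hypothesis": (
        "{a} could act upstream of {b} in this setting .",
        "One explanation is that {a} modulates {b} directly .",
        "{a} activity toward {b} would then depend on complex assembly .",
    ),
    "goal": (
        "To address this question , we examined the role of {a} in {b} signaling .",
        "We next examined the interaction between {a} and {b} .",
        "We therefore compared {a} binding in {b} expressing cells .",
    ),
    "method": (
        "Cells expressing {a} were lysed before blotting for {b} .",
        "Extracts were subjected to immunoprecipitation with an antibody against {a} .",
        "Recombinant {a} was mixed with purified {b} before analysis .",
    ),
    "result": (
        "Binding of {a} to {b} increased markedly",
        "Levels of phosphorylated {a} were strongly reduced in {b} depleted cells",
        "{a} coprecipitated with {b} under these conditions",
    ),
    "implication": (
        "These findings point to a direct role for {a} in {b} activation .",
        "{a} therefore appears to couple {b} engagement to downstream signaling .",
        "Such behavior supports a model in which {a} gates {b} output .",
    ),
}

# Label-ambiguous fillers shared by all seven labels.
_GENERIC_TEMPLATES = (
    "{a} and {b} were compared across the conditions described above .",
    "The role of {a} in this pathway was considered in relation to {b} .",
    "{a} levels in {b} expressing cells varied across replicates .",
    "The relationship between {a} and {b} was assessed further .",
)


@dataclass
class LabeledDocument:
    """A generated document plus its gold-labeled clauses (in text order)."""

    document: Document
    clauses: list[Clause]


def _cues_by_label() -> dict[str, list[str]]:
    by_label: dict[str, list[str]] = {label: [] for label in DISCOURSE_LABELS}
    for phrase, label in default_lexicon().items():
        if label in by_label:
            by_label[label].append(phrase)
    return {k: sorted(v) for k, v in by_label.items()}


def _sample_labels(spec: CorpusSpec, rng: np.random.Generator) -> list[int]:
    state = int(rng.choice(len(DISCOURSE_LABELS), p=spec.start))
    labels = [state]
    while len(labels) < spec.max_paragraph_length:
        state = int(rng.choice(len(DISCOURSE_LABELS) + 1, p=spec.transition[state]))
        if state == _END:
            break
        labels.append(state)
    return labels


def _render_clause(label: str, spec: CorpusSpec, rng: np.random.Generator,
                   cues: dict[str, list[str]], figure_counter: list[int]) -> str:
    a, b = rng.choice(len(_ENTITIES), size=2, replace=False)
    if rng.random() < spec.generic_template_rate:
        bank = _GENERIC_TEMPLATES
    else:
        bank = _TEMPLATES[label]
    text = bank[int(rng.integers(len(bank)))].format(a=_ENTITIES[a], b=_ENTITIES[b])
    trailer = ""
    if label == "result" and rng.random() < spec.figure_ref_rate:
        figure_counter[0] += rng.random() < 0.3
        letter = "ABCDE"[int(rng.integers(5))]
        trailer += f" ( Fig. {max(figure_counter[0], 1)}{letter} )"
    if label == "fact" and rng.random() < spec.citation_rate:
        trailer += f" [{int(rng.integers(1, 40))}]"
    emit = spec.cue_emission.get(label, 0.0) * (1.0 - spec.cue_dropout)
    if cues[label] and rng.random() < emit:
        cue = cues[label][int(rng.integers(len(cues[label])))]
        trailer += f" ( {cue} )"
    if text.endswith(" ."):
        return text[:-2] + trailer + " ."
    return text + trailer + " ."


def generate_discourse_corpus(spec: CorpusSpec | None = None) -> list[LabeledDocument]:
    """Generate gold-labeled synthetic Results-section documents."""
    spec = spec or CorpusSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    cues = _cues_by_label()
    out = []
    for d in range(spec.n_documents):
        doc_id = f"synth{d:04d}"
        parts: list[str] = []
        clauses: list[Clause] = []
        offset = 0
        sentence_index = 0
        figure_counter = [0]

        def _append(text: str, label: str | None, heading: bool = False) -> None:
            nonlocal offset, sentence_index
            start = offset
            parts.append(text)
            offset += len(text)
            clauses.append(
                Clause(doc_id, 0, sentence_index, 0, start, start + len(text),
                       text.strip(), gold_label=label, is_heading=heading)
            )
            sentence_index += 1

        if spec.include_headings:
            _append("RESULTS", "none", heading=True)
            parts.append("\n\n")
            offset += 2
        for p in range(spec.paragraphs_per_document):
            if p and parts:
                parts.append("\n\n")
                offset += 2
            labels = _sample_labels(spec, rng)
            for i, li in enumerate(labels):
                label = DISCOURSE_LABELS[li]
                if i:
                    parts.append(" ")
                    offset += 1
                _append(_render_clause(label, spec, rng, cues, figure_counter), label)
        text = "".join(parts)
        document = Document(doc_id, text, [Section("results", 0, len(text))])
        annotate(document)
        out.append(LabeledDocument(document.validate(), clauses))
    return out


# ---------------------------------------------------------------------------
# experiment-type corpus
# ---------------------------------------------------------------------------

# Disjoint default assay vocabularies (token level); confusability between
# classes comes from the term-bleed parameter and the shared filler tokens.
DEFAULT_CLASS_TERMS: dict[str, tuple[str, ...]] = {
    "MI:0018": ("yeast", "hybrid", "bait", "prey", "reporter", "transformants",
                "galactosidase", "trap"),
    "MI:0019": ("coimmunoprecipitation", "immunoprecipitated", "lysates",
                "antibody", "immunoblot", "coprecipitated", "immunocomplexes",
                "blotted"),
    "MI:0096": ("gst", "glutathione", "beads", "pulldown", "recombinant",
                "sepharose", "fusion", "vitro"),
    "MI:0416": ("epifluorescence", "gfp", "staining", "dapi", "fixed",
                "fluorescent", "coverslips", "counterstained"),
    "MI:0663": ("confocal", "colocalization", "merged", "laser", "scanning",
                "overlay", "stacks", "airy"),
}

# Supports of the reference caption evaluation, used as default frequencies.
REFERENCE_EXPTYPE_SUPPORTS = {
    "MI:0018": 57, "MI:0019": 332, "MI:0096": 125, "MI:0416": 34, "MI:0663": 33,
}

_FILLER = ("protein", "complex", "signal", "analysis", "panel", "experiment",
           "interaction", "sample", "expression", "control", "figure", "shown")


@dataclass
class ExpCorpusSpec:
    """Parameters of the experiment-type passage generator."""

    class_terms: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_TERMS)
    )
    class_frequencies: dict[str, float] = field(
        default_factory=lambda: {
            k: v / sum(REFERENCE_EXPTYPE_SUPPORTS.values())
            for k, v in REFERENCE_EXPTYPE_SUPPORTS.items()
        }
    )
    n_passages: int = 581
    term_bleed: float = 0.25
    caption_ratio: float = 2.0   # caption class-term density / narrative density
    narrative_class_terms: int = 3
    filler_terms: int = 6
    source: str = "both"         # "narrative" | "caption" | "both"
    seed: int = 1

    def validate(self) -> "ExpCorpusSpec":
        if not self.class_terms or any(not v for v in self.class_terms.values()):
            raise ValueError("every class needs a non-empty term pool")
        freqs = np.array([self.class_frequencies[c] for c in self.class_terms])
        if not np.isclose(freqs.sum(), 1.0) or (freqs < 0).any():
            raise ValueError("class frequencies must form a distribution")
        if not 0.0 <= self.term_bleed <= 1.0:
            raise ValueError("term_bleed must lie in [0, 1]")
        if self.source not in ("narrative", "caption", "both"):
            raise ValueError(f"unknown source {self.source!r}")
        return self


def _apportion(freqs: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of n items to the given shares."""
    raw = freqs * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base


def generate_exptype_corpus(spec: ExpCorpusSpec | None = None) -> list[ExperimentPassage]:
    """Generate single-gold-code experiment passages (narrative and caption)."""
    spec = spec or ExpCorpusSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    codes = sorted(spec.class_terms)
    freqs = np.array([spec.class_frequencies[c] for c in codes], dtype=float)
    supports = _apportion(freqs / freqs.sum(), spec.n_passages)
    union = sorted({t for pool in spec.class_terms.values() for t in pool})
    assignments = np.repeat(np.arange(len(codes)), supports)
    rng.shuffle(assignments)
    passages = []
    for i, ci in enumerate(assignments):
        code = codes[ci]
        if spec.source == "both":
            source = "caption" if rng.random() < 0.5 else "narrative"
        else:
            source = spec.source
        n_class = spec.narrative_class_terms
        if source == "caption":
            n_class = max(1, int(round(n_class * spec.caption_ratio)))
        pool = spec.class_terms[code]
        tokens = []
        for _ in range(n_class):
            if rng.random() < spec.term_bleed:
                tokens.append(union[int(rng.integers(len(union)))])
            else:
                tokens.append(pool[int(rng.integers(len(pool)))])
        tokens.extend(_FILLER[int(rng.integers(len(_FILLER)))]
                      for _ in range(spec.filler_terms))
        rng.shuffle(tokens)
        figure = 1 + i % 6
        letter = "ABCDEF"[int(rng.integers(6))]
        body = " ".join(tokens)
        if source == "caption":
            text = f"({letter}) {body.capitalize()}."
        else:
            text = f"{body.capitalize()} ( Fig. {figure}{letter} )."
        passages.append(
            ExperimentPassage(
                doc_id=f"exp{i:04d}",
                source=source,
                text=text,
                subfigures=[(figure, letter)],
                type_codes=[code],
            )
        )
    return passages
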
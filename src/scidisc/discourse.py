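"""Seven-way discourse-segment labelers: SVM one-vs-all and linear-chain CRF.

Both models operate on :class:`ClauseSequence` objects — the clauses of one
paragraph, in text order, paired with their feature vectors.  The SVM
treats clauses independently (argmax over seven one-vs-all margins); the
CRF additionally learns adjacent-label transition weights and so can
exploit the archetypal ordering of Results-section narration
(context -> goal -> method -> result -> implication).

Heading clauses carry the reserved 'none' label and are filtered out before
training and evaluation: the classifiers are strictly seven-way.

Ties in the SVM argmax are broken by the fixed label order
``problem < fact < hypothesis < goal < method < result < implication``.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from sklearn.svm import LinearSVC

from .crf import LinearChainCRF
from .doc_model import Document
from .features import SCHEMA_VERSION, FeatureVector
from .segment import DISCOURSE_LABELS, Clause

LABEL_ORDER: tuple[str, ...] = DISCOURSE_LABELS  # tie-break and storage order
_LABEL_INDEX = {label: i for i, label in enumerate(LABEL_ORDER)}


class SchemaMismatchError(RuntimeError):
    """Feature schema of the model does not match the vectors offered."""


@dataclass
class ClauseSequence:
    """Clauses of one paragraph, in text order, with their feature vectors."""

    group_key: tuple
    items: list[tuple[Clause, FeatureVector]]

    def __post_init__(self) -> None:
        starts = [c.start for c, _ in self.items]
        if starts != sorted(starts):
            raise ValueError("clauses within a sequence must be in text order")

    def without_none(self) -> "ClauseSequence":
        kept = [(c, v) for c, v in self.items
                if not c.is_heading and c.gold_label != "none"]
        return ClauseSequence(self.group_key, kept)

    def __len__(self) -> int:
        return len(self.items)


def make_sequences(clauses: Sequence[Clause], document: Document,
                   vectors: Sequence[FeatureVector]) -> list[ClauseSequence]:
    """Group clauses into per-paragraph sequences, dropping 'none' clauses.

    Paragraphs are blank-line-delimited blocks of the document text; each
    clause joins the paragraph containing its start offset.
    """
    if len(clauses) != len(vectors):
        raise ValueError("one feature vector per clause required")
    boundaries = _paragraph_starts(document.text)
    grouped: dict[tuple, list[tuple[Clause, FeatureVector]]] = {}
    for clause, vec in zip(clauses, vectors):
        para = int(np.searchsorted(boundaries, clause.start, side="right") - 1)
        grouped.setdefault((document.doc_id, para), []).append((clause, vec))
    sequences = []
    for key in sorted(grouped):
        seq = ClauseSequence(key, grouped[key]).without_none()
        if len(seq):
            sequences.append(seq)
    return sequences


def _paragraph_starts(text: str) -> np.ndarray:
    starts = [0]
    pos = 0
    while True:
        i = text.find("\n\n", pos)
        if i < 0:
            break
        starts.append(i + 2)
        pos = i + 2
    return np.asarray(starts)


@dataclass
class TrainConfig:
    seed: int = 0
    svm_c: float = 1.0
    crf_l2: float = 0.05
    max_iter: int = 300
    balanced: bool = False  # inverse-frequency class weights for the SVM


@dataclass
class DiscourseModel:
    kind: str  # "svm-ova" | "crf"
    labels: tuple[str, ...]
    vocabulary: dict[str, int]
    params: dict[str, np.ndarray]
    schema_version: str
    metadata: dict = field(default_factory=dict)


def _check_training_labels(sequences: Sequence[ClauseSequence]) -> None:
    seen = {c.gold_label for s in sequences for c, _ in s.items if c.gold_label}
    seen &= set(LABEL_ORDER)
    if len(seen) < 2:
        missing = [l for l in LABEL_ORDER if l not in seen]
        raise ValueError(
            f"training data covers {sorted(seen)} only; at least two of the seven "
            f"labels are required (missing: {missing})"
        )


def _vectorize(sequences: Sequence[ClauseSequence],
               vocabulary: dict[str, int] | None = None):
    """Stack feature vectors into one CSR matrix; build vocab if not given."""
    if not sequences or not any(len(s) for s in sequences):
        raise ValueError("no clauses to vectorize")
    schema = {v.schema_version for s in sequences for _, v in s.items}
    if len(schema) > 1:
        raise SchemaMismatchError(f"mixed feature schema versions: {sorted(schema)}")
    if vocabulary is None:
        names = sorted({name for s in sequences for _, v in s.items for name in v.features})
        vocabulary = {name: i for i, name in enumerate(names)}
    rows, cols, vals = [], [], []
    r = 0
    lengths = []
    for seq in sequences:
        for _, vec in seq.items:
            for name, value in vec.features.items():
                j = vocabulary.get(name)
                if j is not None:
                    rows.append(r)
                    cols.append(j)
                    vals.append(value)
            r += 1
        lengths.append(len(seq))
    X = sparse.csr_matrix((vals, (rows, cols)), shape=(r, len(vocabulary)))
    return X, lengths, vocabulary, schema.pop()


def _gold_indices(sequences: Sequence[ClauseSequence]) -> np.ndarray:
    y = []
    for seq in sequences:
        for clause, _ in seq.items:
            if clause.gold_label not in _LABEL_INDEX:
                raise ValueError(f"clause without a usable gold label: {clause.text[:40]!r}")
            y.append(_LABEL_INDEX[clause.gold_label])
    return np.asarray(y, dtype=np.intp)


def train_svm(sequences: Sequence[ClauseSequence],
              config: TrainConfig | None = None) -> DiscourseModel:
    """Train the seven-way one-vs-all linear SVM baseline."""
    config = config or TrainConfig()
    _check_training_labels(sequences)
    X, _, vocab, schema = _vectorize(sequences)
    y = _gold_indices(sequences)
    present = sorted(set(y.tolist()))
    clf = LinearSVC(
        C=config.svm_c,
        class_weight="balanced" if config.balanced else None,
        random_state=config.seed,
        max_iter=5000,
    )
    clf.fit(X, y)
    # expand margins to the full seven-label space (absent labels -> -inf)
    coef = np.full((len(LABEL_ORDER), X.shape[1]), 0.0)
    intercept = np.full(len(LABEL_ORDER), -np.inf)
    if len(present) == 2:  # sklearn collapses binary problems to one margin
        neg, pos = present
        coef[pos], intercept[pos] = clf.coef_[0], clf.intercept_[0]
        coef[neg], intercept[neg] = -clf.coef_[0], -clf.intercept_[0]
    else:
        for row, label_idx in enumerate(clf.classes_):
            coef[label_idx] = clf.coef_[row]
            intercept[label_idx] = clf.intercept_[row]
    return DiscourseModel(
        kind="svm-ova",
        labels=LABEL_ORDER,
        vocabulary=vocab,
        params={"coef": coef, "intercept": intercept},
        schema_version=schema,
        metadata={"seed": config.seed, "svm_c": config.svm_c,
                  "balanced": config.balanced},
    )


def train_crf(sequences: Sequence[ClauseSequence],
              config: TrainConfig | None = None) -> DiscourseModel:
    """Train the linear-chain CRF sequence labeler (paragraph = one chain)."""
    config = config or TrainConfig()
    _check_training_labels(sequences)
    X, lengths, vocab, schema = _vectorize(sequences)
    y = _gold_indices(sequences)
    crf = LinearChainCRF(len(LABEL_ORDER), X.shape[1],
                         l2=config.crf_l2, max_iter=config.max_iter)
    crf.fit(X, y, lengths)
    return DiscourseModel(
        kind="crf",
        labels=LABEL_ORDER,
        vocabulary=vocab,
        params={"W": crf.W, "T": crf.T, "start": crf.start, "end": crf.end},
        schema_version=schema,
        metadata={"seed": config.seed, "crf_l2": config.crf_l2,
                  "max_iter": config.max_iter},
    )


def predict(model: DiscourseModel,
            sequences: Sequence[ClauseSequence]) -> list[list[str]]:
    """Label every clause of every sequence with one of the seven types."""
    X, lengths, _, schema = _vectorize(sequences, model.vocabulary)
    if schema != model.schema_version:
        raise SchemaMismatchError(
            f"model was trained on feature schema {model.schema_version!r} "
            f"but vectors carry {schema!r}"
        )
    if model.kind == "svm-ova":
        margins = np.asarray(X @ model.params["coef"].T) + model.params["intercept"]
        flat = np.argmax(margins, axis=1)  # first max -> fixed label-order tie-break
    elif model.kind == "crf":
        crf = LinearChainCRF(len(model.labels), len(model.vocabulary))
        crf.W = model.params["W"]
        crf.T = model.params["T"]
        crf.start = model.params["start"]
        crf.end = model.params["end"]
        flat = np.concatenate(crf.decode(X, lengths))
    else:
        raise ValueError(f"unknown model kind {model.kind!r}")
    out = []
    pos = 0
    for ln in lengths:
        out.append([model.labels[i] for i in flat[pos: pos + ln]])
        pos += ln
    return out


def gold_pairs(model_labels: Sequence[str], sequences: Sequence[ClauseSequence],
               predictions: Sequence[Sequence[str]]) -> list[tuple[str, str]]:
    """Flatten (gold, predicted) pairs for evaluation."""
    pairs = []
    for seq, preds in zip(sequences, predictions):
        for (clause, _), pred in zip(seq.items, preds):
            pairs.append((clause.gold_label, pred))
    return pairs


# ---------------------------------------------------------------------------
# persistence: a single-file zip archive (metadata JSON + npz parameters)
# ---------------------------------------------------------------------------

def save_model(model: DiscourseModel, path: str) -> None:
    meta = {
        "kind": model.kind,
        "labels": list(model.labels),
        "schema_version": model.schema_version,
        "metadata": model.metadata,
        "vocabulary": sorted(model.vocabulary, key=model.vocabulary.get),
    }
    buf = io.BytesIO()
    np.savez(buf, **model.params)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("meta.json", json.dumps(meta))
        zf.writestr("params.npz", buf.getvalue())


def load_model(path: str) -> DiscourseModel:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        with np.load(io.BytesIO(zf.read("params.npz"))) as npz:
            params = {k: npz[k] for k in npz.files}
    if meta["schema_version"] != SCHEMA_VERSION:
        raise SchemaMismatchError(
            f"model feature schema {meta['schema_version']!r} does not match "
            f"this package's schema {SCHEMA_VERSION!r}"
        )
    return DiscourseModel(
        kind=meta["kind"],
        labels=tuple(meta["labels"]),
        vocabulary={name: i for i, name in enumerate(meta["vocabulary"])},
        params=params,
        schema_version=meta["schema_version"],
        metadata=meta["metadata"],
    )
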
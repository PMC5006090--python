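"""tf·idf term-based classification of experiment type from passage text.

The classifier is nearest-centroid over tf·idf vectors: passages are
tokenized (lowercase alphanumeric tokens, English stopwords removed),
weighted with natural term frequency and smoothed inverse document
frequency ``idf = ln((1+N)/(1+df)) + 1``, L2-normalized, and each
experiment-type code gets the mean vector of its training passages as a
centroid.  A passage is classified to the centroid of highest cosine
similarity; ties break by code string order.  A variant that votes over
the top-m most discriminative terms per class is available through
``FitConfig.mode = "terms"``.

:func:`cross_validate` runs seeded stratified k-fold cross-validation and
pools the out-of-fold predictions into a single confusion matrix, from
which mean accuracy and weighted F1 are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer

from .evaluation import ConfusionMatrix, EvalReport, matrix_from_predictions, report_from_matrix
from .linking import ExperimentPassage

logger = logging.getLogger(__name__)

TOKEN_PATTERN = r"(?u)\b[a-z0-9][a-z0-9]+\b"


@dataclass
class FitConfig:
    mode: str = "centroid"  # "centroid" | "terms"
    top_m_terms: int = 20   # only used by the term-voting variant
    min_df: int = 1


@dataclass
class CvConfig:
    k: int = 5
    seed: int = 0
    fit: FitConfig = field(default_factory=FitConfig)


@dataclass
class TfidfModel:
    vectorizer: TfidfVectorizer
    codes: tuple[str, ...]          # sorted; index order for centroids
    centroids: np.ndarray           # (C, V), L2-normalized
    class_terms: list[list[str]]    # top-m discriminative terms per class
    most_frequent: str
    mode: str

    @property
    def vocabulary(self) -> dict[str, int]:
        return self.vectorizer.vocabulary_

    @property
    def idf(self) -> np.ndarray:
        return self.vectorizer.idf_


def _single_code(p: ExperimentPassage) -> str:
    if len(p.type_codes) != 1:
        raise ValueError("every training passage must carry exactly one gold code")
    return p.type_codes[0]


def fit_tfidf(passages: Sequence[ExperimentPassage],
              config: FitConfig | None = None) -> TfidfModel:
    """Fit the term-based classifier on single-code passages."""
    config = config or FitConfig()
    if not passages:
        raise ValueError("no passages to fit on")
    y = [_single_code(p) for p in passages]
    codes = tuple(sorted(set(y)))
    if len(codes) < 2:
        raise ValueError(f"at least two classes required; got {codes}")
    vectorizer = TfidfVectorizer(
        lowercase=True,
        token_pattern=TOKEN_PATTERN,
        stop_words="english",
        norm="l2",
        smooth_idf=True,      # idf = ln((1+N)/(1+df)) + 1
        sublinear_tf=False,   # natural tf
        min_df=config.min_df,
    )
    X = vectorizer.fit_transform([p.text for p in passages])
    code_index = {c: i for i, c in enumerate(codes)}
    centroids = np.zeros((len(codes), X.shape[1]))
    for i, code in enumerate(codes):
        rows = [j for j, label in enumerate(y) if label == code]
        centroids[i] = np.asarray(X[rows].mean(axis=0)).ravel()
    norms = np.linalg.norm(centroids, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    centroids = centroids / norms
    terms = np.array(vectorizer.get_feature_names_out())
    class_terms = []
    for i in range(len(codes)):
        rest = centroids[[j for j in range(len(codes)) if j != i]].mean(axis=0)
        score = centroids[i] - rest
        top = np.argsort(-score, kind="stable")[: config.top_m_terms]
        class_terms.append([terms[t] for t in top if score[t] > 0] or [terms[int(np.argmax(centroids[i]))]])
    counts = {c: y.count(c) for c in codes}
    most_frequent = sorted(codes, key=lambda c: (-counts[c], c))[0]
    return TfidfModel(vectorizer, codes, centroids, class_terms, most_frequent,
                      config.mode)


def classify(model: TfidfModel, text: str) -> tuple[str, bool]:
    """Classify one passage; returns (code, flagged).

    ``flagged`` is True when the passage had no in-vocabulary tokens and the
    most frequent training class was returned as a fallback.
    """
    codes, flags = classify_many(model, [text])
    return codes[0], flags[0]


def classify_many(model: TfidfModel, texts: Sequence[str]) -> tuple[list[str], list[bool]]:
    X = model.vectorizer.transform(texts)
    empty = np.asarray((X != 0).sum(axis=1)).ravel() == 0
    if model.mode == "centroid":
        sims = np.asarray(X @ model.centroids.T)  # cosine: both sides L2-normalized
    elif model.mode == "terms":
        vocab = model.vocabulary
        votes = np.zeros((X.shape[0], len(model.codes)))
        Xb = (X != 0).astype(float)
        for i, terms in enumerate(model.class_terms):
            cols = [vocab[t] for t in terms if t in vocab]
            if cols:
                votes[:, i] = np.asarray(Xb[:, cols].sum(axis=1)).ravel()
        sims = votes
    else:
        raise ValueError(f"unknown classifier mode {model.mode!r}")
    best = np.argmax(sims, axis=1)  # first max -> code-string-order tie-break
    out, flagged = [], []
    for i, is_empty in enumerate(empty):
        if is_empty:
            out.append(model.most_frequent)
            flagged.append(True)
        else:
            out.append(model.codes[best[i]])
            flagged.append(False)
    return out, flagged


def _fold_assignment(y: Sequence[str], k: int, seed: int) -> np.ndarray:
    """Stratified fold ids: per-class shuffle, then cyclic assignment.

    Classes with fewer than k members inevitably miss some folds; this is
    logged and otherwise handled by the same cyclic rule.
    """
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    labels = sorted(set(y))
    offset = 0
    for label in labels:
        idx = np.asarray([i for i, v in enumerate(y) if v == label])
        if len(idx) < k:
            logger.warning("class %r has %d < k=%d members; folds will be uneven",
                           label, len(idx), k)
        rng.shuffle(idx)
        folds[idx] = (np.arange(len(idx)) + offset) % k
        offset += len(idx)
    return folds


@dataclass
class CvResult:
    report: EvalReport
    matrix: ConfusionMatrix
    predictions: list[str]
    flagged: list[bool]
    mean_accuracy: float


def cross_validate(passages: Sequence[ExperimentPassage],
                   config: CvConfig | None = None) -> CvResult:
    """Seeded stratified k-fold CV with pooled out-of-fold predictions."""
    config = config or CvConfig()
    k = config.k
    if len(passages) < k:
        raise ValueError(f"need at least k={k} passages, got {len(passages)}")
    y = [_single_code(p) for p in passages]
    if len(set(y)) < 2:
        raise ValueError("at least two classes required")
    folds = _fold_assignment(y, k, config.seed)
    predictions: list[str | None] = [None] * len(passages)
    flagged = [False] * len(passages)
    fold_acc = []
    for fold in range(k):
        train = [p for p, f in zip(passages, folds) if f != fold]
        test_idx = [i for i, f in enumerate(folds) if f == fold]
        if not test_idx:
            continue
        model = fit_tfidf(train, config.fit)
        codes, flags = classify_many(model, [passages[i].text for i in test_idx])
        correct = 0
        for i, code, fl in zip(test_idx, codes, flags):
            predictions[i] = code
            flagged[i] = fl
            correct += code == y[i]
        fold_acc.append(correct / len(test_idx))
    pairs = list(zip(y, predictions))
    label_order = sorted(set(y) | set(predictions))
    matrix = matrix_from_predictions(pairs, label_order)
    return CvResult(
        report=report_from_matrix(matrix),
        matrix=matrix,
        predictions=list(predictions),
        flagged=flagged,
        mean_accuracy=float(np.mean(fold_acc)),
    )
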
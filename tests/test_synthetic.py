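"""Synthetic corpus generators: determinism, priors, dials."""

from collections import Counter

import numpy as np
import pytest

from conftest import corpus_sequences
from scidisc import (
    CorpusSpec,
    ExpCorpusSpec,
    generate_discourse_corpus,
    generate_exptype_corpus,
    most_frequent_baseline,
    segment_document,
)
from scidisc import discourse as dm
from scidisc import evaluation as ev
from scidisc import exptype
from scidisc.features import default_lexicon, extract_features


def test_discourse_generator_is_seed_deterministic():
    a = generate_discourse_corpus(CorpusSpec(seed=5, n_documents=3))
    b = generate_discourse_corpus(CorpusSpec(seed=5, n_documents=3))
    assert [d.document.text for d in a] == [d.document.text for d in b]
    assert [c.gold_label for d in a for c in d.clauses] == \
        [c.gold_label for d in b for c in d.clauses]
    c = generate_discourse_corpus(CorpusSpec(seed=6, n_documents=3))
    assert [d.document.text for d in a] != [d.document.text for d in c]


def test_full_cue_dropout_leaves_no_cue_features():
    lexicon = default_lexicon()
    docs = generate_discourse_corpus(CorpusSpec(seed=2, n_documents=3, cue_dropout=1.0))
    for labeled in docs:
        for clause in labeled.clauses:
            vec = extract_features(clause, labeled.document, lexicon=lexicon)
            assert not any(k.startswith("cue:") for k in vec.features)


def test_label_frequencies_track_reference_priors():
    """~3600 clauses drawn at the reference class priors land within 2%."""
    spec = CorpusSpec(seed=1, n_documents=45)
    clauses = [c for d in generate_discourse_corpus(spec) for c in d.clauses
               if c.gold_label != "none"]
    assert len(clauses) > 3000
    freq = Counter(c.gold_label for c in clauses)
    total = sum(freq.values())
    for label, prior in spec.label_priors.items():
        assert abs(freq[label] / total - prior) < 0.02


def test_generated_clauses_match_segmenter_output():
    for labeled in generate_discourse_corpus(CorpusSpec(seed=3, n_documents=2)):
        segmented = segment_document(labeled.document)
        assert [(c.start, c.end) for c in segmented] == \
            [(c.start, c.end) for c in labeled.clauses]


def test_result_clauses_carry_figure_references():
    docs = generate_discourse_corpus(CorpusSpec(seed=4, n_documents=4))
    hits = total = 0
    for labeled in docs:
        for clause in labeled.clauses:
            if clause.gold_label == "result":
                total += 1
                hits += any(clause.start <= r.start < clause.end
                            for r in labeled.document.figure_refs)
    assert total > 50 and 0.4 < hits / total < 0.8  # rate parameter 0.6


def test_invalid_transition_matrix_rejected():
    bad = np.full((7, 8), 0.2)
    with pytest.raises(ValueError, match="sum to 1"):
        CorpusSpec(transition=bad, start=np.full(7, 1 / 7))


def test_exptype_generator_deterministic_and_single_code():
    a = generate_exptype_corpus(ExpCorpusSpec(seed=8, n_passages=60))
    b = generate_exptype_corpus(ExpCorpusSpec(seed=8, n_passages=60))
    assert [p.text for p in a] == [p.text for p in b]
    assert all(len(p.type_codes) == 1 for p in a)


def test_exptype_realized_supports_match_reference_baseline():
    passages = generate_exptype_corpus(ExpCorpusSpec(seed=1))
    supports = Counter(p.type_codes[0] for p in passages)
    assert sum(supports.values()) == 581
    assert abs(most_frequent_baseline(list(supports.values())) - 0.42) < 0.02


def test_zero_bleed_classes_are_lexically_disjoint():
    spec = ExpCorpusSpec(term_bleed=0.0, seed=2, n_passages=100, filler_terms=0)
    passages = generate_exptype_corpus(spec)
    class_tokens = {}
    for p in passages:
        class_tokens.setdefault(p.type_codes[0], set()).update(p.text.lower().split())
    codes = sorted(class_tokens)
    for i, a in enumerate(codes):
        for b in codes[i + 1:]:
            shared = class_tokens[a] & class_tokens[b]
            assert not {t for t in shared if t.isalpha() and len(t) > 2}


def test_more_term_bleed_never_helps_tfidf():
    means = []
    for bleed in (0.1, 0.5, 0.9):
        scores = []
        for seed in range(1, 6):
            ps = generate_exptype_corpus(
                ExpCorpusSpec(term_bleed=bleed, seed=seed, n_passages=200))
            scores.append(
                exptype.cross_validate(ps, exptype.CvConfig(seed=seed)).report.weighted_f1)
        means.append(float(np.mean(scores)))
    assert means[0] >= means[1] >= means[2]


def test_more_cue_dropout_never_helps_the_crf():
    """Statistical monotonicity, tested at the extreme settings (all cues
    present vs all cues dropped) where the effect exceeds seed noise."""
    means = []
    for dropout in (0.0, 1.0):
        scores = []
        for seed in range(1, 6):
            seqs = corpus_sequences(seed, n_documents=10, cue_dropout=dropout)
            cut = int(len(seqs) * 0.8)
            model = dm.train_crf(seqs[:cut], dm.TrainConfig(seed=seed))
            preds = dm.predict(model, seqs[cut:])
            pairs = dm.gold_pairs(model.labels, seqs[cut:], preds)
            matrix = ev.matrix_from_predictions(pairs, dm.LABEL_ORDER)
            scores.append(ev.report_from_matrix(matrix).weighted_f1)
        means.append(float(np.mean(scores)))
    assert means[0] >= means[1]
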
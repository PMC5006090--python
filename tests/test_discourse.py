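"""Discourse labelers: training contracts, determinism, ordering effects."""

import numpy as np
import pytest

from conftest import corpus_sequences
from scidisc import discourse as dm
from scidisc import evaluation as ev
from scidisc.features import FeatureVector
from scidisc.segment import Clause


def _seq(labels, texts=None, doc_id="d"):
    items = []
    for i, label in enumerate(labels):
        c = Clause(doc_id, 0, i, 0, i * 10, i * 10 + 5, (texts or labels)[i],
                   gold_label=label)
        items.append((c, FeatureVector({f"lex:{(texts or labels)[i]}": 1.0})))
    return dm.ClauseSequence((doc_id, 0), items)


def _wf1(sequences, model):
    preds = dm.predict(model, sequences)
    pairs = dm.gold_pairs(model.labels, sequences, preds)
    matrix = ev.matrix_from_predictions(pairs, dm.LABEL_ORDER)
    return ev.report_from_matrix(matrix).weighted_f1, matrix


def test_single_label_training_set_rejected():
    seqs = [_seq(["result", "result"])]
    with pytest.raises(ValueError, match="missing"):
        dm.train_svm(seqs)
    with pytest.raises(ValueError, match="missing"):
        dm.train_crf(seqs)


def test_empty_sequence_list_rejected():
    with pytest.raises(ValueError):
        dm.train_crf([])


def test_predictions_cover_only_the_seven_labels(small_sequences):
    model = dm.train_svm(small_sequences[:40], dm.TrainConfig(seed=0))
    preds = dm.predict(model, small_sequences[40:60])
    flat = {p for seq in preds for p in seq}
    assert flat <= set(dm.LABEL_ORDER)
    assert "none" not in flat


def test_same_seed_gives_identical_predictions(small_sequences):
    train, test = small_sequences[:40], small_sequences[40:60]
    for trainer in (dm.train_svm, dm.train_crf):
        m1 = trainer(train, dm.TrainConfig(seed=9))
        m2 = trainer(train, dm.TrainConfig(seed=9))
        assert dm.predict(m1, test) == dm.predict(m2, test)


def test_single_clause_sequence_predicts(small_sequences):
    model = dm.train_crf(small_sequences[:30], dm.TrainConfig(seed=1))
    single = dm.ClauseSequence(("d", 0), small_sequences[30].items[:1])
    (preds,) = dm.predict(model, [single])
    assert len(preds) == 1 and preds[0] in dm.LABEL_ORDER


def test_schema_mismatch_refused(small_sequences):
    model = dm.train_svm(small_sequences[:20], dm.TrainConfig(seed=0))
    clause, vec = small_sequences[20].items[0]
    stale = dm.ClauseSequence(("d", 0), [(clause, FeatureVector(vec.features, "0"))])
    with pytest.raises(dm.SchemaMismatchError):
        dm.predict(model, [stale])


def test_model_persistence_round_trip(tmp_path, small_sequences):
    test = small_sequences[40:50]
    for trainer in (dm.train_svm, dm.train_crf):
        model = trainer(small_sequences[:40], dm.TrainConfig(seed=2))
        path = tmp_path / f"{model.kind}.zip"
        dm.save_model(model, str(path))
        loaded = dm.load_model(str(path))
        assert dm.predict(loaded, test) == dm.predict(model, test)


def test_training_f1_beats_most_frequent_baseline(small_sequences):
    train = small_sequences[:40]  # ~300 clauses
    for trainer in (dm.train_svm, dm.train_crf):
        model = trainer(train, dm.TrainConfig(seed=1))
        f1, matrix = _wf1(train, model)
        assert f1 > ev.most_frequent_baseline(matrix.supports)


def test_cue_and_figure_context_yields_result_label(small_sequences):
    """A clause carrying the 'data not shown' cue and a figure link, flanked
    by method clauses, comes out 'result' under default-corpus models."""
    from scidisc import doc_model as docm
    from scidisc.features import default_lexicon, extract_features

    texts = [
        "Extracts were subjected to immunoprecipitation with an antibody against RAF1 .",
        "Binding was abolished ( data not shown ) ( Fig. 2A ) .",
        "Cells expressing MEK1 were lysed before blotting for ERK2 .",
    ]
    text = " ".join(texts)
    doc = docm.annotate(
        docm.Document("d", text, [docm.Section("results", 0, len(text))]))
    lexicon = default_lexicon()
    items, pos = [], 0
    for i, t in enumerate(texts):
        start = text.find(t, pos)
        pos = start + len(t)
        clause = Clause("d", 0, i, 0, start, pos, t.strip(), gold_label="method")
        items.append((clause, extract_features(clause, doc, lexicon=lexicon)))
    middle = items[1][1].features
    assert "cue:data_not_shown" in middle and "link:figure" in middle
    sequence = dm.ClauseSequence(("d", 0), items)
    for trainer in (dm.train_svm, dm.train_crf):
        model = trainer(small_sequences, dm.TrainConfig(seed=1))
        (preds,) = dm.predict(model, [sequence])
        assert preds[1] == "result"


def test_iid_labels_remove_the_crf_advantage():
    """With labels assigned i.i.d. (uniform rows), CRF and SVM differ < 0.05."""
    labels = dm.LABEL_ORDER
    uniform = np.full((7, 8), 1 / 7)
    uniform[:, 7] = 0.0
    # keep paragraphs finite: renormalize with an end probability of 1/8
    uniform = np.hstack([np.full((7, 7), (7 / 8) / 7), np.full((7, 1), 1 / 8)])
    start = np.full(7, 1 / 7)
    gaps = []
    for seed in range(1, 6):
        seqs = corpus_sequences(seed, n_documents=6, transition=uniform, start=start)
        cut = int(len(seqs) * 0.8)
        train, test = seqs[:cut], seqs[cut:]
        crf_f1, _ = _wf1(test, dm.train_crf(train, dm.TrainConfig(seed=seed)))
        svm_f1, _ = _wf1(test, dm.train_svm(train, dm.TrainConfig(seed=seed)))
        gaps.append(crf_f1 - svm_f1)
    assert abs(float(np.mean(gaps))) < 0.05
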
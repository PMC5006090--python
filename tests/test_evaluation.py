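"""Confusion-matrix algebra and metric definitions."""

import io
from collections import Counter

import numpy as np
import pytest

from scidisc import evaluation as ev


def _per_item_report(pairs, labels):
    """Brute-force oracle: metrics computed directly from item pairs."""
    gold = Counter(g for g, _ in pairs)
    pred = Counter(p for _, p in pairs)
    correct = Counter(g for g, p in pairs if g == p)
    out = {}
    for label in labels:
        precision = correct[label] / pred[label] if pred[label] else 0.0
        recall = correct[label] / gold[label] if gold[label] else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        out[label] = (precision, recall, f1)
    total = len(pairs)
    weighted = sum(gold[l] * out[l][2] for l in labels) / total if total else 0.0
    return out, weighted


def test_identity_matrix_is_perfect():
    m = ev.ConfusionMatrix(("a", "b", "c"), np.eye(3, dtype=int) * 5)
    report = ev.report_from_matrix(m)
    assert all(s.precision == s.recall == s.f1 == 1.0 for s in report.per_label)
    assert report.weighted_f1 == 1.0


def test_report_matches_per_item_oracle_on_random_matrices():
    rng = np.random.default_rng(42)
    labels = ("a", "b", "c", "d")
    for _ in range(25):
        counts = rng.integers(0, 9, size=(4, 4))
        pairs = [
            (labels[i], labels[j])
            for i in range(4) for j in range(4)
            for _ in range(counts[i, j])
        ]
        report = ev.report_from_matrix(ev.ConfusionMatrix(labels, counts))
        oracle, weighted = _per_item_report(pairs, labels)
        for s in report.per_label:
            assert (s.precision, s.recall, s.f1) == pytest.approx(oracle[s.label])
        assert report.weighted_f1 == pytest.approx(weighted)


def test_weighted_f1_invariant_under_label_permutation():
    rng = np.random.default_rng(7)
    counts = rng.integers(0, 20, size=(5, 5))
    labels = tuple("abcde")
    base = ev.report_from_matrix(ev.ConfusionMatrix(labels, counts)).weighted_f1
    perm = rng.permutation(5)
    permuted = ev.ConfusionMatrix(
        tuple(labels[i] for i in perm), counts[np.ix_(perm, perm)]
    )
    assert ev.report_from_matrix(permuted).weighted_f1 == pytest.approx(base)


def test_matrix_from_predictions_counting_oracle():
    rng = np.random.default_rng(3)
    labels = ("x", "y", "z")
    pairs = [(labels[rng.integers(3)], labels[rng.integers(3)]) for _ in range(1000)]
    m = ev.matrix_from_predictions(pairs, labels)
    gold_counts = Counter(g for g, _ in pairs)
    assert [int(s) for s in m.supports] == [gold_counts[l] for l in labels]
    assert m.total == 1000


def test_matrix_from_predictions_edge_cases():
    m = ev.matrix_from_predictions([], ("a", "b"))
    assert m.counts.sum() == 0
    m = ev.matrix_from_predictions([("a", "a")], ("a", "b"))
    assert m.counts.tolist() == [[1, 0], [0, 0]]
    with pytest.raises(ValueError, match="unknown"):
        ev.matrix_from_predictions([("a", "q")], ("a", "b"))


def test_invalid_matrices_rejected():
    with pytest.raises(ValueError, match="square"):
        ev.ConfusionMatrix(("a",), np.zeros((1, 2)))
    with pytest.raises(ValueError, match="non-negative"):
        ev.ConfusionMatrix(("a", "b"), np.array([[1, -1], [0, 0]]))


def test_most_frequent_baseline_closed_form_cases():
    assert ev.most_frequent_baseline([10]) == pytest.approx(1.0)
    assert ev.most_frequent_baseline([5, 5]) == pytest.approx(1 / 3)
    with pytest.raises(ValueError):
        ev.most_frequent_baseline([0, 0])


def test_baseline_equals_constant_predictor_construction():
    rng = np.random.default_rng(11)
    for _ in range(25):
        k = int(rng.integers(2, 7))
        supports = rng.integers(0, 50, size=k)
        if supports.sum() == 0:
            supports[0] = 1
        j = int(np.argmax(supports))
        counts = np.zeros((k, k), dtype=int)
        counts[:, j] = supports
        labels = tuple(f"l{i}" for i in range(k))
        constructed = ev.report_from_matrix(ev.ConfusionMatrix(labels, counts))
        assert ev.most_frequent_baseline(supports) == pytest.approx(constructed.weighted_f1)


def test_zero_denominator_convention():
    # a class never predicted and a class never occurring both score 0
    counts = np.array([[0, 2], [0, 3]])
    report = ev.report_from_matrix(ev.ConfusionMatrix(("a", "b"), counts))
    a = report.stats("a")
    assert (a.precision, a.recall, a.f1) == (0.0, 0.0, 0.0)


def test_half_up_rounding_at_presentation():
    assert ev.round2(0.625) == 0.63
    assert ev.round2(0.464) == 0.46


def test_matrix_tsv_round_trip():
    m = ev.ConfusionMatrix(("a", "b"), np.array([[3, 1], [0, 2]]))
    buf = io.StringIO()
    m.to_tsv(buf)
    back = ev.ConfusionMatrix.from_tsv(io.StringIO(buf.getvalue()))
    assert back.labels == m.labels and (back.counts == m.counts).all()
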
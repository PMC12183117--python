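"""CAFA metrics against brute-force oracles."""

import numpy as np
import pytest

from gopredict.containers import ScoreMatrix
from gopredict.errors import ValidationError
from gopredict.evaluation import aupr, evaluate, fmax, fmax_arrays, naive_baseline
from gopredict.ontology import AnnotationSet

from conftest import truth_from_matrix


def brute_force_fmax(s: np.ndarray, y: np.ndarray, step: float = 0.01):
    """Materialize predictions at every grid threshold with python sets."""
    n, _ = s.shape
    true_sets = [set(np.flatnonzero(y[i])) for i in range(n)]
    best_f, best_t = 0.0, step
    grid = [round(step * k, 10) for k in range(1, int(round(1.0 / step)) + 1)]
    for t in grid:
        precisions, recalls = [], []
        for i in range(n):
            pred = set(np.flatnonzero(s[i] >= t))
            if pred:
                precisions.append(len(pred & true_sets[i]) / len(pred))
            recalls.append(len(pred & true_sets[i]) / len(true_sets[i]))
        pr = sum(precisions) / len(precisions) if precisions else 0.0
        rc = sum(recalls) / n
        f = 2 * pr * rc / (pr + rc) if precisions and (pr + rc) > 0 else 0.0
        if f > best_f:
            best_f, best_t = f, t
    return best_f, best_t


def brute_force_average_precision(scores: np.ndarray, labels: np.ndarray) -> float:
    """AP by enumerating thresholds at every distinct score value."""
    thresholds = sorted(set(scores), reverse=True)
    total_pos = int(labels.sum())
    ap, prev_recall = 0.0, 0.0
    for t in thresholds:
        pred = scores >= t
        tp = int((pred & (labels > 0)).sum())
        precision = tp / int(pred.sum())
        recall = tp / total_pos
        ap += precision * (recall - prev_recall)
        prev_recall = recall
    return ap


class TestFmax:
    def test_worked_example(self):
        # truth p1={t1,t2}, p2={t3}; best F at threshold 0.80 is 6/7
        m = ScoreMatrix(
            ["p1", "p2"], ["t1", "t2", "t3"],
            np.array([[0.9, 0.4, 0.5], [0.7, 0.0, 0.8]]),
        )
        truth = AnnotationSet({"p1": {"t1", "t2"}, "p2": {"t3"}}, "BP")
        res = fmax(m, truth)
        assert res.fmax == pytest.approx(6 / 7, abs=1e-12)
        # the optimum is attained on [0.71, 0.80]; the smallest attaining
        # threshold is reported, and t = 0.80 also attains it
        assert res.best_threshold == pytest.approx(0.71)
        row_80 = res.table[np.isclose(res.table[:, 0], 0.80)][0]
        _, pr, rc, _ = row_80
        assert 2 * pr * rc / (pr + rc) == pytest.approx(6 / 7, abs=1e-12)

    def test_perfect_predictor(self):
        rng = np.random.default_rng(0)
        y = rng.random((5, 6)) > 0.6
        y[y.sum(axis=1) == 0, 0] = True
        proteins = [f"p{i}" for i in range(5)]
        terms = [f"t{j}" for j in range(6)]
        m = ScoreMatrix(proteins, terms, y.astype(float))
        assert fmax(m, truth_from_matrix(y, proteins, terms)).fmax == 1.0

    def test_all_zero_scores(self):
        proteins, terms = ["p1"], ["t1", "t2"]
        m = ScoreMatrix(proteins, terms, np.zeros((1, 2)))
        truth = AnnotationSet({"p1": {"t1"}}, "BP")
        assert fmax(m, truth).fmax == 0.0

    def test_empty_truth_rejected(self):
        m = ScoreMatrix(["p1"], ["t1"], np.array([[0.5]]))
        with pytest.raises(ValidationError):
            fmax(m, AnnotationSet({}, "BP"))

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            n = int(rng.integers(2, 31))
            t = int(rng.integers(2, 41))
            s = np.round(rng.random((n, t)), 2)
            y = rng.random((n, t)) > 0.7
            y[y.sum(axis=1) == 0, 0] = True
            res = fmax_arrays(s, y)
            bf_f, bf_t = brute_force_fmax(s, y)
            assert res.fmax == pytest.approx(bf_f, abs=1e-12)
            assert res.best_threshold == pytest.approx(bf_t)

    def test_monotone_improvement(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            s = rng.random((6, 8))
            y = rng.random((6, 8)) > 0.6
            y[y.sum(axis=1) == 0, 0] = True
            base = fmax_arrays(s, y).fmax
            # raise one wrongly-zero true-term score to 1.0
            idx = np.argwhere(y & (s < 0.5))
            if idx.size == 0:
                continue
            i, j = idx[0]
            s2 = s.copy()
            s2[i, j] = 1.0
            assert fmax_arrays(s2, y).fmax >= base - 1e-12

    def test_scored_proteins_missing_from_truth_excluded(self):
        m = ScoreMatrix(
            ["p1", "extra"], ["t1"], np.array([[1.0], [1.0]])
        )
        truth = AnnotationSet({"p1": {"t1"}}, "BP")
        assert fmax(m, truth).fmax == 1.0


class TestAupr:
    def _instance(self, rng, n=10, t=5):
        s = rng.random((n, t))
        y = rng.random((n, t)) > 0.6
        y[:, y.sum(axis=0) == 0] = False  # leave possibly-empty columns
        y[0, 0] = True  # ensure at least one eligible term
        proteins = [f"p{i}" for i in range(n)]
        terms = [f"t{j}" for j in range(t)]
        return ScoreMatrix(proteins, terms, s), truth_from_matrix(y, proteins, terms), s, y

    def test_perfect_ranking_is_one(self):
        y = np.array([[True, False], [False, True], [True, True]])
        s = y.astype(float) * 0.9 + 0.05
        proteins, terms = ["a", "b", "c"], ["t1", "t2"]
        m = ScoreMatrix(proteins, terms, s)
        truth = truth_from_matrix(y, proteins, terms)
        assert aupr(m, truth) == pytest.approx(1.0)
        assert aupr(m, truth, mode="micro") == pytest.approx(1.0)

    def test_worst_first_single_positive(self):
        # 1 positive ranked last among 4 pairs -> AP = 0.25
        scores = np.array([0.9, 0.8, 0.7, 0.1])
        labels = np.array([0, 0, 0, 1])
        assert brute_force_average_precision(scores, labels) == pytest.approx(0.25)
        # every protein annotated somewhere (else it leaves the benchmark);
        # column "t" ranks its one positive worst
        s = np.column_stack([scores, np.full(4, 0.5)])
        y = np.column_stack([labels.astype(bool), np.array([1, 1, 1, 0], bool)])
        proteins = ["p1", "p2", "p3", "p4"]
        m = ScoreMatrix(proteins, ["t", "t2"], s)
        truth = truth_from_matrix(y, proteins, ["t", "t2"])
        ap_t2 = brute_force_average_precision(s[:, 1], y[:, 1])
        assert aupr(m, truth) == pytest.approx((0.25 + ap_t2) / 2, abs=1e-12)

    def test_matches_brute_force_both_modes(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            m, truth, s, y = self._instance(rng)
            keep = y.any(axis=1)
            s_kept, y_kept = s[keep], y[keep]
            eligible = np.flatnonzero(y_kept.any(axis=0))
            expected_macro = np.mean([
                brute_force_average_precision(s_kept[:, j], y_kept[:, j])
                for j in eligible
            ])
            assert aupr(m, truth) == pytest.approx(expected_macro, abs=1e-9)
            expected_micro = brute_force_average_precision(
                s_kept.ravel(), y_kept.ravel()
            )
            assert aupr(m, truth, mode="micro") == pytest.approx(
                expected_micro, abs=1e-9
            )

    def test_no_eligible_term_rejected(self):
        m = ScoreMatrix(["p1"], ["t1"], np.array([[0.5]]))
        truth = AnnotationSet({"p1": {"t_other"}}, "BP")
        with pytest.raises(ValidationError):
            aupr(m, truth)


class TestNaiveBaseline:
    def test_direct_counting_example(self):
        train = AnnotationSet({"p1": {"A"}, "p2": {"A", "B"}}, "BP")
        m = naive_baseline(train, ["x", "y"])
        frame = m.to_frame()
        assert frame.loc["x", "A"] == 1.0
        assert frame.loc["x", "B"] == 0.5
        np.testing.assert_array_equal(frame.loc["x"], frame.loc["y"])

    def test_unseen_term_column_absent(self):
        train = AnnotationSet({"p1": {"A"}}, "BP")
        m = naive_baseline(train, ["x"])
        assert m.terms == ["A"]

    def test_all_rows_identical_on_random_inputs(self):
        rng = np.random.default_rng(4)
        terms = [f"t{j}" for j in range(6)]
        annots = {
            f"p{i}": {terms[int(j)] for j in rng.choice(6, size=2, replace=False)}
            for i in range(10)
        }
        m = naive_baseline(AnnotationSet(annots, "BP"), ["a", "b", "c"])
        assert (m.values == m.values[0]).all()

    def test_empty_training_rejected(self):
        with pytest.raises(ValidationError):
            naive_baseline(AnnotationSet({}, "BP"), ["x"])


def test_evaluate_combines_both_metrics():
    rng = np.random.default_rng(5)
    y = rng.random((6, 4)) > 0.5
    y[y.sum(axis=1) == 0, 0] = True
    proteins = [f"p{i}" for i in range(6)]
    terms = [f"t{j}" for j in range(4)]
    m = ScoreMatrix(proteins, terms, y.astype(float) * 0.8 + 0.1)
    res = evaluate(m, truth_from_matrix(y, proteins, terms))
    assert res.fmax == pytest.approx(1.0)
    assert res.aupr == pytest.approx(1.0)
    assert "Fmax" in res.summary()
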
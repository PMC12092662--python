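import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metach import (compute_aupr, compute_auroc, evaluate,
                    permutation_importance, subset_evaluate)
from metach.errors import EvaluationError, GroupingError

from conftest import make_record


# -- independent oracles ---------------------------------------------------

def brute_auroc(scores, labels):
    """Exhaustive pairwise comparison (ties worth one half)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_aupr(scores, labels):
    """Full precision-recall staircase over distinct thresholds."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    thresholds = sorted(set(scores), reverse=True)
    n_pos = labels.sum()
    ap, prev_tp = 0.0, 0
    for t in thresholds:
        called = scores >= t
        tp = int(labels[called].sum())
        precision = tp / called.sum()
        ap += (tp - prev_tp) * precision
        prev_tp = tp
    return ap / n_pos


def random_instance(rng, max_n=100, ties=False):
    n = int(rng.integers(4, max_n + 1))
    y = np.zeros(n, int)
    y[:int(rng.integers(1, n))] = 1
    rng.shuffle(y)
    if ties:
        s = rng.integers(0, 4, size=n) / 4.0
    else:
        s = rng.random(n)
    if y.sum() == 0 or y.sum() == n:
        y[0], y[-1] = 1, 0
    return s, y


class TestAgainstOracles:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(123)
        for i in range(200):
            s, y = random_instance(rng, ties=(i % 3 == 0))
            assert abs(compute_auroc(s, y) - brute_auroc(s, y)) < 1e-9
            assert abs(compute_aupr(s, y) - brute_aupr(s, y)) < 1e-9

    def test_agrees_with_sklearn_when_tie_free(self):
        from sklearn.metrics import average_precision_score, roc_auc_score

        rng = np.random.default_rng(5)
        for _ in range(20):
            s, y = random_instance(rng, ties=False)
            assert compute_auroc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)
            assert compute_aupr(s, y) == pytest.approx(
                average_precision_score(y, s), abs=1e-12)


class TestWorkedExamples:
    def test_perfect_ranking(self):
        assert compute_auroc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0
        assert compute_aupr([0.9, 0.1], [1, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert compute_auroc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_interleaved_ranking(self):
        assert compute_auroc([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0]) == 0.75

    def test_reversed_pair_average_precision(self):
        assert compute_aupr([0.9, 0.1], [0, 1]) == 0.5

    def test_null_scores_aupr_near_prevalence(self):
        rng = np.random.default_rng(11)
        n, prev = 10_000, 0.2
        y = (rng.random(n) < prev).astype(int)
        s = rng.random(n)
        assert abs(compute_aupr(s, y) - y.mean()) < 0.03

    def test_single_class_raises(self):
        with pytest.raises(EvaluationError):
            compute_auroc([0.1, 0.2], [1, 1])
        with pytest.raises(EvaluationError):
            compute_aupr([0.1, 0.2], [0, 0])


class TestInvariances:
    @given(st.lists(st.floats(min_value=-50, max_value=50, allow_nan=False),
                    min_size=4, max_size=60))
    @settings(deadline=None, max_examples=60)
    def test_auroc_invariant_under_monotone_transform(self, raw):
        rng = np.random.default_rng(len(raw))
        y = rng.integers(0, 2, size=len(raw))
        if y.sum() in (0, len(y)):
            y[0], y[-1] = 0, 1
        s = np.asarray(raw)
        a = compute_auroc(s, y)
        # doubling is exact in binary floats: strictly monotone, tie-preserving
        b = compute_auroc(2.0 * s, y)
        assert a == pytest.approx(b, abs=1e-12)

    def test_evaluate_report_carries_counts_and_curves(self):
        rep = evaluate([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0], subset_tag="demo")
        assert rep.n_pos == 2 and rep.n_neg == 2 and rep.subset_tag == "demo"
        assert rep.roc_points[0] == (0.0, 0.0) and rep.roc_points[-1] == (1.0, 1.0)


class _LinearScorer:
    """Deterministic stand-in model: score = first feature column."""

    def predict_proba(self, X):
        p = 1 / (1 + np.exp(-X[:, 0]))
        return np.column_stack([1 - p, p])


class TestPermutationImportance:
    def _data(self, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 4))
        y = (X[:, 0] + 0.1 * rng.standard_normal(n) > 0).astype(int)
        groups = {"signal": np.array([0]), "noise": np.array([1, 2, 3])}
        return X, y, groups

    def test_null_group_has_negligible_importance(self):
        X, y, groups = self._data()
        imp = permutation_importance(_LinearScorer(), X, y, groups,
                                     n_repeats=10, seed=1)
        assert abs(imp.loc["noise", "mean_drop"]) < 0.02

    def test_informative_group_drop_matches_null_degradation(self):
        """Permuting the only informative group degrades auPR to prevalence."""
        X, y, groups = self._data()
        imp = permutation_importance(_LinearScorer(), X, y, groups,
                                     n_repeats=10, seed=1)
        baseline = imp.attrs["baseline_aupr"]
        expected = baseline - y.mean()
        assert imp.loc["signal", "mean_drop"] == pytest.approx(expected, abs=0.05)

    def test_bit_reproducible_under_seed(self):
        X, y, groups = self._data(n=300)
        a = permutation_importance(_LinearScorer(), X, y, groups, n_repeats=5, seed=9)
        b = permutation_importance(_LinearScorer(), X, y, groups, n_repeats=5, seed=9)
        assert a.equals(b)

    def test_empty_group_raises(self):
        X, y, groups = self._data(n=100)
        groups["empty"] = np.array([], dtype=int)
        with pytest.raises(GroupingError):
            permutation_importance(_LinearScorer(), X, y, groups, n_repeats=2)


class TestSubsetEvaluate:
    def _cohort(self, seed=0):
        rng = np.random.default_rng(seed)
        recs, scores, labels = [], [], []
        for i in range(200):
            gene = "DNMT3A" if rng.random() < 0.3 else f"G{rng.integers(5)}"
            y = int(rng.random() < (0.8 if gene == "DNMT3A" else 0.3))
            recs.append(make_record(patient=f"P{i}", gene=gene, pos=100 + i))
            labels.append(y)
            scores.append(y * 0.5 + rng.random() * 0.5)
        return recs, np.array(scores), np.array(labels)

    def test_empty_predicate_outside_equals_full(self):
        recs, s, y = self._cohort()
        inside, outside = subset_evaluate(recs, s, y, set())
        assert not inside.computable
        assert outside.auroc == evaluate(s, y).auroc
        assert outside.aupr == evaluate(s, y).aupr

    def test_full_predicate_inside_equals_full(self):
        recs, s, y = self._cohort()
        genes = {r.gene for r in recs}
        inside, outside = subset_evaluate(recs, s, y, genes)
        assert not outside.computable
        assert inside.auroc == evaluate(s, y).auroc

    def test_matches_filter_then_score_oracle(self):
        recs, s, y = self._cohort(seed=3)
        inside, outside = subset_evaluate(recs, s, y, {"DNMT3A"})
        mask = np.array([r.gene == "DNMT3A" for r in recs])
        assert inside.auroc == compute_auroc(s[mask], y[mask])
        assert outside.auroc == compute_auroc(s[~mask], y[~mask])
        assert inside.n_pos == int(y[mask].sum())
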
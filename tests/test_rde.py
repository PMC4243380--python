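"""RDE scoring, reference selection, pruning, SuRDE, ensembles."""

import numpy as np
import pytest
from scipy import sparse

from goseed import cooc_stats as cs
from goseed import rde
from goseed.rde import (
    RDEConfig,
    RDEModel,
    build_rde,
    combine_mean,
    dependency_expectation,
    precision_indicator,
    prune,
    rescale_minmax,
    score_rde,
    select_references,
    train_ensemble,
    train_surde,
    transform,
    tune_threshold,
)

FOUR = [np.array([0, 2]), np.array([0]), np.array([2]), np.array([1])]


def oracle_score(stats, r, active, eps):
    """Naive re-enumeration of f(x, r)."""
    total = 0.0
    p_r = (stats.count_r(r) + eps) / (stats.n_examples + 2 * eps)
    for j in sorted(set(int(i) for i in active)):
        p_r_given_j = (stats.count_jr(j, r) + eps) / (stats.count_j(j) + 2 * eps)
        total += p_r_given_j - p_r
    return total


def oracle_dependency(stats, r, eps):
    total = 0.0
    N = stats.n_examples + 2 * eps
    p_r = (stats.count_r(r) + eps) / N
    for j in range(stats.n_features):
        p_j = (stats.count_j(j) + eps) / N
        p_jr = (stats.count_jr(j, r) + eps) / N
        total += p_j * abs(p_jr / (p_j * p_r) - 1.0)
    return total


class TestScoreRDE:
    def test_empty_vector_scores_zero(self):
        m = RDEModel(r=0, weights=np.array([0.2, -0.1]))
        assert score_rde(m, np.array([], dtype=int)) == 0.0

    def test_zero_weights_score_zero(self):
        m = RDEModel(r=0, weights=np.zeros(5))
        assert score_rde(m, np.array([0, 3, 4])) == 0.0

    def test_matches_hand_computed_weights(self):
        stats = cs.accumulate(FOUR, [2], 3)
        m = build_rde(stats, 2, eps=0)
        # P(r|a) = 1/2, P(r|b) = 0, P(r) = 1/2
        assert score_rde(m, np.array([0, 1])) == pytest.approx(
            (0.5 - 0.5) + (0.0 - 0.5))

    def test_matches_oracle_random(self, rng):
        vectors = [np.flatnonzero(rng.random(10) < 0.4) for _ in range(50)]
        stats = cs.accumulate(vectors, [1, 6], 10)
        for r in (1, 6):
            m = build_rde(stats, r, eps=0.5)
            for _ in range(20):
                x = np.flatnonzero(rng.random(10) < 0.3)
                assert score_rde(m, x) == pytest.approx(
                    oracle_score(stats, r, x, 0.5), abs=1e-12)


class TestDependencyExpectation:
    def test_fully_independent_reference_scores_zero(self):
        # r (id 2) present in every example: P(j, r) = P(j) P(r) for all j.
        vectors = [np.array([0, 2]), np.array([2]), np.array([1, 2]),
                   np.array([2])]
        stats = cs.accumulate(vectors, [2], 3)
        assert dependency_expectation(stats, 2, eps=0) == pytest.approx(0.0)

    def test_single_feature_closed_form(self):
        vectors = [np.array([0]), np.array([], dtype=int)]
        stats = cs.accumulate(vectors, [0], 1)
        # P(r) |1/P(r) - 1| * P(r)... reduces to 1 - P(r) = 0.5
        assert dependency_expectation(stats, 0, eps=0) == pytest.approx(0.5)

    def test_matches_exhaustive_summation(self, rng):
        vectors = [np.flatnonzero(rng.random(8) < 0.5) for _ in range(6)]
        vectors = [v for v in vectors if len(v)]
        stats = cs.accumulate(vectors, list(range(8)), 8)
        for r in range(8):
            assert dependency_expectation(stats, r, eps=0.5) == pytest.approx(
                oracle_dependency(stats, r, 0.5), abs=1e-12)


class TestPrecisionIndicator:
    def _labeled(self):
        X = sparse.csr_matrix(np.array([
            [1, 0, 1], [1, 0, 0], [0, 1, 1], [0, 1, 0], [1, 1, 1],
            [0, 0, 1], [1, 0, 1], [0, 1, 0], [1, 0, 0], [0, 0, 1],
        ]))
        y = np.array([1, 1, 1, 0, 0, 0, 1, 0, 0, 1])
        return X, y

    def test_absent_reference_scores_zero(self):
        X = sparse.csr_matrix(np.array([[1, 0], [0, 0]]))
        assert precision_indicator(X, [1, 0], 1) == 0.0

    def test_all_positive_reference(self):
        # r in every positive, never in a negative -> I(r) = P(y)
        X = sparse.csr_matrix(np.array([[1], [1], [0], [0]]))
        y = np.array([1, 1, 0, 0])
        assert precision_indicator(X, y, 0, alpha=7.0) == pytest.approx(0.5)

    def test_hand_counted_fixture(self):
        X, y = self._labeled()
        col = X.toarray()[:, 0]
        p_r = col.mean()
        p_r_y = ((col == 1) & (y == 1)).mean()
        p_r_ybar = ((col == 1) & (y == 0)).mean()
        expected = p_r_y - 1.0 * p_r_ybar * p_r
        assert precision_indicator(X, y, 0, alpha=1.0) == pytest.approx(
            expected, abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            precision_indicator(sparse.csr_matrix((0, 2)), [], 0)


class TestSelectReferences:
    def test_frequency_strategy_sorts_by_count(self, rng):
        vectors = [np.flatnonzero(rng.random(6) < p)
                   for p in rng.uniform(0.2, 0.8, size=80)]
        stats = cs.accumulate(vectors, list(range(6)), 6)
        cfg = RDEConfig(k=3, strategy="frequency", min_candidate_freq=0)
        refs = select_references(stats, cfg)
        counts = [stats.count_j(j) for j in range(6)]
        expected = sorted(range(6), key=lambda j: (-counts[j], j))[:3]
        assert refs == expected

    def test_k_at_least_vocab_returns_all(self):
        stats = cs.accumulate(FOUR, list(range(3)), 3)
        cfg = RDEConfig(k=3, strategy="frequency")
        assert sorted(select_references(stats, cfg)) == [0, 1, 2]

    def test_k_too_large_raises(self):
        stats = cs.accumulate(FOUR, list(range(3)), 3)
        with pytest.raises(ValueError):
            select_references(stats, RDEConfig(k=10, strategy="frequency"))

    def test_bound_ranks_independent_feature_first(self):
        # feature 2 is present everywhere in the unlabeled stream
        # (exactly independent of all features), others are dependent.
        vectors = [np.array([0, 2]), np.array([0, 2]), np.array([1, 2]),
                   np.array([2]), np.array([0, 1, 2]), np.array([2])]
        stats = cs.accumulate(vectors, list(range(3)), 3)
        X = sparse.csr_matrix(np.array([[1, 0, 1], [0, 1, 1], [0, 0, 1],
                                        [1, 1, 1]]))
        y = np.array([1, 1, 0, 1])
        cfg = RDEConfig(k=1, strategy="bound", epsilon=0.0)
        refs = select_references(stats, cfg, labeled=(X, y))
        assert refs == [2]

    def test_chi_square_prefers_label_associated_feature(self, rng):
        y = np.array([1] * 20 + [0] * 20)
        informative = (y == 1).astype(int)
        noise = rng.integers(0, 2, size=40)
        X = sparse.csr_matrix(np.stack([informative, noise], axis=1))
        stats = cs.accumulate([np.flatnonzero(row) for row in X.toarray()],
                              [0, 1], 2)
        cfg = RDEConfig(k=1, strategy="chi_square")
        assert select_references(stats, cfg, labeled=(X, y)) == [0]


class TestPrune:
    def _stats(self):
        # feature 0 perfectly dependent on r=2, feature 1 exactly independent
        vectors = [np.array([0, 1, 2]), np.array([0, 2]), np.array([1]),
                   np.array([], dtype=int)]
        return cs.accumulate(vectors, [2], 3)

    def test_infinite_threshold_is_identity(self):
        stats = self._stats()
        m = build_rde(stats, 2, eps=0)
        pruned = prune(m, stats, t=np.inf, eps=0)
        assert np.array_equal(pruned.weights, m.weights)
        assert pruned.pruned

    def test_zero_like_threshold_keeps_independent_only(self):
        stats = self._stats()
        m = build_rde(stats, 2, eps=0)
        pruned = prune(m, stats, t=1e-9, eps=0)
        assert pruned.weights[0] == 0.0  # dependent, removed
        assert pruned.weights[1] == m.weights[1]  # independent, kept

    def test_straddle_threshold(self):
        stats = self._stats()
        m = build_rde(stats, 2, eps=0)
        # deviations: feature 0 -> |2-1| = 1, feature 1 -> 0
        pruned = prune(m, stats, t=0.5, eps=0)
        assert pruned.weights[0] == 0.0
        assert pruned.weights[1] == m.weights[1]


class TestTransform:
    def test_single_cell_matches_score(self):
        stats = cs.accumulate(FOUR, [2], 3)
        m = build_rde(stats, 2)
        X = sparse.csr_matrix(np.array([[1, 1, 0]], dtype=float))
        Z = transform(X, [m])
        assert Z.shape == (1, 1)
        assert Z[0, 0] == pytest.approx(score_rde(m, np.array([0, 1])))

    def test_duplicate_rows_identical(self):
        stats = cs.accumulate(FOUR, [0, 2], 3)
        rdes = [build_rde(stats, 0), build_rde(stats, 2)]
        X = sparse.csr_matrix(np.array([[1, 0, 1], [1, 0, 1]], dtype=float))
        Z = transform(X, rdes)
        assert np.array_equal(Z[0], Z[1])

    def test_per_cell_oracle(self, rng):
        vectors = [np.flatnonzero(rng.random(7) < 0.4) for _ in range(30)]
        stats = cs.accumulate(vectors, [1, 5], 7)
        rdes = [build_rde(stats, 1), build_rde(stats, 5)]
        rows = [np.array([0, 2]), np.array([1, 5, 6]), np.array([], dtype=int)]
        X = sparse.csr_matrix(
            np.array([np.isin(np.arange(7), row) for row in rows], dtype=float))
        Z = transform(X, rdes)
        for i, row in enumerate(rows):
            for mi, m in enumerate(rdes):
                assert Z[i, mi] == pytest.approx(score_rde(m, row), abs=1e-12)


class TestSuRDE:
    def test_positive_only_feature_weight(self):
        X = sparse.csr_matrix(np.array([[1], [1], [0], [0]]))
        y = [1, 1, 0, 0]
        m = train_surde(X, y)
        assert m.weights[0] == pytest.approx(1 - 0.5)

    def test_prior_matching_feature_weight_zero(self):
        X = sparse.csr_matrix(np.array([[1], [1], [1], [1]]))
        y = [1, 1, 0, 0]
        m = train_surde(X, y)
        assert m.weights[0] == pytest.approx(0.0)

    def test_single_class_rejected(self):
        X = sparse.csr_matrix(np.array([[1], [0]]))
        with pytest.raises(ValueError):
            train_surde(X, [1, 1])


class TestEnsemble:
    def test_separable_scores_reach_dev_f1_one(self):
        Z = np.array([[0.1], [0.2], [0.9], [1.0]])
        y = np.array([0, 0, 1, 1])
        model = train_ensemble(Z, y, [], Z, y)
        scores = rde.meta_scores(model.meta, model.meta_kind, Z)
        assert np.array_equal((scores >= model.threshold).astype(int), y)
        _, f1 = tune_threshold(scores, y)
        assert f1 == pytest.approx(1.0)

    def test_threshold_beats_prevalence_baseline(self, rng):
        scores = rng.random(60)
        y = (rng.random(60) < 0.5).astype(int)
        _, f1 = tune_threshold(scores, y)
        # all-positive baseline F1
        p = y.mean()
        baseline = 2 * p / (1 + p)
        assert f1 >= baseline - 1e-12

    def test_constant_scores_all_one_way(self):
        scores = np.full(6, 0.3)
        y = np.array([1, 0, 1, 0, 1, 0])
        threshold, f1 = tune_threshold(scores, y)
        p = y.mean()
        assert f1 == pytest.approx(2 * p / (1 + p))

    def test_single_class_labels_raise(self):
        Z = np.ones((3, 1))
        with pytest.raises(ValueError):
            train_ensemble(Z, [1, 1, 1], [], Z, [1, 1, 1])


class TestCombineMean:
    def test_single_list_identity(self):
        s = np.array([0.1, 0.9])
        assert np.array_equal(combine_mean([s]), s)

    def test_two_lists(self):
        out = combine_mean([np.array([0.0, 1.0]), np.array([1.0, 0.0])])
        assert out.tolist() == [0.5, 0.5]

    def test_three_list_elementwise(self, rng):
        lists = [rng.random(5) for _ in range(3)]
        out = combine_mean(lists)
        for i in range(5):
            assert out[i] == pytest.approx(sum(l[i] for l in lists) / 3)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            combine_mean([np.array([1.0]), np.array([1.0, 2.0])])

    def test_rescale_minmax_uses_reference_range(self):
        dev = np.array([0.0, 2.0])
        out = rescale_minmax(np.array([-1.0, 1.0, 3.0]), reference=dev)
        assert out.tolist() == [0.0, 0.5, 1.0]
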
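import numpy as np
import pytest

from conftest import exhaustive_best_split, pinv_fit
from sylvanreg.linmodel import add_intercept, fit_ols
from sylvanreg.tree_builder import (
    SplitRule,
    best_split,
    build_tree,
    candidate_thresholds,
    evaluate_split,
)


class TestCandidateThresholds:
    def test_midpoints_of_distinct_values(self):
        np.testing.assert_allclose(candidate_thresholds(np.array([1, 2, 2, 4])), [1.5, 3.0])

    def test_all_equal_gives_none(self):
        assert candidate_thresholds(np.array([7, 7, 7])).size == 0

    def test_n_distinct_gives_n_minus_one(self, rng):
        vals = rng.permutation(np.arange(17.0))
        assert candidate_thresholds(vals).size == 16


class TestEvaluateSplit:
    def test_small_child_is_infeasible(self, rng):
        X = np.sort(rng.standard_normal(30))[:, None]
        y = rng.standard_normal(30)
        rule = SplitRule(0, float((X[4, 0] + X[5, 0]) / 2))  # left child size 5 < m=6
        assert not evaluate_split(X, y, rule, m=6).feasible

    def test_perfect_piecewise_children_have_zero_mse(self):
        x = np.linspace(-2, 2, 40)
        y = np.where(x <= 0, 3 * x, -2 * x)
        ev = evaluate_split(x[:, None], y, SplitRule(0, 0.0), m=5)
        assert ev.left_mse == pytest.approx(0.0, abs=1e-20)
        assert ev.right_mse == pytest.approx(0.0, abs=1e-20)
        assert ev.feasible

    def test_agrees_with_refit_oracle_on_all_rules(self, rng):
        X = rng.standard_normal((40, 2))
        y = rng.standard_normal(40)
        for f in range(2):
            for t in candidate_thresholds(X[:, f]):
                ev = evaluate_split(X, y, SplitRule(f, float(t)), m=1)
                mask = X[:, f] <= t
                _, ml = pinv_fit(add_intercept(X[mask]), y[mask])
                _, mr = pinv_fit(add_intercept(X[~mask]), y[~mask])
                assert ev.left_mse == pytest.approx(ml, abs=1e-10)
                assert ev.right_mse == pytest.approx(mr, abs=1e-10)


class TestBestSplit:
    def test_alpha_above_one_blocks_noisy_root(self, rng):
        X = rng.standard_normal((80, 2))
        y = X[:, 0] + 0.5 * rng.standard_normal(80)
        root_mse = fit_ols(add_intercept(X), y).mse
        assert best_split(X, y, [0, 1], m=8, alpha=1.1, root_mse=root_mse) is None

    def test_recovers_breakpoint_of_piecewise_slope(self, rng):
        x = np.sort(rng.uniform(-2, 2, 150))
        y = np.where(x <= 0, x, -x) + 1e-4 * rng.standard_normal(150)
        X = x[:, None]
        root_mse = fit_ols(add_intercept(X), y).mse
        rule = best_split(X, y, [0], m=10, alpha=0.0, root_mse=root_mse)
        left_of_zero = x[x <= 0].max()
        right_of_zero = x[x > 0].min()
        assert left_of_zero <= rule.threshold <= right_of_zero
        want = exhaustive_best_split(X, y, [0], 10, 0.0, root_mse)
        assert (rule.feature, rule.threshold) == pytest.approx(want)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 150))
        p = int(rng.integers(1, 5))
        X = rng.standard_normal((n, p))
        beta = rng.standard_normal(p + 1)
        y = beta[0] + X @ beta[1:] + 0.5 * rng.standard_normal(n)
        root_mse = fit_ols(add_intercept(X), y).mse
        m = p + 3
        got = best_split(X, y, range(p), m=m, alpha=0.0, root_mse=root_mse)
        want = exhaustive_best_split(X, y, range(p), m, 0.0, root_mse)
        if want is None:
            assert got is None
        else:
            assert (got.feature, got.threshold) == pytest.approx(want)


class TestWeightedVariant:
    def test_weighted_sum_matches_refit_oracle_argmin(self, rng):
        X = rng.standard_normal((80, 2))
        y = np.where(X[:, 0] <= 0, X[:, 1], -X[:, 1]) + 0.3 * rng.standard_normal(80)
        root_mse = fit_ols(add_intercept(X), y).mse
        got = best_split(X, y, [0, 1], m=8, alpha=0.0, root_mse=root_mse, weighted=True)
        # independent argmin of the size-weighted child MSE
        best, best_w = None, np.inf
        for f in range(2):
            for t in candidate_thresholds(X[:, f]):
                ev = evaluate_split(X, y, SplitRule(f, float(t)), m=8)
                if not ev.feasible:
                    continue
                mask = X[:, f] <= t
                w = (mask.sum() * ev.left_mse + (~mask).sum() * ev.right_mse) / 80
                if root_mse - w > 0 and w < best_w - 1e-12:
                    best_w, best = w, (f, float(t))
        assert (got.feature, got.threshold) == pytest.approx(best)

    def test_weighted_criterion_splits_on_mild_heterogeneity(self, rng):
        # a 50% slope change: each child cannot halve the parent MSE, so the
        # literal unweighted sum refuses while the weighted mean accepts
        X = rng.standard_normal((400, 2))
        y = X[:, 1] * np.where(X[:, 0] <= 0, 1.0, 1.5) + 0.5 * rng.standard_normal(400)
        root_mse = fit_ols(add_intercept(X), y).mse
        plain = best_split(X, y, [0, 1], m=30, alpha=0.01, root_mse=root_mse)
        weighted = best_split(X, y, [0, 1], m=30, alpha=0.01, root_mse=root_mse, weighted=True)
        assert plain is None
        assert weighted is not None and weighted.feature == 0


class TestBuildTree:
    def test_prohibitive_alpha_gives_root_leaf_with_ols_coefficients(self, rng):
        X = rng.standard_normal((100, 3))
        y = X[:, 0] + rng.standard_normal(100)
        tree = build_tree(X, y, m=10, j=3, alpha=1.1, rng=rng)
        assert tree.root.is_leaf
        np.testing.assert_allclose(
            tree.root.fit.coefficients, fit_ols(add_intercept(X), y).coefficients, atol=1e-12
        )

    def test_two_regime_root_split_matches_oracle(self, rng):
        from sylvanreg.synthetic_data import gen_two_regime

        truth = gen_two_regime(
            400, 3, 0, 0.0, np.array([0.0, 1, 0.3, 0]), np.array([0.0, -1, 0.3, 0]), 0.2, 11
        )
        root_mse = fit_ols(add_intercept(truth.X), truth.y).mse
        rule = best_split(truth.X, truth.y, range(3), m=20, alpha=0.0, root_mse=root_mse)
        assert rule.feature == 0
        assert abs(rule.threshold) < 0.3

    def test_invariants_hold_on_built_trees(self, rng):
        X = rng.standard_normal((250, 3))
        y = np.where(X[:, 1] <= 0, 1.5 * X[:, 0], -1.5 * X[:, 0]) + 0.3 * rng.standard_normal(250)
        m = 15
        tree = build_tree(X, y, m=m, j=2, alpha=0.005, rng=rng)
        leaf_total = 0
        stack = [tree.root]
        seen_internal = False
        while stack:
            node = stack.pop()
            assert node.fit.coefficients.size == 4  # all p variables in every node fit
            if node.is_leaf:
                assert node.sample_indices.size >= m
                leaf_total += node.sample_indices.size
            else:
                seen_internal = True
                reduction = node.fit.mse - (node.left.fit.mse + node.right.fit.mse)
                assert reduction >= 0.005 * tree.root_mse
                stack.extend([node.left, node.right])
        assert leaf_total == 250  # leaves partition the bootstrap sample
        assert seen_internal  # the regime structure must trigger at least one split

    def test_growth_deterministic_given_rng_state(self):
        X = np.random.default_rng(3).standard_normal((200, 3))
        y = np.where(X[:, 0] <= 0, X[:, 1], -X[:, 1]) + 0.2 * np.random.default_rng(4).standard_normal(200)
        t1 = build_tree(X, y, m=12, j=2, alpha=0.01, rng=np.random.default_rng(99))
        t2 = build_tree(X, y, m=12, j=2, alpha=0.01, rng=np.random.default_rng(99))
        assert t1.to_dict() == t2.to_dict()
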
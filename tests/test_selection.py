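"""t-test screening, LASSO fitting, the 1SE rule and stability selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import ista_lasso, lasso_objective
from connstab import (
    PipelineParams,
    cv_lasso_select,
    fit_lasso,
    lambda_grid,
    one_se_lambda,
    select_by_occurrence,
    ttest_screen,
    two_sample_t,
)


class TestTTestScreen:
    def test_closed_form_example(self):
        t, p = two_sample_t(np.array([[1.0], [2.0], [3.0]]), np.array([[4.0], [5.0], [6.0]]))
        assert t[0] == pytest.approx(-3.674, abs=1e-3)
        assert p[0] == pytest.approx(0.0213, abs=1e-3)

    def test_p0_one_passes_everything(self, tiny_table):
        idx, _, _ = ttest_screen(tiny_table.values, tiny_table.labels, 1.0)
        assert idx.size == tiny_table.n_edges

    def test_zero_variance_edge_gets_p_one(self, caplog):
        X = np.random.default_rng(0).normal(size=(10, 3))
        X[:, 1] = 7.0
        y = np.r_[np.zeros(5, int), np.ones(5, int)]
        with caplog.at_level("WARNING"):
            idx, t, p = ttest_screen(X, y, 0.99)
        assert p[1] == 1.0 and t[1] == 0.0
        assert 1 not in idx

    def test_screen_nesting_in_p0(self, tiny_table):
        lo, _, _ = ttest_screen(tiny_table.values, tiny_table.labels, 0.1)
        hi, _, _ = ttest_screen(tiny_table.values, tiny_table.labels, 0.5)
        assert set(lo) <= set(hi)


class TestFitLasso:
    def test_unpenalized_limit_is_least_squares(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(30, 1))
        y = 0.7 * x[:, 0] + rng.normal(0, 0.1, 30)
        beta, _ = fit_lasso(x, y, 0.0)
        xs = (x[:, 0] - x[:, 0].mean()) / x[:, 0].std()
        slope = np.polyfit(xs, y, 1)[0]
        assert beta[0] == pytest.approx(slope, abs=1e-10)

    def test_soft_threshold_closed_form(self):
        # standardized single predictor with (1/n)Σxy = 0.5: β = S(0.5, λ)
        x = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        y = np.array([1.0, 0.0, 1.0, 0.0])
        beta, intercept = fit_lasso(x, y, 0.2)
        assert beta[0] == pytest.approx(0.3, abs=1e-8)
        assert intercept == pytest.approx(0.5, abs=1e-8)

    def test_lambda_max_zeroes_everything(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        lmax = lambda_grid(X, y, n_lambdas=2)[0]
        beta, _ = fit_lasso(X, y, lmax * 1.0001)
        np.testing.assert_array_equal(beta, 0.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            fit_lasso(np.array([[np.nan], [1.0]]), np.array([0.0, 1.0]), 0.1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_proximal_gradient_oracle(self, seed):
        """Coordinate descent agrees with an independent ISTA minimizer."""
        rng = np.random.default_rng(seed)
        n, p = rng.integers(6, 13), rng.integers(1, 4)
        X = rng.normal(size=(n, p))
        Xs = (X - X.mean(0)) / X.std(0)
        y = rng.normal(size=n)
        for lam in (0.01, 0.1, 0.5):
            beta, b0 = fit_lasso(Xs, y, lam, standardize=False)
            beta_o, b0_o = ista_lasso(Xs, y, lam)
            assert np.max(np.abs(beta - beta_o)) < 1e-4
            obj = lasso_objective(Xs, y, beta, b0, lam)
            obj_o = lasso_objective(Xs, y, beta_o, b0_o, lam)
            assert obj <= obj_o + 1e-8


class TestOneSERule:
    def test_worked_example(self):
        lam = one_se_lambda(
            np.array([1.0, 0.5, 0.1]),
            np.array([0.30, 0.20, 0.25]),
            np.array([0.05, 0.06, 0.04]),
        )
        assert lam == 0.5

    def test_all_equal_picks_largest(self):
        lam = one_se_lambda(np.array([2.0, 1.0, 0.5]), np.ones(3), np.zeros(3))
        assert lam == 2.0

    def test_zero_se_picks_largest_exact_minimum(self):
        lam = one_se_lambda(
            np.array([1.0, 0.5, 0.25, 0.1]),
            np.array([0.4, 0.2, 0.2, 0.3]),
            np.zeros(4),
        )
        assert lam == 0.5

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            one_se_lambda(np.array([]), np.array([]), np.array([]))


class TestCVLassoSelect:
    def test_produces_k_inner_sets(self, signal_table):
        sets, occ = cv_lasso_select(
            signal_table.values, signal_table.labels, k_inner=10, seed=0,
            n_lambdas=20, k_lambda=3,
        )
        assert len(sets) == 10
        assert occ.shape == (signal_table.n_edges,)
        assert occ.max() <= 10 and occ.min() >= 0

    def test_deterministic_given_seed(self, signal_table):
        a = cv_lasso_select(signal_table.values, signal_table.labels, 5, seed=3,
                            n_lambdas=15, k_lambda=3)[1]
        b = cv_lasso_select(signal_table.values, signal_table.labels, 5, seed=3,
                            n_lambdas=15, k_lambda=3)[1]
        np.testing.assert_array_equal(a, b)

    def test_noise_features_rarely_stable(self):
        """Pure-noise inputs: any fixed edge is selected <2 inner folds on average."""
        rng = np.random.default_rng(9)
        occs = []
        for s in range(12):
            X = rng.normal(size=(24, 30))
            y = np.r_[np.zeros(12, int), np.ones(12, int)]
            _, occ = cv_lasso_select(X, y, k_inner=5, seed=s, n_lambdas=15, k_lambda=3)
            occs.append(occ * 2.0)  # rescale 0..5 folds to the 0..10 convention
        assert float(np.mean(occs)) < 2.0

    def test_overwhelming_signal_always_selected(self):
        """An edge with a huge shift enters every inner set nearly always."""
        hits = 0
        for s in range(15):
            rng = np.random.default_rng(1000 + s)
            X = rng.normal(size=(40, 10))
            y = np.r_[np.zeros(20, int), np.ones(20, int)]
            X[y == 1, 0] += 3.0
            _, occ = cv_lasso_select(X, y, k_inner=10, seed=s, n_lambdas=20, k_lambda=3)
            hits += occ[0] == 10
        assert hits >= 14

    def test_params_validation(self):
        with pytest.raises(ValueError):
            PipelineParams(p0=0.0)
        with pytest.raises(ValueError):
            PipelineParams(n_occurrence=11, k_inner=10)
        with pytest.raises(ValueError):
            PipelineParams(svm_cost=-1)


class TestSelectByOccurrence:
    def test_threshold_filters(self):
        occ = np.array([10, 3, 0, 5])
        assert select_by_occurrence(occ, 5).tolist() == [0, 3]

    def test_union_and_intersection_limits(self):
        sets = [np.array([0, 1]), np.array([1, 2]), np.array([1])]
        occ = np.zeros(4, int)
        for s in sets:
            occ[s] += 1
        assert select_by_occurrence(occ, 1).tolist() == sorted({0, 1, 2})
        assert select_by_occurrence(occ, 3).tolist() == [1]

    @given(
        occ=st.lists(st.integers(0, 10), min_size=1, max_size=30),
        n1=st.integers(1, 10),
        n2=st.integers(1, 10),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_threshold(self, occ, n1, n2):
        lo, hi = sorted((n1, n2))
        a = set(select_by_occurrence(np.array(occ), hi).tolist())
        b = set(select_by_occurrence(np.array(occ), lo).tolist())
        assert a <= b
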
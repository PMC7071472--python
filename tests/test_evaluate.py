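"""Model registry, nRMSE, FSFS, LOOCV and the paired permutation test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbciscreen.evaluate import (
    ModelSpec,
    fit_predict,
    fsfs,
    loocv,
    nrmse,
    paired_permutation_test,
)


def make_problem(n=20, p=8, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[0] = 1.0
    y = X @ beta + noise * rng.standard_normal(n)
    return X, y


class TestNrmse:
    def test_perfect_prediction_is_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        assert nrmse(a, a) == 0.0

    def test_hand_arithmetic(self):
        # RMSE = 1, range = 2 -> 0.5
        assert nrmse([0.0, 2.0], [1.0, 1.0]) == pytest.approx(0.5)

    @given(st.floats(0.01, 100.0), st.integers(0, 2**16))
    @settings(max_examples=40, deadline=None)
    def test_scale_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(12)
        p = a + rng.standard_normal(12)
        assert nrmse(c * a, c * p) == pytest.approx(nrmse(a, p), rel=1e-9)

    def test_matches_direct_arithmetic(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, p = rng.standard_normal((2, 15))
            direct = np.sqrt(np.mean((a - p) ** 2)) / (a.max() - a.min())
            assert nrmse(a, p) == pytest.approx(direct, rel=1e-15)

    def test_zero_range_rejected(self):
        with pytest.raises(ValueError, match="zero range"):
            nrmse([1.0, 1.0], [0.0, 2.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            nrmse([1.0, 2.0], [1.0, 2.0, 3.0])


class TestFitPredict:
    def test_mlr_matches_normal_equations(self):
        X, y = make_problem(n=15, p=3, noise=0.3)
        Xte = np.random.default_rng(9).standard_normal((4, 3))
        got = fit_predict(ModelSpec("MLR"), X, y, Xte)
        # normal-equations oracle on raw (unstandardized) design with intercept
        A = np.column_stack([np.ones(len(X)), X])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        expected = np.column_stack([np.ones(len(Xte)), Xte]) @ beta
        np.testing.assert_allclose(got, expected, rtol=1e-8)

    def test_depth_zero_tree_predicts_training_mean(self):
        X, y = make_problem(noise=0.5)
        spec = ModelSpec("TR", {"max_depth": 1, "min_samples_leaf": len(y)})
        got = fit_predict(spec, X, y, X[:3])
        np.testing.assert_allclose(got, np.full(3, y.mean()), rtol=1e-12)

    def test_gpr_interpolates_noise_free_linear_target(self):
        X, y = make_problem(n=12, p=2, noise=0.0)
        got = fit_predict(ModelSpec("GPR"), X, y, X)
        assert np.max(np.abs(got - y)) < 1e-3

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown model family"):
            ModelSpec("ridge")

    @pytest.mark.parametrize("family", ["MLR", "TR", "ebTR", "SVMR", "kSVMR", "GPR"])
    def test_deterministic_given_seed(self, family):
        X, y = make_problem(n=25, p=5, noise=0.4, seed=3)
        a = fit_predict(ModelSpec(family), X, y, X[:5], seed=7)
        b = fit_predict(ModelSpec(family), X, y, X[:5], seed=7)
        np.testing.assert_array_equal(a, b)


class TestFsfs:
    def test_exact_column_selected_first(self):
        X, y = make_problem(n=20, p=10, noise=0.0)
        selected = fsfs(X, y, ModelSpec("MLR"))
        assert selected[0] == 0
        # training fit after step 1 is essentially perfect
        yhat = fit_predict(ModelSpec("MLR"), X[:, [0]], y, X[:, [0]])
        assert nrmse(y, yhat) < 1e-10

    def test_noise_target_selects_small_set(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((20, 40))
        y = rng.standard_normal(20)
        selected = fsfs(X, y, ModelSpec("MLR"))
        assert len(selected) <= 5

    def test_degenerate_target_rejected(self):
        X, _ = make_problem()
        with pytest.raises(ValueError, match="zero range"):
            fsfs(X, np.ones(len(X)), ModelSpec("MLR"))

    def test_constant_columns_never_selected(self):
        X, y = make_problem(n=20, p=5, noise=0.2)
        X[:, 3] = 7.0
        assert 3 not in fsfs(X, y, ModelSpec("MLR"))

    def test_names_returned_in_selection_order(self):
        X, y = make_problem(n=20, p=4, noise=0.0)
        names = [f"c{i}" for i in range(4)]
        selected = fsfs(X, y, ModelSpec("MLR"), names=names)
        assert selected[0] == "c0"


class TestLoocv:
    def test_one_prediction_per_participant(self):
        X, y = make_problem(n=12, p=6, noise=0.3)
        res = loocv(pd.DataFrame(X), pd.Series(y), ModelSpec("MLR"))
        assert len(res.per_participant) == 12

    def test_mean_model_matches_loo_oracle(self):
        X, y = make_problem(n=10, p=3, noise=0.5)
        res = loocv(pd.DataFrame(X), pd.Series(y), ModelSpec("Mean"))
        n = len(y)
        expected = np.array([(y.sum() - y[i]) / (n - 1) for i in range(n)])
        np.testing.assert_allclose(res.per_participant["predicted"], expected, rtol=1e-12)
        assert res.nrmse == pytest.approx(nrmse(y, expected), rel=1e-12)

    def test_no_information_leak_from_held_out_target(self):
        """A participant's own target value must never influence their prediction."""
        X, y = make_problem(n=10, p=4, noise=0.3)
        res_a = loocv(pd.DataFrame(X), pd.Series(y), ModelSpec("MLR"))
        y2 = y.copy()
        y2[0] = 99.0  # corrupt only the held-out participant's target
        res_b = loocv(pd.DataFrame(X), pd.Series(y2), ModelSpec("MLR"))
        assert res_a.per_participant["predicted"][0] == res_b.per_participant["predicted"][0]

    def test_baseline_requires_fixed_predictors(self):
        X, y = make_problem(n=8, p=3)
        with pytest.raises(ValueError, match="predictors"):
            loocv(pd.DataFrame(X), pd.Series(y), ModelSpec("Baseline"))

    def test_baseline_uses_named_column(self):
        X, y = make_problem(n=10, p=3, noise=0.1)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        res = loocv(df, pd.Series(y), ModelSpec("Baseline", {"predictors": ["a"]}))
        assert res.nrmse < 0.2  # y ~ column a, so the fixed single predictor works


class TestPairedPermutation:
    def test_identical_errors_give_large_p(self):
        e = np.abs(np.random.default_rng(0).standard_normal(20))
        assert paired_permutation_test(e, e, n_perm=500, seed=1) >= 0.5

    def test_clear_improvement_gives_small_p(self):
        rng = np.random.default_rng(2)
        worse = rng.uniform(1.0, 2.0, 30)
        better = rng.uniform(0.0, 0.1, 30)
        assert paired_permutation_test(worse, better, n_perm=2000, seed=3) < 0.01

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        a, b = rng.uniform(0, 1, (2, 15))
        p1 = paired_permutation_test(a, b, n_perm=1000, seed=5)
        p2 = paired_permutation_test(a, b, n_perm=1000, seed=5)
        assert p1 == p2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="identical length"):
            paired_permutation_test([1.0], [1.0, 2.0])

    def test_type_i_error_calibrated_under_null(self):
        """Rejection rate at alpha=0.05 stays near nominal under the null."""
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 300
        for r in range(reps):
            a, b = rng.exponential(1.0, (2, 20))
            p = paired_permutation_test(a, b, n_perm=500, seed=1000 + r)
            rejections += p <= 0.05
        rate = rejections / reps
        assert 0.02 <= rate <= 0.08
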
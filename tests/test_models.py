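"""MoCA prediction: standardization, MLR with CIs, the descending-width
sigmoid network, repeated-holdout validation and model comparison."""

import numpy as np
import pytest

from gaitcog.errors import GaitcogError, InvalidParameterError
from gaitcog.models import (
    NNRegressor,
    SigmoidNet,
    Standardizer,
    build_nn,
    compare_models,
    fit_mlr,
    predict_mlr,
    reference_predictor,
    train_nn,
    validate,
    zstandardize,
)

REF_COEF = np.array([5.74, -4.39, 1.03, 0.61, 1.01, 1.21])


def velocity_block(rng, n):
    """Six weakly correlated walk-velocity columns at cohort-like scales."""
    base = rng.normal([1.35, 1.38, 1.70, 1.72, 1.30, 1.33], [0.17] * 6, size=(n, 6))
    return base


class TestStandardizer:
    def test_hand_case(self):
        s = Standardizer(mu=np.array([1.0]), sigma=np.array([1.0]))
        np.testing.assert_allclose(zstandardize(np.array([[0.0], [2.0]]), s), [[-1], [1]])

    def test_round_trip(self):
        X = np.random.default_rng(0).normal(size=(30, 4)) * 3 + 5
        s = Standardizer.fit(X)
        np.testing.assert_allclose(s.inverse(s.transform(X)), X, atol=1e-12)

    def test_training_set_becomes_unit_scale(self):
        X = np.random.default_rng(1).normal(size=(50, 3))
        Z = Standardizer.fit(X).transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_zero_variance_rejected(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(InvalidParameterError):
            Standardizer.fit(X)


class TestMLR:
    def test_noiseless_recovery_is_exact(self):
        rng = np.random.default_rng(0)
        X = velocity_block(rng, 40)
        y = X @ REF_COEF + 21.2
        fit = fit_mlr(X, y)
        np.testing.assert_allclose(fit.coef, REF_COEF, atol=1e-9)
        assert fit.intercept == pytest.approx(21.2, abs=1e-9)

    def test_six_inputs_give_seven_parameters(self):
        rng = np.random.default_rng(1)
        X = velocity_block(rng, 50)
        y = rng.normal(27, 2, 50)
        fit = fit_mlr(X, y)
        assert len(fit.coef) == 6
        assert fit.conf_int.shape == (7, 2)

    def test_ci_coverage_near_nominal(self):
        rng = np.random.default_rng(2)
        hits = np.zeros(7)
        reps = 200
        for _ in range(reps):
            X = velocity_block(rng, 106)
            y = X @ REF_COEF + 21.2 + rng.normal(0, 1.5, 106)
            fit = fit_mlr(X, y)
            truth = np.append(REF_COEF, 21.2)
            hits += (fit.conf_int[:, 0] <= truth) & (truth <= fit.conf_int[:, 1])
        assert np.all(hits / reps >= 0.90)
        assert np.all(hits / reps <= 0.99)

    def test_rank_deficient_rejected(self):
        X = np.ones((30, 2))
        with pytest.raises(GaitcogError):
            fit_mlr(X, np.arange(30.0))


class TestPredictMLR:
    def test_reference_intercept_at_zero_velocities(self):
        assert predict_mlr(reference_predictor(), np.zeros(6)) == 21.2

    def test_constant_model(self):
        fit = reference_predictor()
        fit.coef[:] = 0.0
        assert predict_mlr(fit, np.array([9.0] * 6)) == pytest.approx(21.2)

    def test_linearity(self):
        fit = reference_predictor()
        rng = np.random.default_rng(3)
        v1, v2 = rng.normal(size=6), rng.normal(size=6)
        lhs = predict_mlr(fit, v1 + v2)
        rhs = predict_mlr(fit, v1) + predict_mlr(fit, v2) - fit.intercept
        assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_wrong_arity_rejected(self):
        with pytest.raises(InvalidParameterError):
            predict_mlr(reference_predictor(), np.zeros(4))


class TestNetwork:
    def test_descending_widths(self):
        assert build_nn(6).widths == (6, 5, 4, 3, 2, 1)

    def test_degenerate_two_input_case(self):
        assert build_nn(2).widths == (2, 1)

    @pytest.mark.parametrize("n", [2, 3, 6, 9])
    def test_parameter_count_closed_form(self, n):
        spec = build_nn(n)
        expected = sum(w * (w - 1) + (w - 1) for w in range(n, 1, -1))
        assert spec.n_parameters == expected
        net = SigmoidNet(spec, seed=0)
        assert sum(w.size for w in net.W) + sum(b.size for b in net.b) == expected

    def test_too_few_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_nn(1)

    def test_training_reduces_loss_on_learnable_target(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 3))
        y = 10 + 2 * X.sum(axis=1)  # monotone, sigmoid-reachable after scaling
        reg = NNRegressor(seed=0, max_epochs=2000, patience=2000)
        reg.fit(X[:60], y[:60], X[60:], y[60:])
        mae = np.mean(np.abs(reg.predict(X[:60]) - y[:60]))
        mae0 = np.mean(np.abs(y[:60] - y[:60].mean()))
        assert mae < mae0

    def test_fixed_seed_is_deterministic(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 3))
        y = rng.normal(size=60)
        r1, f1 = train_nn(X[:45], y[:45], X[45:], y[45:], max_epochs=500, seed=9)
        r2, f2 = train_nn(X[:45], y[:45], X[45:], y[45:], max_epochs=500, seed=9)
        np.testing.assert_array_equal(r1.predict(X), r2.predict(X))
        assert f1.meta["best_epoch"] == f2.meta["best_epoch"]

    def test_early_stopping_on_pure_noise(self):
        rng = np.random.default_rng(6)
        stops = []
        for seed in range(5):
            X = rng.normal(size=(60, 3))
            y = rng.normal(size=60)
            _, fr = train_nn(X[:45], y[:45], X[45:], y[45:], seed=seed)
            stops.append(fr.meta["epochs_run"])
        assert np.median(stops) < 5000  # patience fires long before the cap


class TestValidation:
    def test_perfect_model_zero_mae(self):
        rng = np.random.default_rng(7)
        X = velocity_block(rng, 60)
        y = X @ REF_COEF + 21.2  # noiseless: MLR interpolates exactly
        rep = validate("mlr", X, y, repeats=5, seed=0)
        assert rep.mean_mae < 1e-8

    def test_mae_approaches_gaussian_mad(self):
        # MAE of an unbiased predictor under N(0, sigma) noise -> sigma*sqrt(2/pi)
        rng = np.random.default_rng(8)
        sigma = 1.5
        maes = []
        for _ in range(6):
            X = velocity_block(rng, 133)
            y = X @ REF_COEF + 21.2 + rng.normal(0, sigma, 133)
            maes.append(validate("mlr", X, y, repeats=10, seed=1).mean_mae)
        assert np.mean(maes) == pytest.approx(sigma * np.sqrt(2 / np.pi), rel=0.10)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(9)
        X = velocity_block(rng, 50)
        y = X @ REF_COEF + rng.normal(0, 1, 50)
        rep1 = validate("mlr", X, y, repeats=5, seed=2)
        perm = rng.permutation(50)
        rep2 = validate("mlr", X[perm], y[perm], repeats=5, seed=2)
        assert rep1.mean_mae == pytest.approx(rep2.mean_mae, abs=1e-9)

    def test_too_few_rows_rejected(self):
        with pytest.raises(InvalidParameterError):
            validate("mlr", np.ones((4, 6)), np.ones(4), repeats=2, seed=0)


class TestCompareModels:
    def test_identical_reports_are_ns(self):
        rng = np.random.default_rng(10)
        X = velocity_block(rng, 60)
        y = X @ REF_COEF + rng.normal(0, 1, 60)
        rep = validate("mlr", X, y, repeats=10, seed=3)
        comp = compare_models(rep, rep)
        assert comp.diff_mean == 0.0
        assert comp.verdict == "ns"

    def test_uniformly_worse_is_significant(self):
        rng = np.random.default_rng(11)
        X = velocity_block(rng, 60)
        y = X @ REF_COEF + rng.normal(0, 1, 60)
        rep = validate("mlr", X, y, repeats=10, seed=4)
        import copy

        worse = copy.deepcopy(rep)
        worse.maes = rep.maes + 1.0
        comp = compare_models(worse, rep)
        assert comp.diff_mean == pytest.approx(1.0, abs=1e-12)
        assert comp.verdict == "significant"

    def test_mismatched_repeats_rejected(self):
        rng = np.random.default_rng(12)
        X = velocity_block(rng, 60)
        y = X @ REF_COEF + rng.normal(0, 1, 60)
        a = validate("mlr", X, y, repeats=5, seed=5)
        b = validate("mlr", X, y, repeats=6, seed=5)
        with pytest.raises(InvalidParameterError):
            compare_models(a, b)
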
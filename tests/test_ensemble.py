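"""Stacked regressor: contracts, degenerate targets, determinism, scoring."""

import numpy as np
import pandas as pd
import pytest
from cellfactory.ensemble import (RegressorSpec, StackedTRYRegressor,
                                  ablation_cobra, default_specs, evaluate,
                                  learning_curve)
from cellfactory.mlp import DenseDropoutRegressor
from cellfactory.preprocess import AugmentationParams

from _helpers import cheap_specs


def linear_data(n=150, seed=0, noise=0.05):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"),
                     index=[f"r{i}" for i in range(n)])
    y = pd.Series(3 * X["a"] - 2 * X["b"] + noise * rng.normal(size=n),
                  index=X.index)
    return X, y


class _FixedPredictions:
    """Stub model returning preset values for evaluate() contract checks."""

    def __init__(self, values):
        self.values = np.asarray(values, dtype=float)

    def predict(self, X):
        return self.values[: len(X)]


class TestEvaluate:
    def _xy(self, n=10):
        X = pd.DataFrame({"x": np.arange(n, dtype=float)})
        y = pd.Series(np.linspace(1, 5, n), index=X.index)
        return X, y

    def test_perfect_predictions_score_one(self):
        X, y = self._xy()
        rep = evaluate(_FixedPredictions(y.values), X, y)
        assert rep.r2 == pytest.approx(1.0) and rep.pearson_r == pytest.approx(1.0)

    def test_mean_predictions_score_zero_r2(self):
        X, y = self._xy()
        rep = evaluate(_FixedPredictions(np.full(len(y), y.mean())), X, y)
        assert rep.r2 == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_predictions_negative(self):
        X, y = self._xy()
        rep = evaluate(_FixedPredictions(y.values[::-1]), X, y)
        assert rep.pearson_r < 0 and rep.r2 < 0

    def test_fewer_than_three_rows_is_undefined(self):
        X, y = self._xy(2)
        rep = evaluate(_FixedPredictions(y.values), X, y)
        assert np.isnan(rep.r2) and np.isnan(rep.pearson_r)

    def test_per_product_scaling_reported(self):
        X, y = self._xy(8)
        products = pd.Series(["p1"] * 4 + ["p2"] * 4, index=X.index)
        rep = evaluate(_FixedPredictions(y.values), X, y,
                       products=products, per_product_scaling=True)
        assert rep.r2_scaled == pytest.approx(1.0)
        assert rep.pearson_r_scaled == pytest.approx(1.0)


class TestStack:
    def test_stack_tracks_best_base_learner_on_linear_target(self):
        X, y = linear_data()
        train, test = X.iloc[:120], X.iloc[120:]
        model = StackedTRYRegressor(specs=cheap_specs(), random_state=0)
        model.fit(train, y.iloc[:120])
        rep = evaluate(model, test, y.iloc[120:])
        best_base = max(rep.per_learner.values())
        assert rep.r2 >= best_base - 0.02
        assert rep.r2 > 0.9

    def test_in_sample_predictions_track_fitted_values(self):
        X, y = linear_data(noise=0.0)
        model = StackedTRYRegressor(specs=cheap_specs(), random_state=0).fit(X, y)
        r2 = 1 - np.sum((model.predict(X) - y) ** 2) / np.sum((y - y.mean()) ** 2)
        assert r2 > 0.95

    def test_constant_target_scores_zero_by_convention(self):
        X, _ = linear_data(60)
        y = pd.Series(4.2, index=X.index)
        model = StackedTRYRegressor(specs=cheap_specs(), random_state=0).fit(X, y)
        rep = evaluate(model, X.iloc[:10], y.iloc[:10])
        assert np.allclose(model.predict(X.iloc[:5]), 4.2, atol=0.2)
        assert rep.r2 == 0.0

    def test_fewer_than_two_learners_rejected(self):
        X, y = linear_data(50)
        with pytest.raises(ValueError, match="at least 2"):
            StackedTRYRegressor(specs=cheap_specs()[:1]).fit(X, y)

    def test_failing_learner_excluded_with_warning(self):
        class Exploding:
            def get_params(self, deep=True):
                return {}

            def set_params(self, **kw):
                return self

            def fit(self, X, y):
                raise FloatingPointError("no convergence")

        specs = cheap_specs() + [RegressorSpec("broken", Exploding(), {})]
        X, y = linear_data(80)
        with pytest.warns(UserWarning, match="broken"):
            model = StackedTRYRegressor(specs=specs, random_state=0).fit(X, y)
        assert set(model.base_learners_) == {"elastic_net",
                                             "gradient_boosted_trees", "knn"}

    def test_rows_with_missing_target_dropped(self):
        X, y = linear_data(80)
        y.iloc[:20] = np.nan
        model = StackedTRYRegressor(specs=cheap_specs(), random_state=0).fit(X, y)
        assert len(model.oof_predictions_) == 60

    def test_empty_prediction_set(self):
        X, y = linear_data(50)
        model = StackedTRYRegressor(specs=cheap_specs(), random_state=0).fit(X, y)
        assert len(model.predict(X.iloc[:0])) == 0

    def test_byte_identical_under_fixed_seeds(self):
        X, y = linear_data(90)
        aug = AugmentationParams(n=2, t=0.5, seed=3)
        p1 = StackedTRYRegressor(specs=cheap_specs(), augmentation=aug,
                                 random_state=3).fit(X, y).predict(X)
        p2 = StackedTRYRegressor(specs=cheap_specs(), augmentation=aug,
                                 random_state=3).fit(X, y).predict(X)
        assert np.array_equal(p1, p2)

    def test_six_default_learners_declared(self):
        names = [s.name for s in default_specs()]
        assert names == ["svr", "elastic_net", "random_forest",
                         "gradient_boosted_trees", "knn", "neural_network"]

    def test_neural_learner_architecture_invariant(self):
        nn = next(s.estimator for s in default_specs()
                  if s.name == "neural_network")
        assert isinstance(nn, DenseDropoutRegressor)
        assert nn.N_HIDDEN_LAYERS == 5
        assert nn.hidden_units == 100
        assert 0 < nn.dropout < 1


class TestNeuralLearner:
    def test_learns_nonlinear_response(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(400, 6))
        y = np.tanh(X[:, 0]) * 3 + X[:, 1] ** 2
        nn = DenseDropoutRegressor(epochs=80, random_state=0).fit(X[:300], y[:300])
        pred = nn.predict(X[300:])
        ss = 1 - np.sum((pred - y[300:]) ** 2) / np.sum((y[300:] - y[300:].mean()) ** 2)
        assert ss > 0.7

    def test_seeded_training_is_deterministic(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(120, 4))
        y = X[:, 0] - X[:, 2]
        p1 = DenseDropoutRegressor(epochs=10, random_state=5).fit(X, y).predict(X)
        p2 = DenseDropoutRegressor(epochs=10, random_state=5).fit(X, y).predict(X)
        assert np.array_equal(p1, p2)


class TestAblationAndCurve:
    def test_missing_cobra_columns_rejected(self):
        X, y = linear_data(60)
        with pytest.raises(ValueError, match="cobra"):
            ablation_cobra(X, y, X, y, ["cobra_yp_max"])

    def test_informative_extra_columns_help_paired_stacks(self):
        """When the target depends on a column only the with-arm keeps,
        the with-arm outscores the without-arm under shared seeds."""
        rng = np.random.default_rng(2)
        n = 220
        X = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"),
                         index=[f"r{i}" for i in range(n)])
        X["cobra_yp_max"] = rng.uniform(0, 2, size=n)
        y = pd.Series(2 * X["cobra_yp_max"] + 0.5 * X["a"]
                      + 0.1 * rng.normal(size=n), index=X.index)
        res = ablation_cobra(X.iloc[:180], y.iloc[:180], X.iloc[180:], y.iloc[180:],
                             ["cobra_yp_max"], specs=cheap_specs(),
                             n_components=6, random_state=0)
        assert res["with_cobra"]["test_r2"] > res["without_cobra"]["test_r2"]
        assert res["delta_test_r2"] > 0

    def test_curve_consistency_at_full_size(self):
        X, y = linear_data(100, seed=5)
        table = learning_curve(X, y, [100], specs=cheap_specs(),
                               n_repeats=1, random_state=0)
        direct = StackedTRYRegressor(specs=cheap_specs(), random_state=0).fit(X, y)
        assert table.cv_r2_mean.iloc[0] == pytest.approx(direct.cv_r2_mean_, abs=1e-9)

    def test_oversized_request_rejected(self):
        X, y = linear_data(50)
        with pytest.raises(ValueError, match="exceeds"):
            learning_curve(X, y, [500], specs=cheap_specs())
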
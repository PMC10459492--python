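"""Stacked ensemble: grid search, out-of-fold assembly, tuning, prediction."""

import numpy as np
import pandas as pd
import pytest
from sklearn.dummy import DummyRegressor
from sklearn.linear_model import LinearRegression

from evostack.features import DesignMatrix, FeatureSpec, build_design
from evostack.learners import BaseLearnerSpec, grid_search_fit
from evostack.metrics import vaf
from evostack.optimize import JadeConfig
from evostack.rules import MetaConfig
from evostack.stacking import (fit_stack, predict_one_step, predict_recursive,
                               tune_meta_jade)
from evostack.synth import SynthSystemSpec, gen_multisine, MultisineSpec, simulate_response

from conftest import cheap_specs, make_trial


def linear_design(rng, n=240, p=3, noise=0.0, folds=6):
    """DesignMatrix-shaped container around a plain regression problem."""
    X = rng.normal(size=(n, p))
    beta = np.arange(1, p + 1, dtype=float)
    y = X @ beta + noise * rng.normal(size=n)
    cols = [f"y_lag{j}" for j in range(1, p + 1)]
    prov = pd.DataFrame({"participant": 1,
                         "signal_id": np.repeat(np.arange(folds), n // folds),
                         "t": np.arange(1, n + 1)})
    return DesignMatrix(pd.DataFrame(X, columns=cols), y, prov,
                        FeatureSpec(ny=p, nu=1, window=2))


class TestGridSearch:
    def test_single_point_grid_chosen(self, rng):
        design = linear_design(rng)
        spec = BaseLearnerSpec("ols", lambda p, s: LinearRegression(), {"_": [7]})
        res = grid_search_fit(spec, design)
        assert res.params == {"_": 7}
        assert res.oof_predictions.shape == design.y.shape

    def test_exact_setting_found_on_noise_free_truth(self, rng):
        from sklearn.linear_model import Ridge

        design = linear_design(rng, noise=0.0)
        spec = BaseLearnerSpec("ridge", lambda p, s: Ridge(alpha=p["alpha"]),
                               {"alpha": [1e3, 1e-10]})
        res = grid_search_fit(spec, design)
        assert res.params == {"alpha": 1e-10}
        assert res.cv_rmse < 1e-6

    def test_tie_broken_in_grid_order(self, rng):
        design = linear_design(rng)
        spec = BaseLearnerSpec("dummy", lambda p, s: DummyRegressor(),
                               {"unused": [3, 1, 2]})
        res = grid_search_fit(spec, design)
        assert res.params == {"unused": 3}

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            BaseLearnerSpec("bad", lambda p, s: DummyRegressor(), {"a": []})

    def test_oof_rows_do_not_leak_their_own_targets(self, rng):
        design = linear_design(rng, noise=0.3)
        spec = BaseLearnerSpec("ols", lambda p, s: LinearRegression(), {"_": [0]})
        base = grid_search_fit(spec, design)
        fold0 = design.fold_labels == 0
        corrupted = DesignMatrix(design.X.copy(), design.y.copy(),
                                 design.provenance.copy(), design.spec)
        corrupted.y[fold0] += 100.0
        res = grid_search_fit(spec, corrupted)
        np.testing.assert_allclose(res.oof_predictions[fold0],
                                   base.oof_predictions[fold0])
        assert not np.allclose(res.oof_predictions[~fold0],
                               base.oof_predictions[~fold0])


class TestFitStack:
    def test_meta_input_shape_and_perfect_base(self, rng):
        design = linear_design(rng, noise=0.0)
        model = fit_stack(design, cheap_specs(), seed=0,
                          jade_config=JadeConfig(pop_size=6, generations=3, seed=0))
        assert model.Z.shape == (len(design), 5)
        # one base learner (OLS) is a perfect predictor; the tuned stack
        # should explain essentially all training variance
        res = predict_one_step(model, design)
        assert vaf(design.y, res.yhat) > 99.9

    def test_five_specs_required(self, rng):
        with pytest.raises(ValueError):
            fit_stack(linear_design(rng), cheap_specs()[:3], seed=0)

    def test_stack_not_worse_than_best_base(self):
        """Tuned stack CV VAF within 1 point of the best base learner's."""
        shortfalls = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            design = linear_design(r, n=240, noise=0.5)
            design.y += 0.5 * design.X["y_lag1"].to_numpy() ** 2  # mild nonlinearity
            model = fit_stack(design, cheap_specs(), seed=seed,
                              jade_config=JadeConfig(pop_size=10, generations=10,
                                                     seed=seed))
            base_cv = max(vaf(design.y, model.layer0[n].oof_predictions)
                          for n in model.learner_names)
            shortfalls.append(base_cv - model.cv_vaf)
        assert max(shortfalls) <= 1.0


class TestTuneMeta:
    def test_flat_objective_returns_in_bounds_pair(self, rng):
        class StubBackend:
            def fit(self, X, y, config):
                class M:
                    def predict(self, Z):
                        return np.asarray(Z)[:, 0] * 0.5
                return M()

        Z = rng.normal(size=(120, 5))
        y = rng.normal(size=120)
        labels = np.repeat(np.arange(6), 20)
        c, k, _ = tune_meta_jade(Z, y, labels, backend=StubBackend(), seed=3)
        assert 0 <= c <= 60 and 0 <= k <= 20

    def test_stub_backend_contract(self, rng):
        """The tuner and stack operate unchanged behind the backend seam."""
        class LinearBackend:
            def fit(self, X, y, config):
                model = LinearRegression().fit(X, y)
                class Fitted:
                    def predict(self, Z, _m=model):
                        return _m.predict(Z)
                return Fitted()

        design = linear_design(rng, noise=0.2)
        model = fit_stack(design, cheap_specs(), backend=LinearBackend(), seed=1,
                          jade_config=JadeConfig(pop_size=5, generations=2, seed=1))
        res = predict_one_step(model, design)
        assert vaf(design.y, res.yhat) > 95.0

    def test_neighbors_off_when_strictly_optimal(self, rng):
        # noisy linear targets make the instance correction strictly
        # harmful: the exhaustive 61x21 enumeration must turn the neighbors
        # off, and JADE must match that optimum within tolerance on this
        # smooth landscape
        Z = rng.normal(size=(360, 2))
        y = Z @ np.array([2.0, -1.0]) + rng.normal(0, 1.0, size=360)
        labels = np.repeat(np.arange(6), 60)
        c_g, k_g, v_grid = tune_meta_jade(Z, y, labels, tuner="grid")
        c_j, k_j, v_jade = tune_meta_jade(Z, y, labels, tuner="jade", seed=5)
        assert k_g == 0
        assert v_jade >= v_grid - 1.0

    def test_chain_cache_matches_generic_path(self, rng):
        """The prefix-cached CV objective equals refitting from scratch."""
        from evostack.rules import RuleMetaBackend
        from evostack.stacking import _ChainObjective, _GenericObjective, _fold_indices

        Z = rng.normal(size=(120, 3))
        y = Z @ np.array([1.0, 0.5, -0.5]) + rng.normal(0, 0.3, size=120)
        folds = _fold_indices(np.repeat(np.arange(4), 30))
        fast = _ChainObjective(Z, y, folds, MetaConfig(), 8, 5)
        slow = _GenericObjective(Z, y, folds, MetaConfig(), RuleMetaBackend())
        for c, k in [(0, 0), (1, 0), (3, 2), (8, 5)]:
            x = np.array([c, k], dtype=float)
            assert fast(x) == pytest.approx(slow(x), abs=1e-8)


def exact_linear_stack(trial, spec=None):
    """A stand-in model whose one-step map is the true (linear) system."""
    spec = spec or FeatureSpec()

    class Exact:
        feature_spec = spec

        def __init__(self, a1, a2, b1):
            self.c = (a1, a2, b1)

        def predict_rows(self, X):
            a1, a2, b1 = self.c
            cols = spec.columns
            return (a1 * X[:, cols.index("y_lag1")]
                    + a2 * X[:, cols.index("y_lag2")]
                    + b1 * X[:, cols.index("u_lag1")])

    return Exact


class TestRecursive:
    def _noise_free_trial(self, seed=0, seconds=1.0):
        sys = SynthSystemSpec(a1=0.9, a2=-0.45, b1=0.7, c1=1.0, c3=0.0)
        u = gen_multisine(MultisineSpec(seconds=seconds), np.random.default_rng(seed))
        y = simulate_response(u, sys)
        return make_trial(u, y), sys

    def test_h1_equals_one_step_bitwise(self, rng):
        trial, sys = self._noise_free_trial()
        Exact = exact_linear_stack(trial)
        model = Exact(sys.a1, sys.a2, sys.b1)
        design = build_design(trial)
        one = model.predict_rows(design.X.to_numpy(dtype=float))
        rec = predict_recursive(model, trial, 1)
        np.testing.assert_array_equal(rec.yhat, one)

    def test_exact_model_is_exact_at_h3(self):
        trial, sys = self._noise_free_trial()
        Exact = exact_linear_stack(trial)
        model = Exact(sys.a1, sys.a2, sys.b1)
        rec = predict_recursive(model, trial, 3)
        design = build_design(trial)
        np.testing.assert_allclose(rec.yhat, design.y, atol=1e-10)

    def test_h2_feeds_own_prediction_into_first_lag(self):
        trial, _ = self._noise_free_trial()
        spec = FeatureSpec()

        class Probe:
            feature_spec = spec

            def predict_rows(self, X):
                return X[:, spec.columns.index("y_lag1")] + 1000.0

        model = Probe()
        design = build_design(trial)
        h1 = predict_recursive(model, trial, 1).yhat
        h2 = predict_recursive(model, trial, 2).yhat
        # row r at h=2 sees the model's own h=1 prediction of t-1
        np.testing.assert_allclose(h2[1:], h1[:-1] + 1000.0)
        # while the first row has no in-sample predecessor and keeps the
        # observed lag
        assert h2[0] == h1[0]

    def test_invalid_horizon(self, rng):
        trial, sys = self._noise_free_trial()
        Exact = exact_linear_stack(trial)
        with pytest.raises(ValueError):
            predict_recursive(Exact(0.5, 0.1, 1.0), trial, 0)

    def test_prediction_determinism(self, rng):
        design = linear_design(rng, noise=0.1)
        model = fit_stack(design, cheap_specs(), seed=2,
                          jade_config=JadeConfig(pop_size=5, generations=2, seed=2))
        a = predict_one_step(model, design).yhat
        b = predict_one_step(model, design).yhat
        np.testing.assert_array_equal(a, b)
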
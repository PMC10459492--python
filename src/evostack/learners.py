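"""Layer-0 base learners and the cross-validated grid search.

Five diverse regressors form the first layer of the stack: LASSO, a
single-hidden-layer MLP (sigmoid hidden units, identity output), a
Gaussian process and a support-vector regressor with radial-basis-function
kernels, and gradient boosting with a linear booster. Hyperparameters are
chosen by leave-one-signal-out cross-validated grid search on RMSE, with
ties broken in grid order.

The RBF width for the GP and SVR is parameterized as
``k(x, x') = exp(-sigma ||x - x'||^2)`` so the grid magnitudes line up
with the kernel convention common in the R modeling stack this kind of
pipeline is usually run with.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF
from sklearn.linear_model import Lasso
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .features import DesignMatrix

__all__ = ["BaseLearnerSpec", "GridSearchResult", "grid_search_fit",
           "default_specs", "fast_specs"]


@dataclass
class BaseLearnerSpec:
    """A named estimator factory plus its hyperparameter grid.

    ``factory(params, seed)`` must return an unfitted sklearn-style
    estimator; ``grid`` maps hyperparameter names to candidate values and
    must be non-empty.
    """

    name: str
    factory: Callable[[dict, int | None], object]
    grid: dict

    def __post_init__(self) -> None:
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError(f"{self.name}: empty hyperparameter grid")

    def combinations(self):
        keys = list(self.grid)
        for values in itertools.product(*(self.grid[k] for k in keys)):
            yield dict(zip(keys, values))


def _scaled(est) -> Pipeline:
    return Pipeline([("scale", StandardScaler()), ("model", est)])


def _lasso(params, seed):
    return _scaled(Lasso(alpha=params["regularization"], max_iter=20_000))


def _mlp(params, seed):
    return _scaled(
        MLPRegressor(
            hidden_layer_sizes=(params["hidden_units"],),
            activation="logistic",
            solver="lbfgs",
            max_iter=400,
            tol=1e-6,
            random_state=seed,
        )
    )


def _gp(params, seed):
    length_scale = 1.0 / np.sqrt(2.0 * params["sigma"])
    return _scaled(
        GaussianProcessRegressor(
            kernel=RBF(length_scale=length_scale),
            optimizer=None,
            alpha=params["alpha"],
            normalize_y=True,
        )
    )


def _svr(params, seed):
    return _scaled(SVR(kernel="rbf", gamma=params["sigma"], C=params["cost"], epsilon=0.1))


def _xgb(params, seed):
    return XGBRegressor(
        booster="gblinear",
        n_estimators=params["n_rounds"],
        learning_rate=params["learning_rate"],
        reg_lambda=params["l2"],
        reg_alpha=params["l1"],
        updater="coord_descent",
        feature_selector="cyclic",
        n_jobs=1,
        random_state=0 if seed is None else seed,
        verbosity=0,
    )


def default_specs() -> list[BaseLearnerSpec]:
    """The five layer-0 learners with their search grids.

    Grids include every hyperparameter value the reference study's grid
    search selected; the GP additionally searches a small nugget (noise
    regularization) since the fixed-kernel posterior mean needs it on
    noisy data.
    """
    return [
        BaseLearnerSpec("LASSO", _lasso, {"regularization": [0.001, 0.1, 0.9]}),
        BaseLearnerSpec("MLP", _mlp, {"hidden_units": [1, 3, 5]}),
        BaseLearnerSpec("GP", _gp, {"sigma": [0.01, 0.07, 0.5], "alpha": [1e-4, 0.1]}),
        BaseLearnerSpec("SVR", _svr, {"sigma": [0.01, 0.07, 0.5], "cost": [0.25, 0.5, 1.0]}),
        BaseLearnerSpec(
            "XGBoost",
            _xgb,
            {"n_rounds": [50, 150], "learning_rate": [0.3, 0.4],
             "l2": [0.0, 1e-4, 0.1], "l1": [0.0, 1e-4, 0.1]},
        ),
    ]


def fast_specs() -> list[BaseLearnerSpec]:
    """Single-point grids for quick experiments and simulation studies."""
    return [
        BaseLearnerSpec("LASSO", _lasso, {"regularization": [0.001]}),
        BaseLearnerSpec("MLP", _mlp, {"hidden_units": [5]}),
        BaseLearnerSpec("GP", _gp, {"sigma": [0.07], "alpha": [0.1]}),
        BaseLearnerSpec("SVR", _svr, {"sigma": [0.07], "cost": [1.0]}),
        BaseLearnerSpec(
            "XGBoost",
            _xgb,
            {"n_rounds": [50], "learning_rate": [0.3], "l2": [0.1], "l1": [0.0]},
        ),
    ]


@dataclass
class GridSearchResult:
    model: object                 # refitted on all training rows
    params: dict
    oof_predictions: np.ndarray   # out-of-fold predictions at the chosen params
    cv_rmse: float


def _clone_fit_predict(spec, params, seed, X_tr, y_tr, X_te):
    est = spec.factory(params, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X_tr, y_tr)
    return est, np.asarray(est.predict(X_te), dtype=float)


def grid_search_fit(
    spec: BaseLearnerSpec,
    design: DesignMatrix,
    fold_labels: np.ndarray | None = None,
    seed: int | None = None,
) -> GridSearchResult:
    """Choose hyperparameters by mean per-fold CV RMSE, first-in-grid ties.

    Out-of-fold predictions at the winning point are kept (they become the
    meta-learner's inputs), and the final model is refitted on all rows.
    """
    X = design.X.to_numpy(dtype=float)
    y = design.y
    labels = design.fold_labels if fold_labels is None else np.asarray(fold_labels)
    folds = [np.flatnonzero(labels == lab) for lab in np.unique(labels)]
    if len(folds) < 2:
        raise ValueError("need at least two folds")
    for f in folds:
        if f.size < 2:
            raise ValueError("every fold needs at least 2 rows")

    best = None  # (rmse, params, oof)
    for params in spec.combinations():
        oof = np.empty_like(y)
        fold_rmse = []
        for te in folds:
            tr = np.setdiff1d(np.arange(len(y)), te, assume_unique=False)
            _, pred = _clone_fit_predict(spec, params, seed, X[tr], y[tr], X[te])
            oof[te] = pred
            fold_rmse.append(np.sqrt(np.mean((y[te] - pred) ** 2)))
        score = float(np.mean(fold_rmse))
        if best is None or score < best[0]:
            best = (score, params, oof.copy())

    score, params, oof = best
    final = spec.factory(params, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        final.fit(X, y)
    return GridSearchResult(final, params, oof, score)
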
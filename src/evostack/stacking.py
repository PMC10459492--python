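"""Stacked-generalization ensemble with an evolution-tuned rule meta-learner.

Training proceeds in two layers. Layer 0 fits the five base learners with
a leave-one-signal-out cross-validated grid search; their *out-of-fold*
predictions form the meta-input matrix Z (each entry produced by a model
that never saw that row's fold, so the meta-learner trains without
leakage). Layer 1 is the rule-based committee model whose two integer
hyperparameters — committees and neighbors — are tuned by JADE (or classic
DE, or exhaustive search) to maximize the mean cross-validated VAF on
(Z, y); the meta-learner is then refitted on all rows at the tuned pair.

Prediction is one-step by construction. Multi-step forecasts use the
recursive strategy: the one-step predictor is iterated, substituting its
own predictions into the output-lag regressors while the exogenous input
features are recomputed from the known perturbation signal. Errors made at
early steps propagate, which is why accuracy degrades with the horizon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import DesignMatrix, FeatureSpec, TrialSignal, build_design
from .learners import BaseLearnerSpec, GridSearchResult, grid_search_fit
from .metrics import vaf
from .optimize import Bounds, JadeConfig, optimize_classic_de, optimize_jade
from .rules import (MetaConfig, RuleMetaBackend, fit_committee_chain,
                    neighbor_correction)

logger = logging.getLogger(__name__)

__all__ = ["StackModel", "PredictionResult", "fit_stack", "tune_meta_jade",
           "predict_one_step", "predict_recursive", "save_bundle"]


@dataclass
class PredictionResult:
    horizon: int
    yhat: np.ndarray
    residuals: np.ndarray
    provenance: pd.DataFrame

    def to_frame(self, y: np.ndarray | None = None) -> pd.DataFrame:
        out = self.provenance.copy()
        out["horizon"] = self.horizon
        if y is not None:
            out["y"] = y
        out["yhat"] = self.yhat
        out["residual"] = self.residuals
        return out


@dataclass
class StackModel:
    feature_spec: FeatureSpec
    learner_names: list
    layer0: dict                 # name -> GridSearchResult
    Z: np.ndarray                # out-of-fold meta inputs (n rows x 5)
    y: np.ndarray
    meta: object                 # fitted meta-learner with .predict(Z)
    committees: int
    neighbors: int
    cv_vaf: float
    seed: int | None = None
    fold_labels: np.ndarray | None = None
    columns: list | None = None  # training design columns

    @property
    def models(self) -> list:
        return [self.layer0[n].model for n in self.learner_names]

    def layer0_matrix(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([np.asarray(m.predict(X), dtype=float)
                                for m in self.models])

    def predict_rows(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.meta.predict(self.layer0_matrix(X)), dtype=float)


def _fold_indices(labels: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(labels == lab) for lab in np.unique(labels)]


def _fold_vaf(y_true: np.ndarray, pred: np.ndarray) -> float:
    if np.var(y_true, ddof=1) == 0:
        return -np.inf
    return vaf(y_true, pred)


class _ChainObjective:
    """Cross-validated VAF objective over (committees, neighbors).

    For the native rule-meta backend the committee chain is prefix-reusable
    (member j's training target depends only on members < j), so each
    fold's chain is fitted once up to the committees upper bound and every
    integer pair is evaluated from cached member predictions. This is
    mathematically identical to refitting at each candidate pair.
    """

    def __init__(self, Z, y, folds, template: MetaConfig,
                 max_committees: int, max_neighbors: int):
        self.y = y
        self.folds = []
        self.memo: dict = {}
        for te in folds:
            tr = np.setdiff1d(np.arange(len(y)), te)
            cc = max(max_committees, 1)
            _, train_preds = chain = fit_committee_chain(
                Z[tr], y[tr], template, cc)
            members, train_preds = chain
            test_preds = np.column_stack([m.predict(Z[te]) for m in members])
            denom = np.arange(1, cc + 1)
            te_prefix = np.cumsum(test_preds, axis=1) / denom
            tr_prefix = np.cumsum(train_preds, axis=1) / denom
            mu = Z[tr].mean(axis=0)
            sd = Z[tr].std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            Q = (Z[te] - mu) / sd
            T = (Z[tr] - mu) / sd
            d2 = ((Q[:, None, :] - T[None, :, :]) ** 2).sum(axis=2)
            kmax = min(max_neighbors, len(tr))
            if kmax > 0:
                order = np.argsort(d2, axis=1)[:, :kmax]
                dists = np.sqrt(np.take_along_axis(d2, order, axis=1))
            else:
                order = np.empty((len(te), 0), dtype=int)
                dists = np.empty((len(te), 0))
            self.folds.append(
                {"te": te, "tr": tr, "te_prefix": te_prefix, "tr_prefix": tr_prefix,
                 "nn": order, "dists": dists}
            )

    def __call__(self, x: np.ndarray) -> float:
        c, k = int(x[0]), int(x[1])
        key = (c, k)
        if key in self.memo:
            return self.memo[key]
        cc = max(c, 1)
        scores = []
        for f in self.folds:
            m_te = f["te_prefix"][:, cc - 1]
            if k == 0:
                pred = m_te
            else:
                kk = min(k, f["nn"].shape[1])
                nn = f["nn"][:, :kk]
                pred = neighbor_correction(
                    m_te, f["dists"][:, :kk], nn,
                    self.y[f["tr"]], f["tr_prefix"][:, cc - 1],
                )
            scores.append(_fold_vaf(self.y[f["te"]], pred))
        val = float(np.mean(scores))
        self.memo[key] = val
        return val


class _GenericObjective:
    """Backend-agnostic CV objective: refit the backend per candidate pair."""

    def __init__(self, Z, y, folds, template: MetaConfig, backend):
        self.Z, self.y, self.folds = Z, y, folds
        self.template = template
        self.backend = backend
        self.memo: dict = {}

    def __call__(self, x: np.ndarray) -> float:
        c, k = int(x[0]), int(x[1])
        if (c, k) in self.memo:
            return self.memo[(c, k)]
        cfg = MetaConfig(committees=c, neighbors=k,
                         min_leaf=self.template.min_leaf,
                         prune_factor=self.template.prune_factor,
                         max_depth=self.template.max_depth)
        scores = []
        for te in self.folds:
            tr = np.setdiff1d(np.arange(len(self.y)), te)
            fitted = self.backend.fit(self.Z[tr], self.y[tr], cfg)
            scores.append(_fold_vaf(self.y[te], np.asarray(fitted.predict(self.Z[te]))))
        val = float(np.mean(scores))
        self.memo[(c, k)] = val
        return val


def tune_meta_jade(
    Z: np.ndarray,
    y: np.ndarray,
    fold_labels: np.ndarray,
    jade_config: JadeConfig | None = None,
    template: MetaConfig | None = None,
    backend=None,
    tuner: str = "jade",
    committees_bounds: tuple[int, int] = (0, 60),
    neighbors_bounds: tuple[int, int] = (0, 20),
    seed: int | None = None,
) -> tuple[int, int, float]:
    """Search the integer (committees, neighbors) box for maximal CV VAF.

    The default budget matches the reference protocol: population 10 for 10
    generations over committees in [0, 60] and neighbors in [0, 20].
    Returns the tuned pair and the achieved cross-validated VAF.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    template = template or MetaConfig()
    backend = backend or RuleMetaBackend()
    folds = _fold_indices(np.asarray(fold_labels))

    if np.any(Z.std(axis=0) == 0):
        logger.warning("meta-input matrix has constant columns")

    if getattr(backend, "supports_chain_cache", False):
        objective = _ChainObjective(Z, y, folds, template,
                                    committees_bounds[1], neighbors_bounds[1])
    else:
        objective = _GenericObjective(Z, y, folds, template, backend)

    bounds = Bounds(np.array([committees_bounds[0], neighbors_bounds[0]], float),
                    np.array([committees_bounds[1], neighbors_bounds[1]], float))
    if tuner == "jade":
        cfg = jade_config or JadeConfig(pop_size=10, generations=10)
        cfg = JadeConfig(pop_size=cfg.pop_size, generations=cfg.generations,
                         c=cfg.c, p=cfg.p, maximize=True,
                         integer_mask=[True, True],
                         seed=cfg.seed if cfg.seed is not None else seed)
        result = optimize_jade(objective, bounds, cfg)
        best = result.best
    elif tuner == "de":
        result = optimize_classic_de(objective, bounds, pop_size=100,
                                     generations=10, F=0.2, CR=0.5,
                                     seed=seed, maximize=True,
                                     integer_mask=[True, True])
        best = result.best
    elif tuner == "grid":
        best_val, best_pos = -np.inf, None
        for c in range(committees_bounds[0], committees_bounds[1] + 1):
            for k in range(neighbors_bounds[0], neighbors_bounds[1] + 1):
                v = objective(np.array([c, k], dtype=float))
                if v > best_val:
                    best_val, best_pos = v, (c, k)
        from .optimize import Candidate

        best = Candidate(np.array(best_pos, dtype=float), best_val)
    else:
        raise ValueError(f"unknown tuner {tuner!r}")

    c, k = int(best.position[0]), int(best.position[1])
    return c, k, float(best.fitness)


def fit_stack(
    design: DesignMatrix,
    specs: list[BaseLearnerSpec],
    template: MetaConfig | None = None,
    tuner: str = "jade",
    jade_config: JadeConfig | None = None,
    backend=None,
    seed: int | None = None,
    fold_labels: np.ndarray | None = None,
) -> StackModel:
    """Train layer 0, assemble the out-of-fold meta inputs, tune and refit
    the meta-learner."""
    if len(specs) != 5:
        raise ValueError("the stack uses exactly five base learners")
    template = template or MetaConfig()
    backend = backend or RuleMetaBackend()
    labels = design.fold_labels if fold_labels is None else np.asarray(fold_labels)

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(len(specs) + 1)]

    layer0: dict[str, GridSearchResult] = {}
    for spec, s in zip(specs, child_seeds):
        layer0[spec.name] = grid_search_fit(spec, design, labels, seed=s)
        logger.info("layer-0 %s: params=%s cv_rmse=%.5f", spec.name,
                    layer0[spec.name].params, layer0[spec.name].cv_rmse)

    names = [s.name for s in specs]
    Z = np.column_stack([layer0[n].oof_predictions for n in names])

    committees, neighbors, cv = tune_meta_jade(
        Z, design.y, labels, jade_config=jade_config, template=template,
        backend=backend, tuner=tuner, seed=child_seeds[-1],
    )
    logger.info("meta tuned: committees=%d neighbors=%d cv_vaf=%.3f",
                committees, neighbors, cv)
    cfg = MetaConfig(committees=committees, neighbors=neighbors,
                     min_leaf=template.min_leaf,
                     prune_factor=template.prune_factor,
                     max_depth=template.max_depth)
    meta = backend.fit(Z, design.y, cfg)

    return StackModel(design.spec, names, layer0, Z, design.y.copy(), meta,
                      committees, neighbors, cv, seed, labels.copy(),
                      list(design.X.columns))


def predict_one_step(model: StackModel, design: DesignMatrix) -> PredictionResult:
    """Layer-0 predictions feed the meta-learner, one row at a time ahead."""
    expected = model.columns if getattr(model, "columns", None) else \
        model.feature_spec.columns
    if list(design.X.columns) != list(expected):
        raise ValueError("design columns do not match the training design")
    yhat = model.predict_rows(design.X.to_numpy(dtype=float))
    return PredictionResult(1, yhat, design.y - yhat, design.provenance.copy())


def predict_recursive(model: StackModel, trial: TrialSignal, h: int) -> PredictionResult:
    """Iterate the one-step predictor h times, feeding predictions back
    into the output lags.

    The input ``u`` is an exogenous designed perturbation, so all
    engineered input features stay computed from the observed signal; only
    the ``y`` lags within the forecast horizon are replaced by the model's
    own earlier-step predictions. At h=1 this is exactly the one-step
    prediction.
    """
    if h < 1:
        raise ValueError("horizon must be at least 1")
    design = build_design(trial, model.feature_spec)
    X0 = design.X.to_numpy(dtype=float)
    cols = {name: j for j, name in enumerate(design.X.columns)}
    ny = model.feature_spec.ny

    preds = {1: model.predict_rows(X0)}
    for s in range(2, h + 1):
        Xs = X0.copy()
        for j in range(1, min(s - 1, ny) + 1):
            src = preds[s - j]
            col = cols[f"y_lag{j}"]
            # row r targets t = burn_in + 1 + r; its lag-j slot is the
            # (s-j)-step prediction of t-j, available from row r-j onward
            Xs[j:, col] = src[:-j]
        preds[s] = model.predict_rows(Xs)

    yhat = preds[h]
    return PredictionResult(h, yhat, design.y - yhat, design.provenance.copy())


def save_bundle(model: StackModel, outdir) -> None:
    """Human-readable model bundle: chosen hyperparameters, meta rules and
    a manifest. (Layer-0 weights are not serialized; the bundle documents
    a fitted run rather than round-tripping it.)"""
    import json
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "layer0_hyperparameters.txt", "w") as fh:
        for name in model.learner_names:
            fh.write(f"{name}: {model.layer0[name].params} "
                     f"(cv_rmse={model.layer0[name].cv_rmse:.6f})\n")
    meta = model.meta
    with open(out / "meta_rules.txt", "w") as fh:
        fh.write(f"committees={model.committees} neighbors={model.neighbors} "
                 f"cv_vaf={model.cv_vaf:.4f}\n\n")
        if hasattr(meta, "members"):
            for i, member in enumerate(meta.members, 1):
                fh.write(f"== committee member {i} ==\n")
                fh.write(member.export_text() + "\n\n")
    manifest = {
        "learners": model.learner_names,
        "committees": model.committees,
        "neighbors": model.neighbors,
        "cv_vaf": model.cv_vaf,
        "seed": model.seed,
        "feature_spec": {"ny": model.feature_spec.ny, "nu": model.feature_spec.nu,
                         "window": model.feature_spec.window},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
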
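"""Rule-based regression meta-learner in the Cubist tradition.

The model is a committee of rule sets. Each rule set comes from a
variance-reduction model tree: the tree is grown by splitting on the
feature/threshold pair that most reduces the target sum of squares, pruned
bottom-up, and flattened into rules (path conditions plus a linear model
fitted on the rows each leaf covers). Later committee members are trained
on corrected pseudo-targets that push against the running error of the
earlier members, and the committee predicts with the average of its
members. An optional instance-based correction blends the committee
prediction with adjusted targets of the k nearest training cases.

The two hyperparameters the evolutionary tuner searches are ``committees``
(0-60; 0 and 1 both mean a single member) and ``neighbors`` (0-20; 0
disables the instance correction).

This is a documented approximation with the same hyperparameter semantics
as the classic Cubist implementation, not a bit-compatible port; an
external backend implementing :class:`MetaBackend` can be swapped in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "MetaConfig",
    "Rule",
    "RuleModel",
    "CommitteeModel",
    "MetaBackend",
    "RuleMetaBackend",
    "fit_rule_model",
    "fit_committees",
    "fit_committee_chain",
    "predict_with_neighbors",
]


@dataclass(frozen=True)
class MetaConfig:
    """Hyperparameters and tree-growth controls.

    ``min_leaf`` is the smallest number of rows a leaf may cover;
    ``prune_factor`` is the margin by which a subtree's complexity-adjusted
    linear-model error must undercut its parent's to survive pruning.
    """

    committees: int = 1
    neighbors: int = 0
    min_leaf: int = 8
    prune_factor: float = 0.01
    max_depth: int = 8

    def __post_init__(self) -> None:
        if not 0 <= self.committees <= 60:
            raise ValueError("committees must lie in [0, 60]")
        if not 0 <= self.neighbors <= 20:
            raise ValueError("neighbors must lie in [0, 20]")
        if self.min_leaf < 2:
            raise ValueError("min_leaf must be at least 2")


@dataclass
class _Linear:
    """y ~ intercept + X[:, idx] @ coef"""

    intercept: float
    idx: np.ndarray  # feature indices retained after coefficient pruning
    coef: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.idx.size == 0:
            return np.full(X.shape[0], self.intercept)
        return self.intercept + X[:, self.idx] @ self.coef


@dataclass
class Rule:
    conditions: list  # (feature name, "<=" or ">", threshold)
    model: _Linear
    coverage: int

    def matches(self, X: np.ndarray, name_to_col: dict) -> np.ndarray:
        mask = np.ones(X.shape[0], dtype=bool)
        for name, op, thr in self.conditions:
            col = X[:, name_to_col[name]]
            mask &= (col <= thr) if op == "<=" else (col > thr)
        return mask


def _fit_linear(X: np.ndarray, y: np.ndarray) -> _Linear:
    """Least squares with light coefficient pruning.

    Coefficients whose standardized magnitude is below 1% of the target
    spread are dropped and the model refitted; leaves with too few rows
    fall back to the mean.
    """
    n, p = X.shape
    if n < p + 2:
        return _Linear(float(np.mean(y)), np.arange(0), np.zeros(0))
    sd_y = float(np.std(y))
    if sd_y <= 1e-12 * (abs(float(np.mean(y))) + 1.0):  # constant target
        return _Linear(float(np.mean(y)), np.arange(0), np.zeros(0))
    idx = np.arange(p)
    for _ in range(2):
        A = np.column_stack([np.ones(len(X)), X[:, idx]])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        coef = beta[1:]
        sd_x = X[:, idx].std(axis=0)
        keep = np.abs(coef) * sd_x >= 0.01 * sd_y
        if keep.all():
            return _Linear(float(beta[0]), idx, coef)
        idx = idx[keep]
        if idx.size == 0:
            return _Linear(float(np.mean(y)), idx, np.zeros(0))
    A = np.column_stack([np.ones(len(X)), X[:, idx]])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return _Linear(float(beta[0]), idx, beta[1:])


def _sse(y: np.ndarray) -> float:
    return float(np.sum((y - y.mean()) ** 2)) if y.size else 0.0


def _best_split(X: np.ndarray, y: np.ndarray, min_leaf: int):
    """(feature, threshold, reduction) of the best variance-reduction split."""
    n, p = X.shape
    if n < 2 * min_leaf:
        return None
    total = _sse(y)
    best = None
    for f in range(p):
        order = np.argsort(X[:, f], kind="mergesort")
        xs = X[order, f]
        ys = y[order]
        cs = np.cumsum(ys)
        cs2 = np.cumsum(ys * ys)
        m = np.arange(min_leaf, n - min_leaf + 1)  # left sizes
        valid = xs[m - 1] < xs[m]  # no split between equal values
        if not valid.any():
            continue
        m = m[valid]
        sse_l = cs2[m - 1] - cs[m - 1] ** 2 / m
        sum_r = cs[-1] - cs[m - 1]
        sse_r = (cs2[-1] - cs2[m - 1]) - sum_r**2 / (n - m)
        red = total - (sse_l + sse_r)
        j = int(np.argmax(red))
        if red[j] > 0 and (best is None or red[j] > best[2]):
            thr = 0.5 * (xs[m[j] - 1] + xs[m[j]])
            best = (f, float(thr), float(red[j]))
    return best


class _Node:
    __slots__ = ("rows", "feature", "threshold", "left", "right", "model")

    def __init__(self, rows):
        self.rows = rows
        self.feature = None
        self.threshold = None
        self.left = None
        self.right = None
        self.model = None


def _grow(X, y, rows, depth, config: MetaConfig, root_sse: float) -> _Node:
    node = _Node(rows)
    if depth >= config.max_depth:
        return node
    # do not split near-pure nodes (residual spread below 5% of the root's)
    if _sse(y[rows]) <= 0.0025 * root_sse * rows.size / max(len(y), 1):
        return node
    split = _best_split(X[rows], y[rows], config.min_leaf)
    if split is None:
        return node
    f, thr, _ = split
    node.feature, node.threshold = f, thr
    go_left = X[rows, f] <= thr
    node.left = _grow(X, y, rows[go_left], depth + 1, config, root_sse)
    node.right = _grow(X, y, rows[~go_left], depth + 1, config, root_sse)
    return node


def _adjusted_sse(X: np.ndarray, y: np.ndarray, model: _Linear) -> float:
    """Linear-model SSE inflated by the M5 complexity factor (n+2p)/(n-2p)."""
    n = y.size
    p = model.idx.size + 1
    resid = y - model.predict(X)
    sse = float(resid @ resid)
    if n <= 2 * p:
        return np.inf
    return sse * (n + 2 * p) / (n - 2 * p)


def _prune(node: _Node, X: np.ndarray, y: np.ndarray, prune_factor: float,
           eps: float) -> float:
    """Bottom-up model-tree pruning.

    A split survives only if its subtree's complexity-adjusted linear-model
    error undercuts the parent's own by more than ``prune_factor`` (and an
    absolute epsilon, so exact fits collapse despite rounding noise);
    otherwise the subtree collapses into a single linear leaf. Returns the
    adjusted error estimate of the (possibly collapsed) subtree and caches
    each retained leaf's fitted model on the node.
    """
    rows = node.rows
    node.model = _fit_linear(X[rows], y[rows])
    own = _adjusted_sse(X[rows], y[rows], node.model)
    if node.feature is None:
        return own
    child = (_prune(node.left, X, y, prune_factor, eps)
             + _prune(node.right, X, y, prune_factor, eps))
    if child >= own * (1.0 - prune_factor) - eps:
        node.feature = node.threshold = node.left = node.right = None
        return own
    return child


@dataclass
class RuleModel:
    """Flattened rule set with a global-linear fallback (total prediction)."""

    rules: list
    fallback: _Linear
    feature_names: list

    def predict(self, X) -> np.ndarray:
        X = _as_array(X, self.feature_names)
        name_to_col = {n: j for j, n in enumerate(self.feature_names)}
        sums = np.zeros(X.shape[0])
        counts = np.zeros(X.shape[0])
        for rule in self.rules:
            mask = rule.matches(X, name_to_col)
            if mask.any():
                sums[mask] += rule.model.predict(X[mask])
                counts[mask] += 1
        out = np.where(counts > 0, sums / np.maximum(counts, 1), self.fallback.predict(X))
        return out

    def export_text(self) -> str:
        blocks = []
        for i, rule in enumerate(self.rules, 1):
            conds = " and ".join(f"{n} {op} {thr:.6g}" for n, op, thr in rule.conditions)
            terms = " + ".join(
                f"{c:.6g}*{self.feature_names[j]}"
                for j, c in zip(rule.model.idx, rule.model.coef)
            )
            lhs = f"{rule.model.intercept:.6g}" + (f" + {terms}" if terms else "")
            blocks.append(
                f"rule {i} (coverage {rule.coverage}):\n"
                f"  if {conds or 'TRUE'}\n  then y = {lhs}"
            )
        return "\n".join(blocks)


def _as_array(X, feature_names) -> np.ndarray:
    if hasattr(X, "columns"):
        return X[feature_names].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    return X.reshape(1, -1) if X.ndim == 1 else X


def fit_rule_model(X, y, config: MetaConfig | None = None,
                   feature_names: Sequence[str] | None = None) -> RuleModel:
    """Grow, prune and flatten one model tree into a rule set."""
    config = config or MetaConfig()
    if feature_names is None and hasattr(X, "columns"):
        feature_names = list(X.columns)
    Xa = _as_array(X, feature_names) if feature_names is not None else np.asarray(X, float)
    if feature_names is None:
        feature_names = [f"x{j+1}" for j in range(Xa.shape[1])]
    y = np.asarray(y, dtype=float)
    fallback = _fit_linear(Xa, y)
    n = Xa.shape[0]
    if n < 2 * config.min_leaf:
        return RuleModel([Rule([], fallback, n)], fallback, list(feature_names))

    root = _grow(Xa, y, np.arange(n), 0, config, _sse(y))
    _prune(root, Xa, y, config.prune_factor, eps=1e-9 * (float(y @ y) + 1.0))

    rules: list[Rule] = []

    def collect(node: _Node, conds: list) -> None:
        if node.feature is None:
            model = node.model or _fit_linear(Xa[node.rows], y[node.rows])
            rules.append(Rule(list(conds), model, node.rows.size))
            return
        name = feature_names[node.feature]
        collect(node.left, conds + [(name, "<=", node.threshold)])
        collect(node.right, conds + [(name, ">", node.threshold)])

    collect(root, [])
    return RuleModel(rules, fallback, list(feature_names))


def fit_committee_chain(X, y, config: MetaConfig, n_members: int,
                        feature_names: Sequence[str] | None = None):
    """Fit ``n_members`` rule models with committee pseudo-target correction.

    Member 1 is trained on the observed targets; member j>1 on
    ``y + (y - avg prediction of members 1..j-1)``. Returns the members and
    the (n_rows, n_members) matrix of member predictions at the training
    rows, from which any committee prefix can be evaluated.
    """
    members = []
    train_preds = []
    y = np.asarray(y, dtype=float)
    running = np.zeros_like(y)
    for j in range(n_members):
        target = y if j == 0 else y + (y - running / j)
        member = fit_rule_model(X, target, config, feature_names)
        pred = member.predict(X)
        members.append(member)
        train_preds.append(pred)
        running = running + pred
    return members, np.column_stack(train_preds)


@dataclass
class _TrainingStore:
    X: np.ndarray
    mu: np.ndarray
    sd: np.ndarray
    y: np.ndarray
    m_train: np.ndarray  # committee-average prediction at the training rows


@dataclass
class CommitteeModel:
    """Averaged committee of rule models plus the training store needed for
    the nearest-neighbor correction."""

    members: list
    config: MetaConfig
    store: _TrainingStore
    feature_names: list = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.members)

    def member_matrix(self, X) -> np.ndarray:
        return np.column_stack([m.predict(X) for m in self.members])

    def committee_prediction(self, X) -> np.ndarray:
        return self.member_matrix(X).mean(axis=1)

    def predict(self, X, neighbors: int | None = None) -> np.ndarray:
        k = self.config.neighbors if neighbors is None else neighbors
        return predict_with_neighbors(self, X, k)


def fit_committees(X, y, config: MetaConfig | None = None,
                   feature_names: Sequence[str] | None = None) -> CommitteeModel:
    """Fit the committee (``committees`` 0 and 1 both give a single member)."""
    config = config or MetaConfig()
    if feature_names is None and hasattr(X, "columns"):
        feature_names = list(X.columns)
    Xa = _as_array(X, feature_names) if feature_names is not None else np.asarray(X, float)
    n_members = max(config.committees, 1)
    members, train_preds = fit_committee_chain(Xa, y, config, n_members, feature_names)
    mu = Xa.mean(axis=0)
    sd = Xa.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    store = _TrainingStore(Xa.copy(), mu, sd, np.asarray(y, float).copy(),
                           train_preds.mean(axis=1))
    names = list(feature_names) if feature_names is not None else (
        members[0].feature_names)
    return CommitteeModel(members, config, store, names)


def neighbor_correction(m_query: np.ndarray, dists: np.ndarray, nn_idx: np.ndarray,
                        y_train: np.ndarray, m_train: np.ndarray) -> np.ndarray:
    """Distance-weighted neighbor estimate blended 50/50 with the committee.

    For each neighbor n: value ``y_n + m(x) - m(x_n)``, weight
    ``1 / (distance + 0.5)``.
    """
    w = 1.0 / (dists + 0.5)
    adj = y_train[nn_idx] - m_train[nn_idx]
    est = (w * adj).sum(axis=1) / w.sum(axis=1) + m_query
    return 0.5 * m_query + 0.5 * est


def predict_with_neighbors(model: CommitteeModel, X, k: int) -> np.ndarray:
    """Committee prediction, optionally corrected by the k nearest training
    rows (Euclidean distance on standardized features)."""
    Xa = _as_array(X, model.feature_names)
    m_query = model.committee_prediction(Xa)
    if k == 0:
        return m_query
    store = model.store
    n_train = store.X.shape[0]
    if k > n_train:
        logger.warning("neighbors=%d exceeds %d training rows; clamping", k, n_train)
        k = n_train
    Q = (Xa - store.mu) / store.sd
    T = (store.X - store.mu) / store.sd
    d2 = ((Q[:, None, :] - T[None, :, :]) ** 2).sum(axis=2) if n_train * len(Q) < 4_000_000 \
        else _chunked_d2(Q, T)
    nn_idx = np.argpartition(d2, k - 1, axis=1)[:, :k]
    dists = np.sqrt(np.take_along_axis(d2, nn_idx, axis=1))
    return neighbor_correction(m_query, dists, nn_idx, store.y, store.m_train)


def _chunked_d2(Q: np.ndarray, T: np.ndarray, chunk: int = 512) -> np.ndarray:
    out = np.empty((Q.shape[0], T.shape[0]))
    t2 = (T * T).sum(axis=1)
    for i in range(0, Q.shape[0], chunk):
        q = Q[i:i + chunk]
        out[i:i + chunk] = (q * q).sum(axis=1)[:, None] - 2 * q @ T.T + t2[None, :]
    return np.maximum(out, 0.0)


class MetaBackend(Protocol):
    """Seam for alternative rule-based meta-learner implementations."""

    def fit(self, X, y, config: MetaConfig):
        """Return a fitted object exposing ``predict(X) -> np.ndarray``."""
        ...


class RuleMetaBackend:
    """Default backend: the rule/committee/neighbor model defined here."""

    supports_chain_cache = True

    def fit(self, X, y, config: MetaConfig) -> CommitteeModel:
        return fit_committees(X, y, config)
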
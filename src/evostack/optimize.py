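"""Adaptive differential evolution (JADE) and a classic DE baseline.

JADE (Zhang & Sanderson's adaptive DE with optional external archive) drives
the meta-learner tuning in this package, but the optimizer is generic: it
minimizes or maximizes any scalar objective over a box-bounded continuous
space, optionally rounding selected dimensions to integers before each
objective evaluation.

Core ingredients of JADE:

* ``DE/current-to-pbest/1`` mutation: each individual moves toward a
  randomly chosen member of the best ``p`` fraction of the population, plus
  a difference vector whose second term may come from an archive of
  recently replaced parents.
* Self-adaptation of the mutation factor ``F`` (Cauchy-distributed around a
  running location ``mu_F``, updated with the Lehmer mean of successful
  values) and of the crossover probability ``CR`` (normal around ``mu_CR``,
  updated with the arithmetic mean of successful values).

The classic baseline is ``DE/rand/1/bin`` with fixed ``F`` and ``CR``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Bounds",
    "Candidate",
    "JadeConfig",
    "AdaptiveState",
    "OptimizationResult",
    "init_population",
    "sample_F",
    "sample_CR",
    "mutate_current_to_pbest",
    "crossover_binomial",
    "update_mu_F",
    "update_mu_CR",
    "trim_archive",
    "optimize_jade",
    "optimize_classic_de",
    "write_history",
]


@dataclass(frozen=True)
class Bounds:
    """Box constraints; ``lower[j] < upper[j]`` for every dimension."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if lo.ndim != 1 or lo.shape != hi.shape or lo.size < 1:
            raise ValueError("bounds must be 1-D vectors of equal, positive length")
        if not np.all(lo < hi):
            raise ValueError("each lower bound must be strictly below its upper bound")

    @property
    def dim(self) -> int:
        return self.lower.size


@dataclass
class Candidate:
    position: np.ndarray
    fitness: float | None = None


@dataclass
class JadeConfig:
    """Settings for :func:`optimize_jade`.

    ``c`` controls how fast the adaptive locations ``mu_F``/``mu_CR`` move
    (0 freezes them); ``p`` is the fraction of the population counted as
    "pbest" donors. Defaults are the canonical JADE choices.
    ``integer_mask`` marks dimensions rounded (half away from zero) before
    every objective evaluation.
    """

    pop_size: int = 30
    generations: int = 100
    c: float = 0.1
    p: float = 0.05
    maximize: bool = False
    use_archive: bool = True
    integer_mask: Sequence[bool] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.pop_size < 4:
            raise ValueError("JADE needs a population of at least 4")
        if not 0 <= self.c <= 1:
            raise ValueError("c must lie in [0, 1]")
        if not 0 < self.p <= 1:
            raise ValueError("p must lie in (0, 1]")


@dataclass
class AdaptiveState:
    """Self-adaptation bookkeeping carried across generations."""

    mu_F: float = 0.5
    mu_CR: float = 0.5
    archive: list = field(default_factory=list)
    S_F: list = field(default_factory=list)
    S_CR: list = field(default_factory=list)
    cauchy_scale: float = 0.1
    normal_sd: float = 0.1


@dataclass
class OptimizationResult:
    best: Candidate
    history: np.ndarray  # best-so-far fitness, one entry per generation incl. init
    evaluations: int
    trace: list  # per-generation dict records (generation, best, mu_F, mu_CR, ...)


def init_population(bounds: Bounds, config: JadeConfig, rng: np.random.Generator):
    """Uniform initial population ``x = LB + r * (UB - LB)``, fitness unset."""
    span = bounds.upper - bounds.lower
    members = [
        Candidate(bounds.lower + rng.random(bounds.dim) * span)
        for _ in range(config.pop_size)
    ]
    return members


def sample_F(state: AdaptiveState, rng: np.random.Generator) -> float:
    """Mutation factor: Cauchy(mu_F, 0.1), resampled while <= 0, capped at 1."""
    while True:
        f = state.mu_F + state.cauchy_scale * rng.standard_cauchy()
        if f > 0:
            return min(f, 1.0)


def sample_CR(state: AdaptiveState, rng: np.random.Generator) -> float:
    """Crossover probability: Normal(mu_CR, 0.1) clipped to [0, 1]."""
    return float(np.clip(state.mu_CR + state.normal_sd * rng.standard_normal(), 0.0, 1.0))


def _repair_midpoint(v: np.ndarray, base: np.ndarray, bounds: Bounds) -> np.ndarray:
    """Pull out-of-bounds coordinates to the midpoint between the violated
    bound and the base vector (which is feasible), preserving diversity."""
    low = v < bounds.lower
    high = v > bounds.upper
    if low.any():
        v = np.where(low, 0.5 * (bounds.lower + base), v)
    if high.any():
        v = np.where(high, 0.5 * (bounds.upper + base), v)
    return v


def _better(a: float, b: float, maximize: bool) -> bool:
    return a > b if maximize else a < b


def mutate_current_to_pbest(
    i: int,
    positions: np.ndarray,
    fitness: np.ndarray,
    state: AdaptiveState,
    F: float,
    p: float,
    bounds: Bounds,
    rng: np.random.Generator,
    maximize: bool = False,
) -> np.ndarray:
    """``v = x_i + F (x_pbest - x_i) + F (x_r1 - x~_r2)`` with midpoint repair.

    ``x_pbest`` is uniform over the top ``ceil(p * NP)`` members, ``r1`` over
    the population minus ``i``, and ``x~_r2`` over population-plus-archive
    minus ``{i, r1}``.
    """
    NP = positions.shape[0]
    if NP < 4:
        raise ValueError("population too small for distinct mutation donors")
    n_top = max(1, int(np.ceil(p * NP)))
    order = np.argsort(-fitness if maximize else fitness)
    pbest = positions[order[rng.integers(n_top)]]

    r1 = rng.integers(NP - 1)
    if r1 >= i:
        r1 += 1
    pool = [j for j in range(NP) if j not in (i, r1)]
    n_pool = len(pool) + len(state.archive)
    pick = rng.integers(n_pool)
    if pick < len(pool):
        x_r2 = positions[pool[pick]]
    else:
        x_r2 = state.archive[pick - len(pool)]

    v = positions[i] + F * (pbest - positions[i]) + F * (positions[r1] - x_r2)
    return _repair_midpoint(v, positions[i], bounds)


def crossover_binomial(
    target: np.ndarray, mutant: np.ndarray, CR: float, rng: np.random.Generator
) -> np.ndarray:
    """Binomial crossover with a freshly drawn forced coordinate ``j_rand``."""
    d = target.size
    j_rand = rng.integers(d)
    mask = rng.random(d) <= CR
    mask[j_rand] = True
    return np.where(mask, mutant, target)


def update_mu_F(state: AdaptiveState, c: float) -> float:
    """Blend mu_F with the Lehmer mean of this generation's successful F."""
    if state.S_F:
        s = np.asarray(state.S_F, dtype=float)
        lehmer = float(np.sum(s * s) / np.sum(s))
        state.mu_F = (1.0 - c) * state.mu_F + c * lehmer
    return state.mu_F


def update_mu_CR(state: AdaptiveState, c: float) -> float:
    """Blend mu_CR with the arithmetic mean of this generation's successful CR."""
    if state.S_CR:
        state.mu_CR = (1.0 - c) * state.mu_CR + c * float(np.mean(state.S_CR))
    return state.mu_CR


def trim_archive(state: AdaptiveState, NP: int, rng: np.random.Generator) -> None:
    """Remove uniformly random entries until the archive holds at most NP."""
    excess = len(state.archive) - NP
    if excess > 0:
        keep = rng.choice(len(state.archive), size=NP, replace=False)
        state.archive = [state.archive[j] for j in sorted(keep)]


def _decoder(bounds: Bounds, integer_mask) -> Callable[[np.ndarray], np.ndarray]:
    if integer_mask is None:
        return lambda x: x
    mask = np.asarray(integer_mask, dtype=bool)
    if mask.shape != (bounds.dim,):
        raise ValueError("integer_mask length must match the number of dimensions")

    def decode(x: np.ndarray) -> np.ndarray:
        z = x.copy()
        rounded = np.sign(z[mask]) * np.floor(np.abs(z[mask]) + 0.5)
        z[mask] = np.clip(rounded, bounds.lower[mask], bounds.upper[mask])
        return z

    return decode


def _make_evaluator(objective, decode, maximize):
    worst = -np.inf if maximize else np.inf

    def evaluate(x: np.ndarray) -> float:
        val = float(objective(decode(x)))
        if not np.isfinite(val):
            logger.warning("non-finite objective value %r; treating candidate as worst", val)
            return worst
        return val

    return evaluate


def optimize_jade(
    objective: Callable[[np.ndarray], float],
    bounds: Bounds,
    config: JadeConfig,
) -> OptimizationResult:
    """Run JADE and return the best (decoded) candidate and its trajectory.

    The budget is exactly ``pop_size * (generations + 1)`` objective calls.
    Identical ``(objective, bounds, config)`` with the same seed reproduces
    the result bitwise.
    """
    rng = np.random.default_rng(config.seed)
    decode = _decoder(bounds, config.integer_mask)
    evaluate = _make_evaluator(objective, decode, config.maximize)

    members = init_population(bounds, config, rng)
    positions = np.array([m.position for m in members])
    fitness = np.array([evaluate(x) for x in positions])
    evaluations = len(members)

    state = AdaptiveState()
    best_i = int(np.argmax(fitness) if config.maximize else np.argmin(fitness))
    best = Candidate(decode(positions[best_i].copy()), float(fitness[best_i]))
    history = [best.fitness]
    trace = [
        {"generation": 0, "best_fitness": best.fitness, "mu_F": state.mu_F,
         "mu_CR": state.mu_CR, "archive_size": 0}
    ]

    for gen in range(1, config.generations + 1):
        state.S_F.clear()
        state.S_CR.clear()
        for i in range(config.pop_size):
            F = sample_F(state, rng)
            CR = sample_CR(state, rng)
            mutant = mutate_current_to_pbest(
                i, positions, fitness, state, F, config.p, bounds, rng,
                maximize=config.maximize,
            )
            trial = crossover_binomial(positions[i], mutant, CR, rng)
            f_trial = evaluate(trial)
            evaluations += 1
            if _better(f_trial, fitness[i], config.maximize):
                if config.use_archive:
                    state.archive.append(positions[i].copy())
                positions[i] = trial
                fitness[i] = f_trial
                state.S_F.append(F)
                state.S_CR.append(CR)
                if _better(f_trial, best.fitness, config.maximize):
                    best = Candidate(decode(trial.copy()), f_trial)
        trim_archive(state, config.pop_size, rng)
        update_mu_F(state, config.c)
        update_mu_CR(state, config.c)
        history.append(best.fitness)
        trace.append(
            {"generation": gen, "best_fitness": best.fitness, "mu_F": state.mu_F,
             "mu_CR": state.mu_CR, "archive_size": len(state.archive)}
        )

    return OptimizationResult(best, np.asarray(history), evaluations, trace)


def optimize_classic_de(
    objective: Callable[[np.ndarray], float],
    bounds: Bounds,
    pop_size: int = 100,
    generations: int = 100,
    F: float = 0.2,
    CR: float = 0.5,
    seed: int | None = None,
    maximize: bool = False,
    integer_mask: Sequence[bool] | None = None,
) -> OptimizationResult:
    """``DE/rand/1/bin`` with fixed control parameters (no adaptation, no archive)."""
    if pop_size < 4:
        raise ValueError("DE needs a population of at least 4")
    rng = np.random.default_rng(seed)
    decode = _decoder(bounds, integer_mask)
    evaluate = _make_evaluator(objective, decode, maximize)

    span = bounds.upper - bounds.lower
    positions = bounds.lower + rng.random((pop_size, bounds.dim)) * span
    fitness = np.array([evaluate(x) for x in positions])
    evaluations = pop_size

    best_i = int(np.argmax(fitness) if maximize else np.argmin(fitness))
    best = Candidate(decode(positions[best_i].copy()), float(fitness[best_i]))
    history = [best.fitness]
    trace = [{"generation": 0, "best_fitness": best.fitness}]

    for gen in range(1, generations + 1):
        for i in range(pop_size):
            pool = [j for j in range(pop_size) if j != i]
            r1, r2, r3 = rng.choice(pool, size=3, replace=False)
            v = positions[r1] + F * (positions[r2] - positions[r3])
            v = _repair_midpoint(v, positions[i], bounds)
            trial = crossover_binomial(positions[i], v, CR, rng)
            f_trial = evaluate(trial)
            evaluations += 1
            if _better(f_trial, fitness[i], maximize):
                positions[i] = trial
                fitness[i] = f_trial
                if _better(f_trial, best.fitness, maximize):
                    best = Candidate(decode(trial.copy()), f_trial)
        history.append(best.fitness)
        trace.append({"generation": gen, "best_fitness": best.fitness})

    return OptimizationResult(best, np.asarray(history), evaluations, trace)


def write_history(result: OptimizationResult, path) -> None:
    """Dump the per-generation trace as delimited text."""
    keys = list(result.trace[0])
    with open(path, "w") as fh:
        fh.write(",".join(keys) + "\n")
        for rec in result.trace:
            fh.write(",".join(str(rec.get(k, "")) for k in keys) + "\n")


def save_run_record(config: JadeConfig, bounds: Bounds, path) -> None:
    """Flat key=value record of an optimizer setup."""
    lines = [
        f"np = {config.pop_size}",
        f"generations = {config.generations}",
        f"c = {config.c}",
        f"p = {config.p}",
        f"maximize = {config.maximize}",
        f"seed = {config.seed}",
        "lower = " + ",".join(str(v) for v in bounds.lower),
        "upper = " + ",".join(str(v) for v in bounds.upper),
        "integer = " + ",".join(
            str(bool(b)) for b in (config.integer_mask
                                   or [False] * bounds.dim)),
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_run_record(path) -> tuple[JadeConfig, Bounds]:
    """Read back a record written by :func:`save_run_record`."""
    kv: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
    bounds = Bounds(
        np.array([float(v) for v in kv["lower"].split(",")]),
        np.array([float(v) for v in kv["upper"].split(",")]),
    )
    mask = [v == "True" for v in kv["integer"].split(",")]
    config = JadeConfig(
        pop_size=int(kv["np"]),
        generations=int(kv["generations"]),
        c=float(kv["c"]),
        p=float(kv["p"]),
        maximize=kv["maximize"] == "True",
        integer_mask=mask if any(mask) else None,
        seed=None if kv["seed"] == "None" else int(kv["seed"]),
    )
    return config, bounds
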
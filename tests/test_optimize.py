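"""Unit and property tests for the JADE and classic-DE optimizers."""

import numpy as np
import pytest

from evostack.optimize import (AdaptiveState, Bounds, Candidate, JadeConfig,
                               crossover_binomial, init_population,
                               mutate_current_to_pbest, optimize_classic_de,
                               optimize_jade, sample_CR, sample_F,
                               trim_archive, update_mu_CR, update_mu_F,
                               _repair_midpoint)


class ScriptedRNG:
    """Deterministic stand-in replaying preset draws."""

    def __init__(self, uniforms=(), cauchy=(), normals=(), integers=()):
        self._uniform = list(uniforms)
        self._cauchy = list(cauchy)
        self._normals = list(normals)
        self._integers = list(integers)

    def random(self, size=None):
        if size is None:
            return self._uniform.pop(0)
        return np.array([self._uniform.pop(0) for _ in range(size)])

    def standard_cauchy(self):
        return self._cauchy.pop(0)

    def standard_normal(self):
        return self._normals.pop(0)

    def integers(self, *args):
        return self._integers.pop(0)


def sphere(x):
    return float(np.sum(x * x))


class TestBoundsAndInit:
    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            Bounds(np.array([0.0, 1.0]), np.array([1.0, 1.0]))

    def test_population_too_small_rejected(self):
        with pytest.raises(ValueError):
            JadeConfig(pop_size=3)

    def test_init_is_uniform_within_bounds(self):
        bounds = Bounds(np.array([-1.0]), np.array([3.0]))
        cfg = JadeConfig(pop_size=10_000, generations=1, seed=0)
        members = init_population(bounds, cfg, np.random.default_rng(0))
        pos = np.array([m.position[0] for m in members])
        assert pos.min() >= -1.0 and pos.max() <= 3.0
        # mean of U(-1, 3) is 1; Monte-Carlo tolerance 0.05
        assert abs(pos.mean() - 1.0) < 0.05
        assert all(m.fitness is None for m in members)


class TestAdaptiveSampling:
    def test_F_truncated_above_one(self):
        state = AdaptiveState(mu_F=0.5)
        # raw draw 0.5 + 0.1 * 12 = 1.7 -> capped at 1
        assert sample_F(state, ScriptedRNG(cauchy=[12.0])) == 1.0

    def test_F_resampled_when_nonpositive(self):
        state = AdaptiveState(mu_F=0.1)
        # raw draws 0.1 + 0.1*(-3) = -0.2 (rejected), then 0.1 + 0.1*2 = 0.3
        assert sample_F(state, ScriptedRNG(cauchy=[-3.0, 2.0])) == pytest.approx(0.3)

    def test_F_median_matches_independent_sampler(self):
        state = AdaptiveState(mu_F=0.9)
        rng = np.random.default_rng(7)
        draws = np.array([sample_F(state, rng) for _ in range(100_000)])
        assert 0.80 <= np.median(draws) <= 1.00
        # independent oracle: same resample/truncate rules on raw Cauchy draws
        oracle_rng = np.random.default_rng(8)
        raw = 0.9 + 0.1 * oracle_rng.standard_cauchy(300_000)
        oracle = np.minimum(raw[raw > 0], 1.0)[:100_000]
        assert abs(np.median(draws) - np.median(oracle)) < 0.01

    def test_CR_clipped_to_unit_interval(self):
        state = AdaptiveState(mu_CR=0.5)
        assert sample_CR(state, ScriptedRNG(normals=[8.0])) == 1.0
        assert sample_CR(state, ScriptedRNG(normals=[-6.0])) == 0.0

    def test_CR_mean(self):
        state = AdaptiveState(mu_CR=0.5)
        rng = np.random.default_rng(11)
        draws = np.array([sample_CR(state, rng) for _ in range(100_000)])
        assert abs(draws.mean() - 0.5) < 0.01


class TestMutationCrossover:
    bounds2 = Bounds(np.array([-10.0, -10.0]), np.array([10.0, 10.0]))

    def test_F_zero_collapses_to_current(self):
        pos = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0], [0.0, 2.0]])
        fit = np.array([0.0, 1.0, 2.0, 3.0])
        v = mutate_current_to_pbest(0, pos, fit, AdaptiveState(), 0.0, 0.25,
                                    self.bounds2, np.random.default_rng(0))
        np.testing.assert_allclose(v, pos[0])

    def test_direct_substitution(self):
        # x_i=(0,0), pbest=(1,1), r1=(2,0), r2=(0,2), F=0.5 -> (1.5, -0.5)
        pos = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0], [0.0, 2.0]])
        fit = np.array([3.0, 0.0, 1.0, 2.0])  # pbest (p=0.25) is index 1
        # draws: pbest pick 0, r1 pick -> index 2 (draw 1 skips i=0), r2 pick
        # index 3 (pool [1, 3] -> draw 1)
        rng = ScriptedRNG(integers=[0, 1, 1])
        v = mutate_current_to_pbest(0, pos, fit, AdaptiveState(), 0.5, 0.25,
                                    self.bounds2, rng)
        np.testing.assert_allclose(v, [1.5, -0.5])

    def test_midpoint_repair(self):
        bounds = Bounds(np.array([0.0]), np.array([1.0]))
        v = _repair_midpoint(np.array([1.3]), np.array([0.9]), bounds)
        assert v[0] == pytest.approx(0.95)
        v = _repair_midpoint(np.array([-0.7]), np.array([0.4]), bounds)
        assert v[0] == pytest.approx(0.2)

    def test_crossover_extremes(self):
        target = np.zeros(6)
        mutant = np.ones(6)
        rng = np.random.default_rng(3)
        np.testing.assert_array_equal(
            crossover_binomial(target, mutant, 1.0, rng), mutant)
        trial = crossover_binomial(target, mutant, 0.0, np.random.default_rng(4))
        assert trial.sum() == 1.0  # only the forced coordinate

    def test_crossover_scripted(self):
        # d=3, uniforms (0.2, 0.9, 0.4), CR=0.5, forced j=2 (0-based 1)
        rng = ScriptedRNG(uniforms=[0.2, 0.9, 0.4], integers=[1])
        trial = crossover_binomial(np.zeros(3), np.ones(3), 0.5, rng)
        np.testing.assert_array_equal(trial, [1.0, 1.0, 1.0])


class TestAdaptationUpdates:
    def test_mu_F_unchanged_without_successes(self):
        state = AdaptiveState(mu_F=0.5)
        assert update_mu_F(state, 0.1) == 0.5

    def test_mu_F_fixed_point_and_lehmer(self):
        state = AdaptiveState(mu_F=0.5, S_F=[0.5])
        assert update_mu_F(state, 0.1) == pytest.approx(0.5)
        state = AdaptiveState(mu_F=0.5, S_F=[1.0, 0.5])
        assert update_mu_F(state, 0.1) == pytest.approx(0.9 * 0.5 + 0.1 * (1.25 / 1.5))

    def test_mu_CR_arithmetic(self):
        state = AdaptiveState(mu_CR=0.7)
        assert update_mu_CR(state, 0.1) == 0.7
        state = AdaptiveState(mu_CR=0.123, S_CR=[0.2, 0.4])
        assert update_mu_CR(state, 1.0) == pytest.approx(0.3)
        state = AdaptiveState(mu_CR=0.5, S_CR=[0.9])
        assert update_mu_CR(state, 0.1) == pytest.approx(0.54)

    def test_trim_archive(self):
        rng = np.random.default_rng(0)
        state = AdaptiveState(archive=[np.array([float(i)]) for i in range(13)])
        before = {float(a[0]) for a in state.archive}
        trim_archive(state, 10, rng)
        assert len(state.archive) == 10
        assert {float(a[0]) for a in state.archive} <= before
        # seeded removals are reproducible
        s1 = AdaptiveState(archive=[np.array([float(i)]) for i in range(13)])
        s2 = AdaptiveState(archive=[np.array([float(i)]) for i in range(13)])
        trim_archive(s1, 10, np.random.default_rng(42))
        trim_archive(s2, 10, np.random.default_rng(42))
        assert [a[0] for a in s1.archive] == [a[0] for a in s2.archive]


class TestOptimizeJade:
    bounds = Bounds(np.array([-5.0, -5.0]), np.array([5.0, 5.0]))

    def test_sphere_converges(self):
        cfg = JadeConfig(pop_size=20, generations=100, seed=1)
        res = optimize_jade(sphere, self.bounds, cfg)
        assert res.best.fitness < 1e-6
        # independent reference optimizer agrees the optimum is reachable
        from scipy.optimize import differential_evolution

        ref = differential_evolution(sphere, [(-5, 5)] * 2, seed=1, tol=1e-12)
        assert ref.fun < 1e-6

    def test_constant_objective_flat_history(self):
        cfg = JadeConfig(pop_size=8, generations=20, seed=2)
        res = optimize_jade(lambda x: 3.25, self.bounds, cfg)
        assert res.best.fitness == 3.25
        assert np.all(res.history == 3.25)

    def test_integer_dimension_brute_force(self):
        bounds = Bounds(np.array([0.0]), np.array([10.0]))
        cfg = JadeConfig(pop_size=10, generations=30, integer_mask=[True], seed=3)
        res = optimize_jade(lambda x: (x[0] - 3.4) ** 2, bounds, cfg)
        brute = min(range(11), key=lambda k: (k - 3.4) ** 2)
        assert res.best.position[0] == brute == 3

    def test_budget_and_determinism(self):
        cfg = JadeConfig(pop_size=12, generations=15, seed=9)
        r1 = optimize_jade(sphere, self.bounds, cfg)
        r2 = optimize_jade(sphere, self.bounds, cfg)
        assert r1.evaluations == 12 * 16
        np.testing.assert_array_equal(r1.history, r2.history)
        np.testing.assert_array_equal(r1.best.position, r2.best.position)

    def test_invariants_along_run(self):
        cfg = JadeConfig(pop_size=10, generations=40, seed=5)
        res = optimize_jade(sphere, self.bounds, cfg)
        hist = res.history
        assert np.all(np.diff(hist) <= 0)  # monotone for minimization
        for rec in res.trace:
            assert 0.0 <= rec["mu_F"] <= 1.0
            assert 0.0 <= rec["mu_CR"] <= 1.0
            assert rec["archive_size"] <= 10
        assert np.all(np.abs(res.best.position) <= 5.0)

    def test_c_zero_freezes_adaptation(self):
        cfg = JadeConfig(pop_size=10, generations=25, c=0.0, seed=6)
        res = optimize_jade(sphere, self.bounds, cfg)
        assert all(rec["mu_F"] == 0.5 and rec["mu_CR"] == 0.5 for rec in res.trace)

    def test_maximize_direction(self):
        cfg = JadeConfig(pop_size=15, generations=60, maximize=True, seed=7)
        res = optimize_jade(lambda x: -sphere(x), self.bounds, cfg)
        assert res.best.fitness > -1e-5
        assert np.all(np.diff(res.history) >= 0)

    def test_nonfinite_objective_treated_as_worst(self):
        def bad(x):
            return np.nan if x[0] > 0 else sphere(x)

        cfg = JadeConfig(pop_size=10, generations=30, seed=8)
        res = optimize_jade(bad, self.bounds, cfg)
        assert np.isfinite(res.best.fitness)
        assert res.best.position[0] <= 0


class TestClassicDE:
    bounds = Bounds(np.array([-5.0, -5.0]), np.array([5.0, 5.0]))

    def test_sphere_converges(self):
        res = optimize_classic_de(sphere, self.bounds, pop_size=30,
                                  generations=150, F=0.5, CR=0.9, seed=21)
        assert res.best.fitness < 1e-4

    def test_determinism_and_monotonicity(self):
        kw = dict(pop_size=20, generations=40, F=0.2, CR=0.5, seed=13)
        r1 = optimize_classic_de(sphere, self.bounds, **kw)
        r2 = optimize_classic_de(sphere, self.bounds, **kw)
        np.testing.assert_array_equal(r1.history, r2.history)
        assert np.all(np.diff(r1.history) <= 0)
        assert r1.evaluations == 20 * 41


class TestRunArtifacts:
    def test_history_written_as_delimited_text(self, tmp_path):
        from evostack.optimize import write_history

        bounds = Bounds(np.array([-1.0]), np.array([1.0]))
        res = optimize_jade(sphere, bounds, JadeConfig(pop_size=5, generations=4,
                                                       seed=0))
        path = tmp_path / "history.csv"
        write_history(res, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0].split(",")[:2] == ["generation", "best_fitness"]
        assert len(lines) == 1 + 5  # header + init + 4 generations

    def test_run_record_round_trip(self, tmp_path):
        from evostack.optimize import load_run_record, save_run_record

        bounds = Bounds(np.array([0.0, -2.0]), np.array([6.0, 2.0]))
        cfg = JadeConfig(pop_size=12, generations=7, c=0.2, p=0.1,
                         maximize=True, integer_mask=[True, False], seed=4)
        path = tmp_path / "run.cfg"
        save_run_record(cfg, bounds, path)
        cfg2, bounds2 = load_run_record(path)
        assert cfg2.pop_size == 12 and cfg2.generations == 7
        assert cfg2.c == 0.2 and cfg2.p == 0.1 and cfg2.maximize
        assert cfg2.integer_mask == [True, False] and cfg2.seed == 4
        np.testing.assert_array_equal(bounds2.lower, bounds.lower)
        np.testing.assert_array_equal(bounds2.upper, bounds.upper)
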
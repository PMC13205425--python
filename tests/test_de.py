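"""DE/best/1/bin machinery: initialisation, operators, repair, full runs."""

import math

import numpy as np
import pytest
from scipy import stats

from evogmd.de import (Bounds, Candidate, DEConfig, crossover_bin, decode,
                       default_bounds, encode, init_population, mutate_best1,
                       repair_bounds, run_optimization, select_greedy)
from evogmd.gabor import GaborBank, GaborParams


class TestInitPopulation:
    def test_deterministic_under_seed(self):
        cfg = DEConfig(population_size=8, n_filters=2)
        b = default_bounds(2)
        p1 = init_population(cfg, b, np.random.default_rng(3))
        p2 = init_population(cfg, b, np.random.default_rng(3))
        np.testing.assert_array_equal(p1, p2)
        assert p1.shape == (8, 12)

    def test_draws_stay_within_bounds(self):
        cfg = DEConfig(population_size=10000 // 24 + 4, n_filters=4)
        b = default_bounds(4)
        pop = init_population(cfg, b, np.random.default_rng(0))
        assert (pop >= b.lower).all() and (pop <= b.upper).all()

    def test_marginals_are_uniform(self):
        """KS test of 10^4 draws of each coordinate family vs its uniform law."""
        b = default_bounds(1)
        cfg = DEConfig(population_size=10_000, n_filters=1)
        pop = init_population(cfg, b, np.random.default_rng(7))
        for j in range(6):
            u = stats.uniform(loc=b.lower[j], scale=b.upper[j] - b.lower[j])
            p_value = stats.kstest(pop[:, j], u.cdf).pvalue
            assert p_value > 0.01

    def test_population_below_four_rejected(self):
        with pytest.raises(ValueError):
            DEConfig(population_size=3)


class TestMutation:
    def test_equal_difference_pair_returns_best(self):
        best = np.array([1.0, 2.0])
        a = np.array([3.0, 1.0])
        np.testing.assert_array_equal(mutate_best1(best, a, a, 0.8), best)

    def test_zero_scale_factor_returns_best(self):
        best = np.array([1.0, 2.0])
        v = mutate_best1(best, np.array([9.0, 9.0]), np.array([0.0, 1.0]), 0.0)
        np.testing.assert_array_equal(v, best)

    def test_hand_arithmetic(self):
        v = mutate_best1(np.array([1.0, 2.0]), np.array([3.0, 1.0]),
                         np.array([0.0, 5.0]), 0.8)
        np.testing.assert_allclose(v, [3.4, -1.2])


class TestCrossover:
    def test_full_rate_copies_donor(self, rng):
        t, d = rng.random(24), rng.random(24)
        np.testing.assert_array_equal(crossover_bin(t, d, 1.0, rng), d)

    def test_zero_rate_keeps_target_except_forced_coordinate(self, rng):
        t, d = rng.random(24), rng.random(24)
        trial = crossover_bin(t, d, 0.0, rng)
        donor_coords = np.flatnonzero(trial != t)
        assert donor_coords.size == 1
        j = donor_coords[0]
        assert trial[j] == d[j]

    def test_replays_rng_stream_and_always_takes_one_donor_coordinate(self):
        t = np.zeros(24)
        d = np.ones(24)
        for seed in range(1000):
            r1 = np.random.default_rng(seed)
            trial = crossover_bin(t, d, 0.5, r1)
            r2 = np.random.default_rng(seed)
            j_rand = int(r2.integers(24))
            take = r2.random(24) <= 0.5
            take[j_rand] = True
            np.testing.assert_array_equal(trial, np.where(take, d, t))
            assert trial.sum() >= 1  # at least one donor coordinate


class TestRepair:
    def test_in_range_untouched(self, rng):
        b = default_bounds(2)
        v = rng.uniform(b.lower, b.upper)
        np.testing.assert_array_equal(repair_bounds(v, b), v)

    def test_reflection_above_upper(self):
        b = Bounds(np.array([1.0]), np.array([10.0]))
        # 1 + |12 mod 9| = 4
        np.testing.assert_allclose(repair_bounds(np.array([12.0]), b), [4.0])

    def test_reflection_below_lower(self):
        b = Bounds(np.array([0.0]), np.array([math.pi]))
        # pi - |-0.5 mod pi| = pi - 0.5 (truncated remainder)
        np.testing.assert_allclose(repair_bounds(np.array([-0.5]), b),
                                   [math.pi - 0.5])

    def test_idempotent_and_bound_respecting_under_fuzzing(self):
        b = default_bounds(4)
        rng = np.random.default_rng(99)
        v = rng.uniform(b.lower - 50.0, b.upper + 50.0, size=(10_000, b.dim))
        repaired = repair_bounds(v, b)
        assert (repaired >= b.lower).all() and (repaired <= b.upper).all()
        np.testing.assert_array_equal(repair_bounds(repaired, b), repaired)


class TestSelection:
    def test_strictly_better_trial_wins(self):
        t = Candidate(np.zeros(2), 0.2)
        tr = Candidate(np.ones(2), 0.1)
        assert select_greedy(t, tr) is tr

    def test_tie_retains_target(self):
        t = Candidate(np.zeros(2), 0.2)
        tr = Candidate(np.ones(2), 0.2)
        assert select_greedy(t, tr) is t

    def test_selected_fitness_is_min_except_ties(self, rng):
        for _ in range(100):
            ft, fr = rng.random(2)
            chosen = select_greedy(Candidate(np.zeros(1), ft),
                                   Candidate(np.ones(1), fr))
            assert chosen.fitness == (fr if fr < ft else ft)

    def test_unevaluated_fitness_rejected(self):
        with pytest.raises(ValueError):
            select_greedy(Candidate(np.zeros(1)), Candidate(np.ones(1), 0.1))


class TestDecode:
    def test_nf4_vector_has_24_coordinates_and_decodes_to_4_filters(self):
        b = default_bounds(4)
        assert b.dim == 24
        v = init_population(DEConfig(population_size=4, n_filters=4), b,
                            np.random.default_rng(0))[0]
        bank = decode(v)
        assert len(bank) == 4

    def test_window_rounds_half_away_from_zero(self):
        v = np.array([8.5, 2.0, 0.5, 3.0, 0.5, 1.0])
        assert decode(v).filters[0].m == 9

    def test_encode_decode_fixed_point_for_integer_windows(self):
        bank = GaborBank((
            GaborParams(m=9, sigma=2.0, theta=0.5, lam=3.0, gamma=0.5, psi=1.0),
            GaborParams(m=15, sigma=4.0, theta=1.5, lam=7.0, gamma=0.9, psi=5.0),
        ))
        assert decode(encode(bank)) == bank

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError):
            decode(np.zeros(7))


def sphere_fitness(bounds):
    """Sum of squared normalized coordinates — standard DE sanity benchmark."""
    span = bounds.upper - bounds.lower

    def fn(v):
        z = (v - bounds.lower) / span
        return float(np.mean(z**2))

    return fn


class TestRunOptimization:
    def test_zero_fitness_terminates_immediately_on_threshold(self):
        cfg = DEConfig(population_size=5, n_filters=1, max_iterations=10)
        res = run_optimization(cfg, lambda v: 0.0)
        assert res.termination_reason == "threshold"
        assert len(res.history) == 1
        assert res.n_evaluations == 5

    def test_sphere_improves_over_initial_population(self):
        b = default_bounds(4)
        fn = sphere_fitness(b)
        wins = 0
        for seed in range(31):
            cfg = DEConfig(population_size=20, max_iterations=30,
                           n_filters=4, seed=seed)
            res = run_optimization(cfg, fn, bounds=b)
            initial_best = res.history[0]["best"]
            if res.best_fitness < initial_best:
                wins += 1
        assert wins >= 30

    def test_best_fitness_non_increasing(self):
        b = default_bounds(2)
        cfg = DEConfig(population_size=8, max_iterations=15, n_filters=2, seed=4)
        res = run_optimization(cfg, sphere_fitness(b), bounds=b)
        bests = [h["best"] for h in res.history]
        assert all(b2 <= b1 + 1e-15 for b1, b2 in zip(bests, bests[1:]))

    def test_same_seed_is_bit_reproducible(self):
        b = default_bounds(2)
        cfg = DEConfig(population_size=8, max_iterations=10, n_filters=2, seed=11)
        r1 = run_optimization(cfg, sphere_fitness(b), bounds=b)
        r2 = run_optimization(cfg, sphere_fitness(b), bounds=b)
        np.testing.assert_array_equal(r1.best_vector, r2.best_vector)
        assert r1.best_fitness == r2.best_fitness
        assert r1.history == r2.history

    def test_every_evaluated_vector_respects_bounds(self):
        b = default_bounds(2)
        seen = []

        def fn(v):
            seen.append(v.copy())
            return sphere_fitness(b)(v)

        cfg = DEConfig(population_size=6, max_iterations=10, n_filters=2, seed=2)
        run_optimization(cfg, fn, bounds=b)
        arr = np.array(seen)
        assert (arr >= b.lower).all() and (arr <= b.upper).all()

    def test_fitness_errors_carry_context(self):
        def bad(v):
            raise RuntimeError("boom")

        cfg = DEConfig(population_size=5, n_filters=1)
        with pytest.raises(RuntimeError, match="generation 0, candidate 0"):
            run_optimization(cfg, bad)
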
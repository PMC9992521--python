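"""Binary whale optimizer: encoding, fitness, moves and the full loop."""

import numpy as np
import pytest

from vewselect import (
    EmptySelectionError,
    FitnessContext,
    GeneSubset,
    WhalePopulation,
    WOAParams,
    binarize_position,
    evaluate_fitness,
    exhaustive_minimum,
    initialize_population,
    run_woa,
    update_position,
    variance_filter,
)
from vewselect.woa import convergence_coefficient


class StubContext:
    """Fitness context with a scripted KNN accuracy, to pin the objective formula."""

    def __init__(self, acc, n_candidates, alpha=0.99):
        self.alpha = alpha
        self.n_candidates = n_candidates
        self.empty_penalty = 1.0
        self._cache = {}
        self._acc = acc

    def knn_accuracy(self, mask):
        return self._acc


class ScriptedRng:
    """Replays pre-recorded draws so each update branch can be forced."""

    def __init__(self, draws):
        self.draws = list(draws)

    def random(self, size=None):
        v = self.draws.pop(0)
        return np.full(size, v) if size is not None else v

    def uniform(self, low, high, size=None):
        v = self.draws.pop(0)
        return np.full(size, v) if size is not None else v

    def integers(self, n):
        return self.draws.pop(0)


class TestInitialization:
    def test_bounds_and_shape(self):
        pop = initialize_population(WOAParams(pop_size=5, seed=7), 3)
        assert pop.positions.shape == (5, 3)
        assert (pop.positions >= 0).all() and (pop.positions <= 1).all()

    def test_same_seed_identical(self):
        a = initialize_population(WOAParams(pop_size=5, seed=7), 3)
        b = initialize_population(WOAParams(pop_size=5, seed=7), 3)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_different_seeds_differ(self):
        for seed in range(10):
            a = initialize_population(WOAParams(pop_size=4, seed=seed), 6)
            b = initialize_population(WOAParams(pop_size=4, seed=seed + 100), 6)
            assert not np.array_equal(a.positions, b.positions)

    def test_empty_search_space(self):
        with pytest.raises(EmptySelectionError):
            initialize_population(WOAParams(), 0)


class TestBinarization:
    def test_all_zeros_never_selected(self):
        rng = np.random.default_rng(0)
        assert binarize_position(np.zeros(50), rng).sum() == 0

    def test_all_ones_always_selected(self):
        rng = np.random.default_rng(0)
        assert binarize_position(np.ones(50), rng).sum() == 50

    def test_half_probability_frequency(self):
        # 10,000 draws at x=0.5: frequency inside the 99% binomial interval
        rng = np.random.default_rng(123)
        draws = np.array([binarize_position(np.array([0.5]), rng)[0]
                          for _ in range(10_000)])
        freq = draws.mean()
        half_width = 2.5758 * np.sqrt(0.25 / 10_000)
        assert abs(freq - 0.5) <= half_width

    def test_out_of_range_position_rejected(self):
        with pytest.raises(ValueError):
            binarize_position(np.array([1.2]), np.random.default_rng(0))


class TestFitness:
    @pytest.mark.parametrize("acc,n_sel,n_cand,expected", [
        (1.0, 1, 100, 0.0001),
        (0.0, 100, 100, 1.0),
        (0.9, 10, 100, 0.1),
    ])
    def test_objective_formula_exact(self, acc, n_sel, n_cand, expected):
        ctx = StubContext(acc, n_cand)
        mask = np.zeros(n_cand, dtype=np.int8)
        mask[:n_sel] = 1
        assert evaluate_fitness(mask, ctx) == pytest.approx(expected, abs=1e-12)

    def test_empty_mask_gets_penalty(self):
        ctx = StubContext(1.0, 10)
        assert evaluate_fitness(np.zeros(10, dtype=np.int8), ctx) == 1.0

    def test_fitness_bounded_on_real_context(self, separable_dataset):
        ctx = FitnessContext.from_dataset(
            separable_dataset, GeneSubset.full(separable_dataset), fold_seed=0)
        rng = np.random.default_rng(1)
        for _ in range(20):
            mask = (rng.random(10) < 0.5).astype(np.int8)
            assert 0.0 <= evaluate_fitness(mask, ctx) <= 1.0


class TestUpdateRules:
    def test_a_schedule_endpoints(self):
        assert convergence_coefficient(0, 100) == 2.0
        assert convergence_coefficient(50, 100) == 1.0
        assert convergence_coefficient(100, 100) == 0.0

    def test_encircling_with_zero_a_returns_best(self):
        # at t = T, a = 0 hence A = 0: the move collapses onto X_q exactly
        params = WOAParams(pop_size=2, max_iter=10)
        pop = WhalePopulation(np.array([[0.2, 0.9], [0.5, 0.5]]),
                              best_position=np.array([0.3, 0.4]),
                              iteration=10)
        rng = ScriptedRng([0.2, 0.7, 0.6])  # p<0.5, rand1, rand2
        np.testing.assert_allclose(update_position(pop, 0, params, rng), [0.3, 0.4])

    def test_spiral_from_best_stays_at_best(self):
        # X_i = X_q makes D' = 0, so the spiral lands on X_q for any l
        params = WOAParams(pop_size=2, max_iter=10)
        best = np.array([0.3, 0.4])
        pop = WhalePopulation(np.array([best.copy(), [0.5, 0.5]]),
                              best_position=best.copy(), iteration=3)
        rng = ScriptedRng([0.9, -0.37])  # p>=0.5, l
        np.testing.assert_allclose(update_position(pop, 0, params, rng), best)

    def test_random_search_uses_another_whale(self):
        # rand1 = 1 at t=0 gives A = a = 2 >= 1: exploration against X_rand
        params = WOAParams(pop_size=3, max_iter=10)
        pop = WhalePopulation(np.array([[0.2, 0.2], [0.6, 0.6], [0.9, 0.1]]),
                              best_position=np.array([0.0, 0.0]), iteration=0)
        rng = ScriptedRng([0.1, 1.0, 0.5, 1])  # p, rand1, rand2 -> C=1, pick index
        out = update_position(pop, 0, params, rng)
        x_rand, x_i = pop.positions[2], pop.positions[0]
        expected = np.clip(x_rand - 2.0 * np.abs(x_rand - x_i), 0, 1)
        np.testing.assert_allclose(out, expected)

    def test_positions_remain_feasible_under_updates(self):
        params = WOAParams(pop_size=6, max_iter=20, seed=3)
        rng = np.random.default_rng(3)
        pop = initialize_population(params, 8, rng=rng)
        pop.best_position = pop.positions[0].copy()
        for t in range(20):
            pop.iteration = t
            for i in range(6):
                pop.positions[i] = update_position(pop, i, params, rng)
                assert (pop.positions[i] >= 0).all() and (pop.positions[i] <= 1).all()


class TestRunWOA:
    @pytest.fixture
    def context(self, separable_dataset):
        subset = variance_filter(separable_dataset, 0.05)
        return FitnessContext.from_dataset(separable_dataset, subset, fold_seed=0), subset

    def test_trace_non_increasing_and_deterministic(self, context):
        ctx, _ = context
        params = WOAParams(pop_size=8, max_iter=15, seed=2)
        a = run_woa(ctx, params)
        b = run_woa(ctx, params)
        np.testing.assert_array_equal(a.mask, b.mask)
        assert a.trace == b.trace
        assert all(x >= y for x, y in zip(a.trace, a.trace[1:]))
        assert 0.0 <= a.fitness <= 1.0

    def test_informative_gene_selected(self, separable_dataset, context):
        ctx, subset = context
        hits = 0
        for seed in range(10):
            result = run_woa(ctx, WOAParams(pop_size=10, max_iter=25, seed=seed))
            chosen = result.selected(subset)
            hits += 0 in chosen.indices
        assert hits >= 9

    def test_never_beats_exhaustive_minimum(self, separable_dataset):
        subset = GeneSubset.from_dataset(separable_dataset, range(8), "custom")
        ctx = FitnessContext.from_dataset(separable_dataset, subset, fold_seed=1)
        _, oracle_best = exhaustive_minimum(ctx)
        for seed in range(3):
            result = run_woa(ctx, WOAParams(pop_size=10, max_iter=30, seed=seed))
            assert result.fitness >= oracle_best - 1e-15

    def test_selected_maps_to_original_coordinates(self, context):
        ctx, subset = context
        result = run_woa(ctx, WOAParams(pop_size=6, max_iter=10, seed=0))
        chosen = result.selected(subset)
        assert chosen.issubset(subset)
        assert chosen.stage_label == "woa"
        assert len(chosen) == result.n_selected
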
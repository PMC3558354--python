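"""GA operators: constraint preservation, determinism, elitism, convergence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vaxopt as v
from vaxopt.fitness import FitnessValue
from vaxopt.ga import (GAConfig, crossover, evolve_generation,
                       init_population, mutate, run_ga, tournament_select)
from vaxopt.schedule import Schedule


@pytest.fixture
def grid():
    return v.make_time_grid(28, 24, [0, 3])  # 8 admissible slots


@pytest.fixture
def cfg():
    return GAConfig(population_size=6, generations=5, cohort_size=2,
                    master_seed=7)


def surrogate_evaluator(target):
    """Fitness = number of admissible genes matching a hidden target."""
    def _eval(population):
        out = []
        for s in population:
            matches = int((s.genes == target).sum())
            out.append(FitnessValue(matches, 0.0, 0.0,
                                    cohort_size=target.size))
        return out
    return _eval


class TestInitPopulation:
    def test_size_and_validity(self, cfg, grid, rng):
        pop = init_population(cfg, grid, rng)
        assert len(pop) == cfg.population_size
        assert all(v.validate_schedule(s) == [] for s in pop)

    def test_same_seed_identical_population(self, cfg, grid):
        p1 = init_population(cfg, grid, np.random.default_rng(3))
        p2 = init_population(cfg, grid, np.random.default_rng(3))
        assert all(a == b for a, b in zip(p1, p2))

    def test_zero_admissible_slots_all_zero_genomes(self, cfg):
        empty = v.make_time_grid(28, 24, [])
        pop = init_population(cfg, empty, np.random.default_rng(0))
        assert all(s.x.sum() == 0 for s in pop)


class TestTournament:
    def test_population_of_one(self, grid, rng):
        cfg = GAConfig(population_size=2, tournament_size=1)
        pop = [Schedule.zeros(grid)]
        fits = [FitnessValue(1, 0, 0, 2)]
        assert tournament_select(pop, fits, cfg, rng) == pop[0]

    def test_full_tournament_returns_global_best(self, grid):
        # tournament covering the whole population must return the best,
        # checked over many RNG draws on a 4-individual population
        cfg = GAConfig(population_size=4, tournament_size=32)
        genes = np.eye(8, dtype=np.uint8)[:4]
        pop = [Schedule.from_genes(grid, g) for g in genes]
        fits = [FitnessValue(i, 0, 0, 8) for i in (1, 3, 0, 2)]
        rng = np.random.default_rng(0)
        for _ in range(10):
            assert tournament_select(pop, fits, cfg, rng) == pop[1]

    def test_equal_fitness_breaks_ties_by_genome(self, grid):
        cfg = GAConfig(population_size=2, tournament_size=8)
        pop = [Schedule.from_genes(grid, np.array([1, 0, 0, 0, 0, 0, 0, 0])),
               Schedule.from_genes(grid, np.array([0, 1, 0, 0, 0, 0, 0, 0]))]
        fits = [FitnessValue(1, 0, 0, 8)] * 2
        rng = np.random.default_rng(1)
        picks = {tournament_select(pop, fits, cfg, rng) for _ in range(10)}
        assert picks == {pop[1]}  # lexicographically smaller genome wins


class TestCrossover:
    def test_identical_parents_give_identical_children(self, grid, rng):
        cfg = GAConfig(population_size=2, crossover_rate=1.0)
        s = Schedule.from_genes(grid, np.ones(8, np.uint8))
        c1, c2 = crossover(s, s, cfg, rng)
        assert c1 == s and c2 == s

    def test_rate_zero_copies_parents(self, grid, rng):
        cfg = GAConfig(population_size=2, crossover_rate=0.0)
        a = Schedule.from_genes(grid, np.zeros(8, np.uint8))
        b = Schedule.from_genes(grid, np.ones(8, np.uint8))
        c1, c2 = crossover(a, b, cfg, rng)
        assert c1 == a and c2 == b

    def test_complementary_parents_give_complementary_children(self, grid, rng):
        cfg = GAConfig(population_size=2, crossover_rate=1.0)
        a = Schedule.from_genes(grid, np.zeros(8, np.uint8))
        b = Schedule.from_genes(grid, np.ones(8, np.uint8))
        c1, c2 = crossover(a, b, cfg, rng)
        assert np.array_equal(c1.genes ^ c2.genes, np.ones(8, np.uint8))

    def test_grid_mismatch_rejected(self, grid, rng):
        other = v.make_time_grid(28, 24, [0])
        cfg = GAConfig(population_size=2)
        with pytest.raises(ValueError):
            crossover(Schedule.zeros(grid), Schedule.zeros(other), cfg, rng)


class TestMutate:
    def test_rate_zero_is_identity(self, grid, rng):
        cfg = GAConfig(population_size=2, mutation_rate=0.0)
        s = Schedule.from_genes(grid, np.ones(8, np.uint8))
        assert mutate(s, cfg, rng) == s

    def test_rate_one_flips_every_admissible_gene(self, grid, rng):
        cfg = GAConfig(population_size=2, mutation_rate=1.0)
        s = Schedule.from_genes(grid, np.zeros(8, np.uint8))
        assert np.array_equal(mutate(s, cfg, rng).genes, np.ones(8))

    def test_default_rate_expected_one_flip(self, monthu_grid):
        # rate 1/114 over 114 genes: mean flips over trials ~ 1
        cfg = GAConfig(population_size=2)
        s = Schedule.zeros(monthu_grid)
        rng = np.random.default_rng(99)
        n_trials = 10_000
        flips = np.array([mutate(s, cfg, rng).genes.sum()
                          for i in range(n_trials)])
        se = np.sqrt(1.0 * (1 - 1 / 114) / n_trials)
        assert abs(flips.mean() - 1.0) < 3 * se

    def test_inadmissible_genes_untouched(self, monthu_grid, rng):
        cfg = GAConfig(population_size=2, mutation_rate=1.0)
        m = mutate(Schedule.zeros(monthu_grid), cfg, rng)
        assert v.validate_schedule(m) == []


class TestEvolveGeneration:
    def test_selection_only_yields_parent_multiset(self, grid, rng):
        cfg = GAConfig(population_size=6, crossover_rate=0.0,
                       mutation_rate=0.0, elite_count=1)
        pop = init_population(cfg, grid, rng)
        fits = [FitnessValue(i % 3, 0, 0, 8) for i in range(6)]
        nxt = evolve_generation(pop, fits, cfg, grid, rng)
        parents = {s.x.tobytes() for s in pop}
        assert len(nxt) == 6
        assert all(s.x.tobytes() in parents for s in nxt)

    def test_elite_genome_survives(self, grid, rng):
        cfg = GAConfig(population_size=6, elite_count=1, master_seed=1)
        pop = init_population(cfg, grid, rng)
        fits = [FitnessValue(i, 0, 0, 8) for i in (0, 5, 1, 2, 3, 4)]
        nxt = evolve_generation(pop, fits, cfg, grid, rng)
        assert nxt[0] == pop[1]

    @given(seed=st.integers(0, 1000), pop_size=st.integers(2, 10),
           cx=st.floats(0, 1), mut=st.floats(0, 1))
    @settings(max_examples=25, deadline=None)
    def test_offspring_always_valid_and_sized(self, seed, pop_size, cx, mut):
        grid = v.make_time_grid(28, 24, [0, 3])
        cfg = GAConfig(population_size=pop_size, crossover_rate=cx,
                       mutation_rate=mut)
        rng = np.random.default_rng(seed)
        pop = init_population(cfg, grid, rng)
        fits = [FitnessValue(int(s.genes.sum()), 0, 0, 8) for s in pop]
        nxt = evolve_generation(pop, fits, cfg, grid, rng)
        assert len(nxt) == pop_size
        assert all(v.validate_schedule(s) == [] for s in nxt)


class TestRunGA:
    def test_zero_generations_history_has_initial_entry_only(self, grid):
        cfg = GAConfig(population_size=4, generations=0, master_seed=0)
        target = np.ones(8, np.uint8)
        h = run_ga(cfg, grid, surrogate_evaluator(target))
        assert len(h.best_fitness) == 1

    def test_history_reproducible_for_same_master_seed(self, grid):
        cfg = GAConfig(population_size=8, generations=10, master_seed=42)
        target = (np.arange(8) % 2).astype(np.uint8)
        h1 = run_ga(cfg, grid, surrogate_evaluator(target))
        h2 = run_ga(cfg, grid, surrogate_evaluator(target))
        assert [f.scalar for f in h1.best_fitness] == \
               [f.scalar for f in h2.best_fitness]
        assert all(np.array_equal(a, b) for a, b in
                   zip(h1.best_genome, h2.best_genome))

    def test_best_scalar_non_decreasing_with_elitism(self, grid):
        cfg = GAConfig(population_size=8, generations=15, master_seed=3)
        target = np.ones(8, np.uint8)
        h = run_ga(cfg, grid, surrogate_evaluator(target))
        best = [f.scalar for f in h.best_fitness]
        assert all(b >= a for a, b in zip(best, best[1:]))

    def test_reaches_optimum_on_small_matching_problem(self, grid):
        cfg = GAConfig(population_size=12, generations=30, master_seed=5)
        target = np.array([1, 0, 1, 1, 0, 0, 1, 0], np.uint8)
        h = run_ga(cfg, grid, surrogate_evaluator(target))
        assert h.best_fitness[-1].survivors == 8
        assert np.array_equal(h.best_schedule(grid).genes, target)

    def test_evaluator_failure_reports_generation(self, grid):
        cfg = GAConfig(population_size=4, generations=3, master_seed=0)

        def broken(population):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="generation 0"):
            run_ga(cfg, grid, broken)
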
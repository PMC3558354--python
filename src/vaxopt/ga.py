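"""Genetic algorithm over vaccination-schedule genomes.

Individuals are binary schedules; all variation operators act on the
*compressed* admissible-gene vector (length = number of admissible slots,
114 on the default grid), so every individual in every generation
satisfies the admissibility constraint by construction.  Operators are
the standard constraint-preserving trio: tournament selection (size 2),
uniform crossover, independent per-gene flips; elitism copies the best
individual unchanged, which makes best-so-far fitness monotone.

RNG discipline: a single evolution stream is derived from
``GAConfig.master_seed`` and consumed only by master-phase operators
(initialization, selection, variation).  Fitness randomness comes
exclusively from the fixed cohort seeds, so evaluation parallelism cannot
perturb the evolution and a run is bit-reproducible for any worker count.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitness import FitnessValue, rank_key
from .schedule import Schedule, TimeGrid, count_administrations

__all__ = ["GAConfig", "GAHistory", "init_population", "tournament_select",
           "crossover", "mutate", "evolve_generation", "run_ga"]


@dataclass
class GAConfig:
    """Parameters of the genetic algorithm.

    ``mutation_rate=None`` resolves to 1/L with L the number of admissible
    genes (one expected flip per genome).
    """

    population_size: int = 80
    generations: int = 150
    cohort_size: int = 8
    crossover_rate: float = 0.7
    mutation_rate: float | None = None
    tournament_size: int = 2
    elite_count: int = 1
    master_seed: int = 0

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0 <= self.elite_count < self.population_size:
            raise ValueError("elite_count must be in 0..population_size-1")
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.generations < 0 or self.cohort_size < 1:
            raise ValueError("generations must be >= 0 and cohort_size >= 1")
        if self.tournament_size < 1:
            raise ValueError("tournament_size must be >= 1")

    def resolved_mutation_rate(self, grid: TimeGrid) -> float:
        if self.mutation_rate is not None:
            return self.mutation_rate
        n_adm = int(grid.admissible_mask.sum())
        return 1.0 / n_adm if n_adm else 0.0


@dataclass
class GAHistory:
    """Per-generation record of a GA run (index 0 = initial population)."""

    best_fitness: list = field(default_factory=list)
    mean_scalar: list = field(default_factory=list)
    best_genome: list = field(default_factory=list)      # full x vectors
    timings: list = field(default_factory=list)          # seconds/generation
    generation_fitness: list = field(default_factory=list)

    def record(self, population, fitnesses, elapsed: float):
        keys = [rank_key(f, s.genes) for s, f in zip(population, fitnesses)]
        best = min(range(len(keys)), key=keys.__getitem__)
        self.best_fitness.append(fitnesses[best])
        self.mean_scalar.append(float(np.mean([f.scalar for f in fitnesses])))
        self.best_genome.append(population[best].x.copy())
        self.timings.append(elapsed)
        self.generation_fitness.append(list(fitnesses))

    @property
    def n_generations(self) -> int:
        return len(self.best_fitness) - 1

    def best_schedule(self, grid: TimeGrid) -> Schedule:
        return Schedule(grid, self.best_genome[-1])

    def to_frame(self, grid: TimeGrid) -> pd.DataFrame:
        """History CSV shape: generation, best_scalar, mean_scalar,
        best_n_administrations (timing is logged separately)."""
        return pd.DataFrame({
            "generation": np.arange(len(self.best_fitness)),
            "best_scalar": [f.scalar for f in self.best_fitness],
            "mean_scalar": self.mean_scalar,
            "best_n_administrations": [
                count_administrations(Schedule(grid, g))
                for g in self.best_genome],
        })

    def fitness_report(self, grid: TimeGrid) -> pd.DataFrame:
        """Individual-level fitness report over all generations."""
        rows = []
        for g, fits in enumerate(self.generation_fitness):
            for i, f in enumerate(fits):
                rows.append((g, i, f.survivors, f.burden_penalty,
                             f.dose_penalty, f.scalar))
        return pd.DataFrame(rows, columns=[
            "generation", "individual_id", "survivors", "burden_penalty",
            "dose_penalty", "scalar"])


def init_population(cfg: GAConfig, grid: TimeGrid,
                    rng: np.random.Generator) -> list:
    """Independent Bernoulli(0.5) draws on admissible genes; inadmissible
    slots are zero by construction."""
    n_adm = int(grid.admissible_mask.sum())
    genes = (rng.random((cfg.population_size, n_adm)) < 0.5).astype(np.uint8)
    return [Schedule.from_genes(grid, g) for g in genes]


def tournament_select(population, fitnesses, cfg: GAConfig,
                      rng: np.random.Generator) -> Schedule:
    """Sample ``tournament_size`` individuals with replacement, return the
    best (ties broken deterministically by genome order)."""
    if not population:
        raise RuntimeError("cannot select from an empty population")
    idx = rng.integers(0, len(population), cfg.tournament_size)
    best = min(idx, key=lambda i: rank_key(fitnesses[i], population[i].genes))
    return population[best]


def crossover(a: Schedule, b: Schedule, cfg: GAConfig,
              rng: np.random.Generator) -> tuple:
    """Uniform crossover on admissible genes with probability
    ``crossover_rate``; otherwise parent copies.  Children are always
    valid schedules."""
    if a.grid != b.grid:
        raise ValueError("cannot cross schedules on different grids")
    ga_, gb = a.genes, b.genes
    if rng.random() >= cfg.crossover_rate:
        return (Schedule.from_genes(a.grid, ga_.copy()),
                Schedule.from_genes(a.grid, gb.copy()))
    take_a = rng.random(ga_.size) < 0.5
    c1 = np.where(take_a, ga_, gb).astype(np.uint8)
    c2 = np.where(take_a, gb, ga_).astype(np.uint8)
    return Schedule.from_genes(a.grid, c1), Schedule.from_genes(a.grid, c2)


def mutate(s: Schedule, cfg: GAConfig, rng: np.random.Generator) -> Schedule:
    """Flip each admissible gene independently with the mutation rate."""
    rate = cfg.resolved_mutation_rate(s.grid)
    genes = s.genes.copy()
    if genes.size:
        flip = rng.random(genes.size) < rate
        genes[flip] ^= 1
    return Schedule.from_genes(s.grid, genes)


def evolve_generation(population, fitnesses, cfg: GAConfig, grid: TimeGrid,
                      rng: np.random.Generator) -> list:
    """One generation: copy elites unchanged, fill the rest via
    select -> crossover -> mutate.  Output size = population size."""
    order = sorted(range(len(population)),
                   key=lambda i: rank_key(fitnesses[i], population[i].genes))
    nxt = [population[order[i]] for i in range(cfg.elite_count)]
    while len(nxt) < cfg.population_size:
        p1 = tournament_select(population, fitnesses, cfg, rng)
        p2 = tournament_select(population, fitnesses, cfg, rng)
        c1, c2 = crossover(p1, p2, cfg, rng)
        nxt.append(mutate(c1, cfg, rng))
        if len(nxt) < cfg.population_size:
            nxt.append(mutate(c2, cfg, rng))
    return nxt


def run_ga(cfg: GAConfig, grid: TimeGrid, evaluator,
           log=None) -> GAHistory:
    """Full GA loop.

    ``evaluator`` maps a list of schedules to a list of
    :class:`FitnessValue` and must be a pure function of the schedules
    (all its randomness fixed, e.g. by cohort seeds); the evolution stream
    is derived from ``cfg.master_seed`` alone, so the history is
    bit-reproducible regardless of how the evaluator parallelizes.
    ``log``, if given, is called with one dict per generation.
    """
    rng = np.random.default_rng(int(cfg.master_seed))
    history = GAHistory()
    population = init_population(cfg, grid, rng)
    t0 = time.perf_counter()
    fitnesses = _checked(evaluator, population, generation=0)
    history.record(population, fitnesses, time.perf_counter() - t0)
    for gen in range(1, cfg.generations + 1):
        t0 = time.perf_counter()
        population = evolve_generation(population, fitnesses, cfg, grid, rng)
        fitnesses = _checked(evaluator, population, generation=gen)
        history.record(population, fitnesses, time.perf_counter() - t0)
        if log is not None:
            log({"generation": gen,
                 "best_scalar": history.best_fitness[-1].scalar,
                 "T_g": history.timings[-1]})
    return history


def _checked(evaluator, population, generation):
    try:
        fitnesses = evaluator(population)
    except Exception as exc:
        raise RuntimeError(
            f"fitness evaluation failed in generation {generation}: {exc}"
        ) from exc
    if len(fitnesses) != len(population):
        raise RuntimeError(
            f"evaluator returned {len(fitnesses)} fitness values for "
            f"{len(population)} individuals in generation {generation}")
    return fitnesses
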
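"""Master-slave fitness evaluation and the generation-time cost model.

Each generation the master broadcasts the population, workers evaluate
their statically assigned block of (individual, mouse) tasks, and the
master gathers the per-task results and aggregates them into per-individual
fitness values.  Because every task carries its own mouse seed, results
are independent of worker count, chunking and completion order, and every
backend is bit-equivalent to the serial reference.

Three backends satisfy the same contract: :class:`SerialBackend` (the
reference), :class:`ProcessPoolBackend` (multi-process pools), and
:class:`ScriptedBackend` (serial evaluation returned in a scrambled
completion order, for testing gather logic).  Message-passing runtimes
would slot in behind the same contract.

Wall clocks are hardware-bound, so per-generation runtime is described by
an analytic cost model instead:

    T_g = T_master(P) + T_sync(c) + ceil(P*M / c) * T_fit

with population P, cohort size M, worker count c, per-simulation time
T_fit, serial master work T_master and synchronization overhead T_sync.
It reproduces the qualitative structure of measured scaling: a linear
regime in 1/c and a plateau T_master + T_sync + T_fit beyond c >= P*M,
which grows with P because master-phase evolution cannot be parallelized.
"""

from __future__ import annotations

import math
from concurrent.futures import ProcessPoolExecutor, as_completed
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd

from . import fitness as _fitness
from . import simulator as _simulator

__all__ = ["Task", "EvaluationError", "build_tasks", "partition",
           "SerialBackend", "ProcessPoolBackend", "ScriptedBackend",
           "evaluate_population", "cohort_evaluator", "CostModelParams",
           "linear_cost_model", "GenerationTiming",
           "predict_generation_time", "estimate_total_runtime",
           "benchmark_workers"]


class Task(NamedTuple):
    """One fitness sub-job: run one mouse of one individual's cohort."""

    individual_index: int
    mouse_index: int
    mouse_seed: int


class EvaluationError(RuntimeError):
    """A worker failed; the generation's partial results are discarded."""


def build_tasks(population_size: int, seeds) -> list:
    """The P*M task list of one generation, row-major by individual."""
    if population_size < 1 or len(seeds) < 1:
        raise ValueError("need at least one individual and one cohort seed")
    return [Task(i, j, int(seed))
            for i in range(population_size)
            for j, seed in enumerate(seeds)]


def partition(tasks, workers: int) -> list:
    """Static block partition: every task to exactly one worker, chunk
    sizes differing by at most one."""
    if workers < 1:
        raise ValueError("worker count must be >= 1")
    n = len(tasks)
    base, extra = divmod(n, workers)
    chunks, lo = [], 0
    for w in range(workers):
        hi = lo + base + (1 if w < extra else 0)
        chunks.append(list(tasks[lo:hi]))
        lo = hi
    return chunks


def _run_task_block(params, payload):
    """Worker entry point: evaluate a block of (task_id, schedule, seed)."""
    out = []
    for task_id, sched, seed in payload:
        out.append((task_id, _simulator.run_mouse(params, sched, seed)))
    return out


class SerialBackend:
    """Reference backend: the master evaluates every task itself."""

    n_workers = 1

    def run_tasks(self, params, payload):
        return _run_task_block(params, payload)

    def close(self):
        pass


class ProcessPoolBackend:
    """Process-pool backend; the pool is created lazily and reused across
    generations.  Usable as a context manager."""

    def __init__(self, n_workers: int):
        if n_workers < 1:
            raise ValueError("worker count must be >= 1")
        self.n_workers = int(n_workers)
        self._pool = None

    def run_tasks(self, params, payload):
        if self._pool is None:
            self._pool = ProcessPoolExecutor(max_workers=self.n_workers)
        chunks = [c for c in partition(payload, self.n_workers) if c]
        futures = [self._pool.submit(_run_task_block, params, c) for c in chunks]
        results = []
        for fut in as_completed(futures):
            try:
                results.extend(fut.result())
            except Exception as exc:
                for other in futures:
                    other.cancel()
                raise EvaluationError(f"worker failed: {exc}") from exc
        results.sort(key=lambda pair: pair[0])
        return results

    def close(self):
        if self._pool is not None:
            self._pool.shutdown()
            self._pool = None

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


class ScriptedBackend:
    """Serial evaluation returned in a scripted (permuted) completion
    order; exercises the master's order-independent gather."""

    n_workers = 1

    def __init__(self, permutation_seed: int = 0):
        self.permutation_seed = permutation_seed

    def run_tasks(self, params, payload):
        results = _run_task_block(params, payload)
        order = np.random.default_rng(self.permutation_seed).permutation(
            len(results))
        shuffled = [results[i] for i in order]
        shuffled.sort(key=lambda pair: pair[0])
        return shuffled

    def close(self):
        pass


def evaluate_population(population, params, seeds, backend=None,
                        weights=_fitness.DEFAULT_WEIGHTS) -> list:
    """Broadcast-evaluate-gather for one generation.

    Returns fitness values aligned with population order, bit-identical
    across backends and worker counts.
    """
    backend = backend or SerialBackend()
    tasks = build_tasks(len(population), seeds)
    payload = [(tid, population[t.individual_index], t.mouse_seed)
               for tid, t in enumerate(tasks)]
    gathered = backend.run_tasks(params, payload)
    if sorted(tid for tid, _ in gathered) != list(range(len(tasks))):
        raise EvaluationError("backend returned an incomplete task set")
    by_id = dict(gathered)
    m = len(seeds)
    out = []
    for i, sched in enumerate(population):
        cohort = [by_id[i * m + j] for j in range(m)]
        out.append(_fitness.aggregate(cohort, sched,
                                      params.palpable_threshold, weights))
    return out


def cohort_evaluator(params, seeds, backend=None,
                     weights=_fitness.DEFAULT_WEIGHTS) -> Callable:
    """An evaluator for :func:`vaxopt.ga.run_ga` closing over fixed cohort
    seeds and a backend."""
    def _evaluate(population):
        return evaluate_population(population, params, seeds, backend, weights)
    return _evaluate


# ---------------------------------------------------------------------------
# analytic cost model

@dataclass
class CostModelParams:
    """Components of per-generation runtime.

    ``t_master`` maps population size to serial master seconds (defaults
    to a linear operation-count proxy), ``t_sync`` maps worker count to
    synchronization seconds (defaults to a constant; an optional log term
    is available through :func:`linear_cost_model`).
    """

    t_fit: float = 30.0
    t_master: Callable = field(default=None)
    t_sync: Callable = field(default=None)

    def __post_init__(self):
        if self.t_fit < 0:
            raise ValueError("t_fit must be >= 0")
        if self.t_master is None:
            self.t_master = lambda P: 0.05 * P
        if self.t_sync is None:
            self.t_sync = lambda c: 1.0


def linear_cost_model(t_fit: float = 30.0, alpha_master: float = 0.05,
                      sync_base: float = 1.0,
                      sync_log: float = 0.0) -> CostModelParams:
    """T_master(P) = alpha*P and T_sync(c) = base + log2(c)*slope."""
    return CostModelParams(
        t_fit=t_fit,
        t_master=lambda P: alpha_master * P,
        t_sync=lambda c: sync_base + sync_log * math.log2(c))


@dataclass(frozen=True)
class GenerationTiming:
    """One generation's predicted or measured runtime."""

    generation: int
    t_g: float
    n_workers: int

    def __post_init__(self):
        if self.t_g <= 0:
            raise ValueError("t_g must be positive")


def predict_generation_time(cm: CostModelParams, P: int, M: int,
                            c: int) -> float:
    """T_g = T_master(P) + T_sync(c) + ceil(P*M/c) * T_fit."""
    if c < 1:
        raise ValueError("worker count must be >= 1")
    return (cm.t_master(P) + cm.t_sync(c)
            + math.ceil(P * M / c) * cm.t_fit)


def estimate_total_runtime(M: int, P: int, G: int, t_fit: float) -> float:
    """Single-CPU cost of a full optimization: M*P*G*T_fit seconds
    (cohort size x population x generations x per-simulation time)."""
    if min(M, P, G) < 1 or t_fit <= 0:
        raise ValueError("M, P, G must be >= 1 and t_fit > 0")
    return M * P * G * t_fit


def benchmark_workers(population, params, seeds, worker_counts,
                      cost_model: CostModelParams | None = None,
                      measured_t_fit: float | None = None) -> pd.DataFrame:
    """Measure one generation's evaluation wall time per worker count on a
    reduced workload, next to the cost model's prediction."""
    import time

    rows = []
    for c in worker_counts:
        backend = SerialBackend() if c == 1 else ProcessPoolBackend(c)
        try:
            t0 = time.perf_counter()
            evaluate_population(population, params, seeds, backend)
            elapsed = time.perf_counter() - t0
        finally:
            backend.close()
        cm = cost_model
        if cm is None:
            t_fit = (measured_t_fit if measured_t_fit is not None
                     else elapsed * c / (len(population) * len(seeds)))
            cm = linear_cost_model(t_fit=t_fit, alpha_master=0.0, sync_base=0.0)
        rows.append((c, len(population), elapsed,
                     predict_generation_time(cm, len(population),
                                             len(seeds), c)))
    return pd.DataFrame(rows, columns=["n_workers", "n_individuals",
                                       "time_per_generation", "predicted_T_g"])
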
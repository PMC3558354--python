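"""Cohort-level scoring of vaccination schedules.

A candidate schedule is applied to a fixed cohort of virtual mice (same
seeds for every candidate and every generation) and scored by, in order of
importance: how many mice it protects, how much tumor burden the cohort
accumulated, and how many administrations it spends.  The scalarization

    scalar = w1 * survivors - w2 * burden_penalty - w3 * dose_penalty

with w1 > w2 + w3 makes protection lexicographically dominant: a schedule
protecting more mice always outranks one protecting fewer, no matter the
penalties.  Both penalties are dimensionless in [0, 1]: mean peak burden
over mice relative to the palpable threshold (capped at 1), and number of
administrations relative to the number of admissible slots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schedule import Schedule, count_administrations, log2_search_space
from .simulator import SimParams, run_cohort

__all__ = ["DEFAULT_WEIGHTS", "FitnessValue", "validate_weights",
           "aggregate", "evaluate_schedule", "compare", "rank_key"]

#: (w1, w2, w3) — protection reward, burden penalty, dose penalty.
DEFAULT_WEIGHTS = (10.0, 1.0, 1.0)


def validate_weights(weights) -> tuple:
    """Check the survivor-dominance condition w1 > w2 + w3."""
    w1, w2, w3 = (float(w) for w in weights)
    if min(w1, w2, w3) < 0:
        raise ValueError(f"fitness weights must be non-negative, got {weights}")
    if not w1 > w2 + w3:
        raise ValueError(
            f"survivor dominance requires w1 > w2 + w3, got {weights}")
    return (w1, w2, w3)


@dataclass(frozen=True)
class FitnessValue:
    """Cohort-level score of one schedule."""

    survivors: int
    burden_penalty: float
    dose_penalty: float
    cohort_size: int
    weights: tuple = DEFAULT_WEIGHTS

    def __post_init__(self):
        if not 0 <= self.survivors <= self.cohort_size:
            raise ValueError(
                f"survivors {self.survivors} outside 0..{self.cohort_size}")
        for name in ("burden_penalty", "dose_penalty"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def scalar(self) -> float:
        w1, w2, w3 = self.weights
        return (w1 * self.survivors - w2 * self.burden_penalty
                - w3 * self.dose_penalty)


def aggregate(results, s: Schedule, palpable_threshold: int,
              weights=DEFAULT_WEIGHTS) -> FitnessValue:
    """Fold per-mouse outcomes into a :class:`FitnessValue`.

    Kept separate from :func:`evaluate_schedule` so the parallel master can
    aggregate worker results without re-running the simulator.
    """
    weights = validate_weights(weights)
    survivors = sum(1 for r in results if r.survived)
    if results:
        burden = float(np.mean([min(r.peak_burden / palpable_threshold, 1.0)
                                for r in results]))
    else:
        burden = 0.0
    admissible = log2_search_space(s.grid)
    dose = count_administrations(s) / admissible if admissible else 0.0
    return FitnessValue(survivors=survivors, burden_penalty=burden,
                        dose_penalty=dose, cohort_size=len(results),
                        weights=weights)


def evaluate_schedule(s: Schedule, params: SimParams, seeds,
                      weights=DEFAULT_WEIGHTS) -> FitnessValue:
    """Run the cohort and aggregate; a pure function of (s, params, seeds)."""
    return aggregate(run_cohort(params, s, seeds), s,
                     params.palpable_threshold, weights)


def rank_key(fv: FitnessValue, genome: np.ndarray | None = None) -> tuple:
    """Sort key under which the *best* fitness is the minimum.

    Orders by scalar, ties broken by more survivors, lower dose penalty,
    lower burden penalty, then (optionally) lexicographically smaller
    genome for full determinism.
    """
    key = (-fv.scalar, -fv.survivors, fv.dose_penalty, fv.burden_penalty)
    if genome is not None:
        key = key + (np.asarray(genome, np.uint8).tobytes(),)
    return key


def compare(a: FitnessValue, b: FitnessValue) -> int:
    """Three-way comparison: positive if ``a`` ranks above ``b``."""
    if a.cohort_size != b.cohort_size:
        raise ValueError(
            f"cannot compare fitness over cohorts of size "
            f"{a.cohort_size} and {b.cohort_size}")
    if a.weights != b.weights:
        raise ValueError("cannot compare fitness computed with different weights")
    ka, kb = rank_key(a), rank_key(b)
    return (kb > ka) - (ka > kb)
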
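"""Discrete vaccination-schedule search space.

A protocol over a horizon of ``T`` days is encoded as a binary vector on a
regular time grid: slot ``i`` covers the half-open interval
``[t_i, t_i + dt)`` (0-based, slot 0 starts at day 0, hour 0) and
``x_i = 1`` means one fixed-quantity vaccine administration in that slot.
Wet-lab constraints — administrations allowed only on certain weekdays,
classically Monday and Thursday — enter as a per-slot admissibility mask,
and the base-2 logarithm of the search-space cardinality is simply the
number of admissible slots.  On a 400-day daily grid this takes the search
space from 2^400 down to 2^114 under the twice-a-week constraint.

The reference *chronic* protocol used in immunoprevention experiments is
also built here: 4-week cycles with administrations on every admissible
slot of each cycle's first two weeks (four shots per full cycle on a
Mon/Thu grid), starting at six weeks of age.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MONDAY", "TUESDAY", "WEDNESDAY", "THURSDAY", "FRIDAY", "SATURDAY",
    "SUNDAY", "WEEKDAY_NAMES", "DEFAULT_START_WEEKDAY", "TimeGrid",
    "Schedule", "ScheduleFormatError", "make_time_grid", "log2_search_space",
    "count_administrations", "chronic_protocol", "validate_schedule",
    "read_schedule", "write_schedule",
]

MONDAY, TUESDAY, WEDNESDAY, THURSDAY, FRIDAY, SATURDAY, SUNDAY = range(7)
WEEKDAY_NAMES = ("monday", "tuesday", "wednesday", "thursday", "friday",
                 "saturday", "sunday")

#: Calendar anchoring of day 0.  A Friday start makes both Monday and
#: Thursday occur exactly floor(400/7) = 57 times over a 400-day horizon,
#: reproducing the canonical 2^114 count for the twice-a-week constraint.
#: The count is alignment-dependent (a Monday or Thursday start would give
#: 115); the anchor is configurable everywhere.
DEFAULT_START_WEEKDAY = FRIDAY


class ScheduleFormatError(ValueError):
    """A schedule file could not be parsed or is internally inconsistent."""


@dataclass(frozen=True, eq=False)
class TimeGrid:
    """Discretization of ``[0, T]`` with a per-slot admissibility mask.

    Attributes
    ----------
    T_days : int
        Horizon in days.
    dt_hours : int
        Slot width in hours; ``N = floor(T*24 / dt)`` slots.
    start_weekday : int
        Weekday (0=Monday .. 6=Sunday) of day 0.
    admissible_weekdays : frozenset[int]
        Weekdays on which administration is permitted.
    """

    T_days: int
    dt_hours: int
    start_weekday: int
    admissible_weekdays: frozenset
    n_slots: int = field(init=False)
    slot_times: np.ndarray = field(init=False, repr=False)
    admissible_mask: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        n = int(self.T_days) * 24 // int(self.dt_hours)
        times = np.arange(n, dtype=np.int64) * int(self.dt_hours)
        days = times // 24
        weekdays = (days + self.start_weekday) % 7
        mask = np.isin(weekdays, sorted(self.admissible_weekdays))
        if self.dt_hours < 24:
            # sub-daily grid: only the first slot of an admissible day
            mask &= times % 24 == 0
        object.__setattr__(self, "n_slots", n)
        object.__setattr__(self, "slot_times", times)
        object.__setattr__(self, "admissible_mask", mask)

    @property
    def key(self):
        return (self.T_days, self.dt_hours, self.start_weekday,
                tuple(sorted(self.admissible_weekdays)))

    def __eq__(self, other):
        return isinstance(other, TimeGrid) and self.key == other.key

    def __hash__(self):
        return hash(self.key)

    @property
    def admissible_indices(self) -> np.ndarray:
        """Slot indices where administration is permitted."""
        return np.nonzero(self.admissible_mask)[0]

    def weekday_of_slot(self, i: int) -> int:
        return int((self.slot_times[i] // 24 + self.start_weekday) % 7)


@dataclass(frozen=True, eq=False)
class Schedule:
    """A binary administration vector over a :class:`TimeGrid`."""

    grid: TimeGrid
    x: np.ndarray  # uint8, length grid.n_slots

    def __post_init__(self):
        x = np.asarray(self.x, dtype=np.uint8)
        object.__setattr__(self, "x", x)

    def __eq__(self, other):
        return (isinstance(other, Schedule) and self.grid == other.grid
                and np.array_equal(self.x, other.x))

    def __hash__(self):
        return hash((self.grid, self.x.tobytes()))

    @property
    def genes(self) -> np.ndarray:
        """The compressed admissible-slot view (the GA genome)."""
        return self.x[self.grid.admissible_indices]

    @classmethod
    def from_genes(cls, grid: TimeGrid, genes: np.ndarray) -> "Schedule":
        genes = np.asarray(genes, dtype=np.uint8)
        idx = grid.admissible_indices
        if genes.shape != idx.shape:
            raise ValueError(
                f"gene vector length {genes.size} != admissible slot count {idx.size}")
        x = np.zeros(grid.n_slots, dtype=np.uint8)
        x[idx] = genes
        return cls(grid, x)

    @classmethod
    def zeros(cls, grid: TimeGrid) -> "Schedule":
        return cls(grid, np.zeros(grid.n_slots, dtype=np.uint8))

    def administration_days(self) -> np.ndarray:
        """Days (0-based) carrying at least one administration."""
        return np.unique(self.grid.slot_times[self.x.astype(bool)] // 24)


def make_time_grid(T_days: int, dt_hours: int, admissible_weekdays,
                   start_weekday: int = DEFAULT_START_WEEKDAY) -> TimeGrid:
    """Build the time grid for a horizon of ``T_days`` with slots of
    ``dt_hours``; a slot is admissible iff its calendar day's weekday is in
    ``admissible_weekdays`` (and, for sub-daily grids, it is the first slot
    of that day)."""
    if T_days <= 0:
        raise ValueError(f"T_days must be positive, got {T_days}")
    if dt_hours <= 0:
        raise ValueError(f"dt_hours must be positive, got {dt_hours}")
    if not (24 % dt_hours == 0 or dt_hours % 24 == 0):
        raise ValueError(
            f"dt_hours must divide 24 or be a multiple of 24, got {dt_hours}")
    wds = frozenset(int(w) for w in admissible_weekdays)
    if any(w < 0 or w > 6 for w in wds):
        raise ValueError(f"weekday indices must be in 0..6, got {sorted(wds)}")
    if not 0 <= start_weekday <= 6:
        raise ValueError(f"start_weekday must be in 0..6, got {start_weekday}")
    return TimeGrid(int(T_days), int(dt_hours), int(start_weekday), wds)


def log2_search_space(grid: TimeGrid) -> int:
    """log2 of the cardinality of the schedule space under the mask
    (= number of admissible slots)."""
    return int(grid.admissible_mask.sum())


def count_administrations(s: Schedule) -> int:
    """Total number of administrations, n = sum_i x_i."""
    if s.x.shape != (s.grid.n_slots,):
        raise ValueError(
            f"schedule length {s.x.size} does not match grid with {s.grid.n_slots} slots")
    return int(s.x.sum())


def chronic_protocol(grid: TimeGrid, start_week: int = 6,
                     end_week: int | None = None) -> Schedule:
    """The reference chronic protocol: 4-week cycles from ``start_week`` to
    ``end_week`` (exclusive, in weeks of age), dosing every admissible slot
    of each cycle's first two weeks — 4 administrations per full cycle on a
    two-days-a-week grid."""
    if not grid.admissible_weekdays:
        raise ValueError("chronic protocol requires a grid with a weekly "
                         "admissibility pattern (non-empty admissible_weekdays)")
    if end_week is None:
        end_week = grid.T_days // 7
    if start_week < 0:
        raise ValueError(f"start_week must be >= 0, got {start_week}")
    if end_week * 7 > grid.T_days:
        raise ValueError(
            f"end_week {end_week} exceeds the {grid.T_days}-day horizon")
    x = np.zeros(grid.n_slots, dtype=np.uint8)
    days = grid.slot_times // 24
    weeks = days // 7
    for cycle_start in range(start_week, end_week, 4):
        dosing = (grid.admissible_mask
                  & (weeks >= cycle_start)
                  & (weeks < min(cycle_start + 2, end_week)))
        x[dosing] = 1
    return Schedule(grid, x)


def validate_schedule(s: Schedule, grid: TimeGrid | None = None) -> list:
    """Diagnostic check of a schedule against a grid.

    Returns a list of ``(slot_index_or_None, reason)`` tuples; empty iff the
    schedule is valid (correct length, binary entries, administrations only
    on admissible slots)."""
    grid = grid if grid is not None else s.grid
    violations: list[tuple[int | None, str]] = []
    if s.x.shape != (grid.n_slots,):
        violations.append(
            (None, f"length {s.x.size} != expected {grid.n_slots} slots"))
        return violations
    bad_values = np.nonzero(s.x > 1)[0]
    for i in bad_values:
        violations.append((int(i), f"non-binary entry {int(s.x[i])}"))
    offending = np.nonzero(s.x.astype(bool) & ~grid.admissible_mask)[0]
    for i in offending:
        wd = WEEKDAY_NAMES[grid.weekday_of_slot(int(i))]
        violations.append(
            (int(i), f"administration on inadmissible slot {int(i)} ({wd})"))
    return violations


def write_schedule(s: Schedule, path) -> None:
    """Serialize a schedule as JSON (grid metadata + 0/1 bitstring)."""
    doc = {
        "T_days": s.grid.T_days,
        "dt_hours": s.grid.dt_hours,
        "start_weekday": s.grid.start_weekday,
        "admissible_weekdays": sorted(s.grid.admissible_weekdays),
        "x": "".join("1" if b else "0" for b in s.x),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_schedule(path) -> Schedule:
    """Parse a schedule file; inverse of :func:`write_schedule`.

    Raises :class:`ScheduleFormatError` on malformed documents and on
    schedules violating their own grid's admissibility."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ScheduleFormatError(
                f"{path}: not valid JSON (line {exc.lineno}: {exc.msg})") from exc
    required = ["T_days", "dt_hours", "start_weekday", "admissible_weekdays", "x"]
    for key in required:
        if key not in doc:
            raise ScheduleFormatError(f"{path}: missing field '{key}'")
    try:
        grid = make_time_grid(doc["T_days"], doc["dt_hours"],
                              doc["admissible_weekdays"], doc["start_weekday"])
    except (ValueError, TypeError) as exc:
        raise ScheduleFormatError(f"{path}: invalid grid metadata: {exc}") from exc
    bits = doc["x"]
    if not isinstance(bits, str) or set(bits) - {"0", "1"}:
        raise ScheduleFormatError(
            f"{path}: field 'x' must be a string of 0/1 characters")
    if len(bits) != grid.n_slots:
        raise ScheduleFormatError(
            f"{path}: bitstring length {len(bits)} != declared N={grid.n_slots}")
    s = Schedule(grid, np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0"))
    violations = validate_schedule(s, grid)
    if violations:
        detail = "; ".join(reason for _, reason in violations)
        raise ScheduleFormatError(f"{path}: invalid schedule: {detail}")
    return s
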
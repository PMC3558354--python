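"""Seeded lattice agent-based model of vaccine-elicited immunity versus
continuous mammary carcinogenesis.

One run with one seed is one *virtual mouse*: all stochastic events
(initial placement, movement, interaction outcomes, tumor seeding) are
drawn from a single per-mouse pseudo-random stream, so a (parameters,
schedule, seed) triple fully determines the trajectory, bit for bit.

The model is a deliberately compact reconstruction in the Celada–Seiden
lineage of immune-system lattice ABMs.  Agents of eight classes — B, Th
and Tc lymphocytes, NK cells, dendritic cells (DC), tumor cells, injected
vaccine cells and secreted antibodies — live on a toroidal square lattice.
Co-located agents interact stochastically; *specific* interactions require
receptor/epitope recognition scored by a Hamming-distance affinity (the
lock-and-key complementarity convention: larger distance = better match),
*aspecific* ones (NK killing, DC antigen uptake) do not.  The vaccine
carries the tumor-associated antigen plus two adjuvant effects: an IL-12
field deposited at injection sites that multiplies Th activation, and an
allogeneic-MHC flag that lets vaccine cells activate Th cells under a
relaxed match threshold (tolerance breaking).  Carcinogenesis is
continuous: ``tumor_birth`` newborn tumor cells appear at random sites
every step and existing tumor cells duplicate with probability ``p_dup``.
When the tumor-cell count reaches the palpable threshold the simulation
stops and the mouse is scored unprotected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .schedule import Schedule

__all__ = [
    "B_CELL", "TH_CELL", "TC_CELL", "NK_CELL", "DC_CELL", "TUMOR",
    "VACCINE", "ANTIBODY", "IMMUNE_CLASSES", "SimParams", "Population",
    "SimState", "MouseResult", "InvalidStateError", "affinity",
    "init_state", "inject_vaccine", "step", "run_mouse", "run_cohort",
    "TRAJECTORY_COLUMNS",
]

B_CELL, TH_CELL, TC_CELL, NK_CELL, DC_CELL = "B", "Th", "Tc", "NK", "DC"
TUMOR, VACCINE, ANTIBODY = "tumor", "vaccine", "antibody"
IMMUNE_CLASSES = (B_CELL, TH_CELL, TC_CELL, NK_CELL, DC_CELL)
_MOBILE = (B_CELL, TH_CELL, TC_CELL, NK_CELL, DC_CELL, ANTIBODY)
_ALL_CLASSES = IMMUNE_CLASSES + (TUMOR, VACCINE, ANTIBODY)

NAIVE, ACTIVE = 0, 1

TRAJECTORY_COLUMNS = ("day", "tumor_cells", "B", "Th", "Tc", "NK", "DC",
                      "antibodies", "vaccine_cells", "il12_total")

# Moore neighborhood displacements (8 neighbors, no rest move)
_MOORE = np.array([(-1, -1), (-1, 0), (-1, 1), (0, -1),
                   (0, 1), (1, -1), (1, 0), (1, 1)], dtype=np.int64)


class InvalidStateError(RuntimeError):
    """Raised when stepping a simulation that has already stopped."""


def _alternating_epitope(n_bits: int) -> int:
    """Fixed tumor-associated-antigen epitope: alternating 1010... bits.
    All virtual mice are transgenic for the same oncogene, so the epitope
    is a constant of the model, not a per-mouse draw."""
    return sum(1 << i for i in range(n_bits) if i % 2 == 0)


def _default_baseline() -> dict:
    # NK slightly above the lymphocyte classes: calibrated so innate
    # surveillance holds net early tumor growth just above zero, placing
    # untreated escape well inside the horizon while leaving the
    # vaccinated arm time to mount its response
    return {B_CELL: 50, TH_CELL: 50, TC_CELL: 50, NK_CELL: 73, DC_CELL: 50}


def _default_lifespans() -> dict:
    # steps (8 h each by default): immune cells live weeks, antibodies and
    # vaccine cells days
    return {B_CELL: 120, TH_CELL: 120, TC_CELL: 120, NK_CELL: 60,
            DC_CELL: 90, ANTIBODY: 60, VACCINE: 45}


@dataclass
class SimParams:
    """Parameters of the virtual-mouse simulator.

    The time unit is one lattice step of ``step_hours`` (default 8 h, three
    steps per simulated day); rates and lifespans are per step.
    """

    lattice_side: int = 32
    receptor_len: int = 12          # bits per receptor/epitope
    min_match: int = 10             # minimum Hamming distance for recognition
    affinity_base: float = 0.3      # c in affinity = c**(l - m)
    step_hours: int = 8
    horizon_steps: int = 1200       # 400 days at 3 steps/day
    tumor_birth: int = 1            # newborn tumor cells per step
    p_dup: float = 0.05             # tumor duplication probability per step
    palpable_threshold: int = 1000  # stop + score unprotected at this count
    baseline_counts: dict = field(default_factory=_default_baseline)
    p_aspecific: float = 0.9       # non-receptor-mediated interaction prob.
    il12_boost: float = 2.0         # Th activation multiplier per unit IL-12
    il12_decay: float = 0.1         # fractional field decay per step
    vaccine_dose: int = 50          # vaccine cells per administration
    lifespans: dict = field(default_factory=_default_lifespans)
    il12_per_cell: float = 1.0      # IL-12 deposited per injected cell
    tumor_visibility: float = 0.005  # antigenicity of tumor vs vaccine cells
    p_specific: float = 0.7         # interaction prob. after recognition
    p_stimulation: float = 0.8      # Th-driven B/Tc duplication probability
    clone_burst: int = 3            # copies per helper stimulation event
    antibodies_per_secretion: int = 12
    opsonization: float = 4.0       # Fc-mediated kill amplification on affinity
    allo_relax: int = 2             # match-threshold relaxation for allo-MHC
    max_class_size: int = 4000      # numerical cap on clonal expansion
    epitope: int | None = None      # override the default TAA bit pattern

    def __post_init__(self):
        if not 0 < self.affinity_base <= 1:
            raise ValueError("affinity_base must be in (0, 1]")
        if not 0 <= self.min_match <= self.receptor_len:
            raise ValueError("min_match must be in 0..receptor_len")
        if not 1 <= self.receptor_len <= 16:
            raise ValueError("receptor_len must be in 1..16")
        for name in ("p_dup", "p_aspecific", "p_specific", "p_stimulation",
                     "il12_decay", "tumor_visibility"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.palpable_threshold <= 0:
            raise ValueError("palpable_threshold must be positive")
        if self.lattice_side <= 0 or self.horizon_steps < 0:
            raise ValueError("lattice_side must be positive and horizon_steps >= 0")
        if 24 % self.step_hours != 0:
            raise ValueError("step_hours must divide 24")
        if self.tumor_birth < 0 or self.vaccine_dose < 0:
            raise ValueError("tumor_birth and vaccine_dose must be >= 0")
        if any(v < 0 for v in self.baseline_counts.values()):
            raise ValueError("baseline counts must be >= 0")

    @property
    def n_sites(self) -> int:
        return self.lattice_side * self.lattice_side

    @property
    def steps_per_day(self) -> int:
        return 24 // self.step_hours

    @property
    def epitope_value(self) -> int:
        if self.epitope is not None:
            return int(self.epitope)
        return _alternating_epitope(self.receptor_len)


class Population:
    """Struct-of-arrays container for one agent class.

    ``pos`` is the flattened lattice site, ``rec`` the receptor (or carried
    epitope) bitstring, ``age`` in steps, ``state`` 0 = naive / 1 = active
    (presenting for DC, activated for Th/Tc, allogeneic for vaccine cells).
    """

    __slots__ = ("pos", "rec", "age", "state")

    def __init__(self, pos=None, rec=None, age=None, state=None):
        self.pos = np.empty(0, np.int64) if pos is None else np.asarray(pos, np.int64)
        n = self.pos.size
        self.rec = (np.zeros(n, np.uint16) if rec is None
                    else np.asarray(rec, np.uint16))
        self.age = (np.zeros(n, np.int64) if age is None
                    else np.asarray(age, np.int64))
        self.state = (np.zeros(n, np.int8) if state is None
                      else np.asarray(state, np.int8))

    def __len__(self):
        return self.pos.size

    def add(self, pos, rec=None, age=0, state=0):
        pos = np.asarray(pos, np.int64)
        n = pos.size
        if n == 0:
            return
        self.pos = np.concatenate([self.pos, pos])
        self.rec = np.concatenate([
            self.rec, np.broadcast_to(np.asarray(rec if rec is not None else 0,
                                                 np.uint16), (n,))])
        self.age = np.concatenate([
            self.age, np.broadcast_to(np.asarray(age, np.int64), (n,))])
        self.state = np.concatenate([
            self.state, np.broadcast_to(np.asarray(state, np.int8), (n,))])

    def keep(self, mask):
        mask = np.asarray(mask, bool)
        self.pos = self.pos[mask]
        self.rec = self.rec[mask]
        self.age = self.age[mask]
        self.state = self.state[mask]

    def copy(self) -> "Population":
        return Population(self.pos.copy(), self.rec.copy(),
                          self.age.copy(), self.state.copy())


@dataclass
class SimState:
    """Full mutable state of one virtual mouse."""

    step: int
    pops: dict
    il12: np.ndarray
    counters: dict
    rng: np.random.Generator
    stopped: bool = False

    @property
    def tumor_count(self) -> int:
        return len(self.pops[TUMOR])

    def ledger_balance(self) -> int:
        """born + duplicated - killed - current count; zero iff the
        tumor-cell conservation ledger balances."""
        c = self.counters
        killed = (c["killed_by_antibody"] + c["killed_by_tc"]
                  + c["killed_by_nk"])
        return c["tumor_born"] + c["tumor_duplicated"] - killed - self.tumor_count

    def class_counts(self) -> dict:
        return {cls: len(pop) for cls, pop in self.pops.items()}


@dataclass(frozen=True)
class MouseResult:
    """Outcome of one virtual mouse.

    ``survived`` is true iff the tumor burden never reached the palpable
    threshold before the horizon; ``survival_step`` is the first step at
    which it did (or the horizon).  ``trajectory`` holds one record per
    simulated day with the counts in :data:`TRAJECTORY_COLUMNS`.
    """

    seed: int
    survived: bool
    survival_step: int
    trajectory: np.ndarray          # structured per-day record array
    peak_burden: int
    final_counts: dict

    @property
    def tumor_trajectory(self) -> np.ndarray:
        return self.trajectory["tumor_cells"]


def affinity(receptor: int, epitope: int, params: SimParams,
             min_match: int | None = None) -> float:
    """Recognition probability between a receptor and an epitope.

    With ``m`` the Hamming distance between the two bitstrings
    (complementarity convention: a receptor matching the full bitwise
    complement of the epitope has m = l and affinity 1), returns 0 if
    ``m < min_match`` and ``c**(l - m)`` otherwise.
    """
    l = params.receptor_len
    for name, v in (("receptor", receptor), ("epitope", epitope)):
        if not 0 <= int(v) < (1 << l):
            raise ValueError(f"{name} {v} does not fit in {l} bits")
    mm = params.min_match if min_match is None else min_match
    m = int(np.bitwise_count(np.uint16(receptor) ^ np.uint16(epitope)))
    if m < mm:
        return 0.0
    return float(params.affinity_base ** (l - m))


def _affinity_vec(recs: np.ndarray, epitope: int, params: SimParams,
                  min_match: int | None = None) -> np.ndarray:
    mm = params.min_match if min_match is None else min_match
    m = np.bitwise_count(recs ^ np.uint16(epitope)).astype(np.int64)
    aff = params.affinity_base ** (params.receptor_len - m)
    return np.where(m >= mm, aff, 0.0)


def _recognises(recs: np.ndarray, epitope: int, params: SimParams,
                min_match: int) -> np.ndarray:
    """Binary threshold recognition: Hamming distance >= min_match.

    Priming and activation use this gate with a fixed interaction
    probability; the graded affinity c**(l-m) is reserved for effector
    (killing) strength."""
    m = np.bitwise_count(recs ^ np.uint16(epitope)).astype(np.int64)
    return (m >= min_match).astype(np.float64)


def _random_receptors(rng, n, n_bits):
    return rng.integers(0, 1 << n_bits, size=n).astype(np.uint16)


def init_state(params: SimParams, seed: int) -> SimState:
    """Place baseline immune populations uniformly at random with random
    receptors; no tumor, no vaccine, zero IL-12.  The per-mouse stream is
    ``np.random.default_rng(seed)`` and is the single source of randomness
    for the whole run."""
    rng = np.random.default_rng(int(seed))
    pops = {cls: Population() for cls in _ALL_CLASSES}
    for cls in IMMUNE_CLASSES:
        n = int(params.baseline_counts.get(cls, 0))
        if n:
            pops[cls].add(rng.integers(0, params.n_sites, n),
                          _random_receptors(rng, n, params.receptor_len))
    counters = dict(tumor_born=0, tumor_duplicated=0, killed_by_antibody=0,
                    killed_by_tc=0, killed_by_nk=0, vaccine_injected=0,
                    vaccine_killed=0, administrations=0)
    return SimState(step=0, pops=pops,
                    il12=np.zeros(params.n_sites), counters=counters, rng=rng)


def inject_vaccine(state: SimState, params: SimParams) -> SimState:
    """Administer one dose: ``vaccine_dose`` vaccine cells carrying the
    tumor-associated antigen and the allogeneic-MHC flag appear at random
    sites and deposit IL-12 there."""
    d = params.vaccine_dose
    if d:
        pos = state.rng.integers(0, params.n_sites, d)
        state.pops[VACCINE].add(pos, params.epitope_value, state=ACTIVE)
        np.add.at(state.il12, pos, params.il12_per_cell)
    state.counters["vaccine_injected"] += d
    state.counters["administrations"] += 1
    return state


def _pick_partner(actor_pos, target_pos, n_sites, rng):
    """For each actor, the index of one uniformly random target sharing its
    lattice site, or -1 if the site holds no target."""
    out = np.full(actor_pos.size, -1, dtype=np.int64)
    if actor_pos.size == 0 or target_pos.size == 0:
        return out
    perm = rng.permutation(target_pos.size)
    order = np.argsort(target_pos[perm], kind="stable")
    sorted_pos = target_pos[perm][order]
    counts = np.bincount(sorted_pos, minlength=n_sites)
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
    cnt = counts[actor_pos]
    has = cnt > 0
    if has.any():
        r = rng.random(actor_pos.size)
        k = np.minimum((r * cnt).astype(np.int64), np.maximum(cnt - 1, 0))
        sel = starts[actor_pos] + k
        out[has] = perm[order[sel[has]]]
    return out


def _move(pop: Population, rng, side: int):
    n = len(pop)
    if n == 0:
        return
    d = _MOORE[rng.integers(0, 8, n)]
    x = (pop.pos // side + d[:, 0]) % side
    y = (pop.pos % side + d[:, 1]) % side
    pop.pos = x * side + y


def _kill(victims: Population, killer_pos, killer_probs, n_sites, rng):
    """Cytotoxic encounter: each victim meets one uniformly random
    co-located killer and dies with that killer's probability.  A killer
    can hit several co-located victims in the same step (a site raid).
    Returns (per-victim death mask, per-victim killer index or -1)."""
    if len(victims) == 0 or killer_pos.size == 0:
        return np.zeros(len(victims), bool), np.full(len(victims), -1)
    part = _pick_partner(victims.pos, killer_pos, n_sites, rng)
    has = part >= 0
    prob = np.zeros(len(victims))
    prob[has] = killer_probs[part[has]]
    die = has & (rng.random(len(victims)) < prob)
    return die, part


def _interact(state: SimState, p: SimParams):
    pops, rng, S = state.pops, state.rng, p.n_sites
    epi = p.epitope_value
    dc, th, b, tc, nk = (pops[DC_CELL], pops[TH_CELL], pops[B_CELL],
                         pops[TC_CELL], pops[NK_CELL])
    vac, tum, ab = pops[VACCINE], pops[TUMOR], pops[ANTIBODY]

    # --- antigen uptake by DC (aspecific; tumor cells are poorly visible)
    naive_dc = np.nonzero(dc.state == NAIVE)[0]
    for source, prob in ((vac, p.p_aspecific),
                         (tum, p.p_aspecific * p.tumor_visibility)):
        if naive_dc.size and len(source):
            part = _pick_partner(dc.pos[naive_dc], source.pos, S, rng)
            took = (part >= 0) & (rng.random(naive_dc.size) < prob)
            dc.state[naive_dc[took]] = ACTIVE
            naive_dc = naive_dc[~took]

    # --- T-cell activation (specific: threshold recognition, fixed
    # interaction probability, IL-12 boosted).  Th can additionally be
    # activated by allogeneic vaccine cells under a relaxed match
    # threshold (tolerance breaking); Tc are cross-primed by DC.
    recognises_th = _recognises(th.rec, epi, p, p.min_match)
    recognises_th_allo = _recognises(th.rec, epi, p,
                                     p.min_match - p.allo_relax)
    pres_pos = dc.pos[dc.state == ACTIVE]
    for cells, sources in ((th, ((pres_pos, recognises_th),
                                 (vac.pos, recognises_th_allo))),
                           (tc, ((pres_pos, _recognises(tc.rec, epi, p,
                                                        p.min_match)),))):
        naive = np.nonzero(cells.state == NAIVE)[0]
        for source_pos, recog in sources:
            if naive.size == 0 or source_pos.size == 0:
                continue
            boost = 1.0 + p.il12_boost * state.il12[cells.pos[naive]]
            part = _pick_partner(cells.pos[naive], source_pos, S, rng)
            prob = np.minimum(1.0, p.p_specific * boost) * recog[naive]
            act = (part >= 0) & (rng.random(naive.size) < prob)
            cells.state[naive[act]] = ACTIVE
            naive = naive[~act]

    # --- clonal expansion: activated Th re-encountering antigen
    # (presenting DC or vaccine cells) proliferate
    if len(th) < p.max_class_size:
        act_th = np.nonzero(th.state == ACTIVE)[0]
        antigen_pos = np.concatenate([pres_pos, vac.pos])
        if act_th.size and antigen_pos.size:
            part = _pick_partner(th.pos[act_th], antigen_pos, S, rng)
            grow = (part >= 0) & (rng.random(act_th.size) < p.p_stimulation)
            chosen = act_th[grow]
            if chosen.size:
                th.add(th.pos[chosen], th.rec[chosen], state=ACTIVE)

    # --- helper-driven expansion of antigen-experienced B and Tc clones
    act_th_pos = th.pos[th.state == ACTIVE]
    if act_th_pos.size:
        for helped in (b, tc):
            experienced = np.nonzero(helped.state == ACTIVE)[0]
            if experienced.size == 0 or len(helped) >= p.max_class_size:
                continue
            part = _pick_partner(act_th_pos, helped.pos[experienced], S, rng)
            stim = (part >= 0) & (rng.random(act_th_pos.size)
                                  < p.p_stimulation)
            chosen = experienced[np.unique(part[stim])]
            if chosen.size:
                burst = np.repeat(chosen, p.clone_burst)
                helped.add(helped.pos[burst], helped.rec[burst], state=ACTIVE)

    # --- B priming on positive antigen encounter; antigen-experienced B
    # act as plasma cells, continuously secreting antibodies
    naive_b = np.nonzero(b.state == NAIVE)[0]
    if naive_b.size:
        recog_b = _recognises(b.rec, epi, p, p.min_match)
        for source, scale in ((vac, 1.0), (tum, p.tumor_visibility)):
            if naive_b.size == 0 or len(source) == 0:
                continue
            part = _pick_partner(b.pos[naive_b], source.pos, S, rng)
            prob = p.p_specific * scale * recog_b[naive_b]
            prime = (part >= 0) & (rng.random(naive_b.size) < prob)
            b.state[naive_b[prime]] = ACTIVE
            naive_b = naive_b[~prime]
    plasma = np.nonzero(b.state == ACTIVE)[0]
    if plasma.size and len(ab) < p.max_class_size:
        k = p.antibodies_per_secretion
        ab.add(np.repeat(b.pos[plasma], k), np.repeat(b.rec[plasma], k))

    # --- tumor killing, in fixed precedence with sequential removal so a
    # cell dies at most once: antibodies, then cytotoxic T, then NK
    if len(tum):
        ab_kill = np.minimum(1.0, p.opsonization
                             * _affinity_vec(ab.rec, epi, p))
        die, part = _kill(tum, ab.pos, ab_kill, S, rng)
        if die.any():
            spent = np.zeros(len(ab), bool)
            spent[np.unique(part[die])] = True
            ab.keep(~spent)  # opsonizing antibodies are consumed
            state.counters["killed_by_antibody"] += int(die.sum())
            tum.keep(~die)
    if len(tum):
        act_tc = tc.state == ACTIVE
        die, _ = _kill(tum, tc.pos[act_tc],
                       _affinity_vec(tc.rec[act_tc], epi, p), S, rng)
        if die.any():
            state.counters["killed_by_tc"] += int(die.sum())
            tum.keep(~die)
    if len(tum):
        die, _ = _kill(tum, nk.pos, np.full(len(nk), p.p_aspecific), S, rng)
        if die.any():
            state.counters["killed_by_nk"] += int(die.sum())
            tum.keep(~die)

    # --- cytotoxic clearance of (allogeneic) vaccine cells releases their
    # antigen to co-located DC
    if len(vac):
        killer_pos = np.concatenate([tc.pos, nk.pos])
        die, _ = _kill(vac, killer_pos,
                       np.full(killer_pos.size, p.p_aspecific), S, rng)
        if die.any():
            released_pos = vac.pos[die]
            state.counters["vaccine_killed"] += int(die.sum())
            vac.keep(~die)
            naive_dc = np.nonzero(dc.state == NAIVE)[0]
            if naive_dc.size:
                part = _pick_partner(dc.pos[naive_dc], released_pos, S, rng)
                dc.state[naive_dc[part >= 0]] = ACTIVE


def step(state: SimState, schedule_bit: int, params: SimParams) -> SimState:
    """Advance the simulation by one lattice step (in place).

    Phases, in fixed order: vaccine injection (first step of an
    administration day), movement, site interactions, ageing/death and
    homeostatic replenishment, tumor seeding and duplication, IL-12 decay,
    palpable-threshold check.
    """
    if state.stopped:
        raise InvalidStateError("cannot step a stopped simulation")
    p = params
    rng = state.rng
    pops = state.pops

    # (1) administration at the first step of the slot's day
    if schedule_bit and state.step % p.steps_per_day == 0:
        inject_vaccine(state, p)

    # (2) movement: mobile agents hop to a random Moore neighbor (torus)
    for cls in _MOBILE:
        _move(pops[cls], rng, p.lattice_side)

    # (3) stochastic site interactions
    _interact(state, p)

    # (4) ageing, death, homeostatic replenishment toward baseline
    for cls in _ALL_CLASSES:
        pop = pops[cls]
        if len(pop) == 0:
            continue
        pop.age += 1
        life = p.lifespans.get(cls)
        if life is not None:
            pop.keep(pop.age < life)
    for cls in IMMUNE_CLASSES:
        deficit = int(p.baseline_counts.get(cls, 0)) - len(pops[cls])
        if deficit > 0:
            pops[cls].add(rng.integers(0, p.n_sites, deficit),
                          _random_receptors(rng, deficit, p.receptor_len))

    # (5) continuous carcinogenesis: seeding + duplication
    tum = pops[TUMOR]
    if p.tumor_birth:
        tum.add(rng.integers(0, p.n_sites, p.tumor_birth), p.epitope_value)
        state.counters["tumor_born"] += p.tumor_birth
    if p.p_dup > 0 and len(tum):
        dup = rng.random(len(tum)) < p.p_dup
        n_dup = int(dup.sum())
        if n_dup:
            # daughters settle on a random Moore-neighbor site: local
            # solid-tumor growth rather than a single-site stack
            side = p.lattice_side
            d = _MOORE[rng.integers(0, 8, n_dup)]
            x = (tum.pos[dup] // side + d[:, 0]) % side
            y = (tum.pos[dup] % side + d[:, 1]) % side
            tum.add(x * side + y, p.epitope_value)
            state.counters["tumor_duplicated"] += n_dup

    # (6) adjuvant field decay
    state.il12 *= 1.0 - p.il12_decay

    # (7) palpable-tumor stop
    state.step += 1
    if state.tumor_count >= p.palpable_threshold:
        state.stopped = True
    return state


def _record(state: SimState, day: int) -> tuple:
    c = state.class_counts()
    return (day, c[TUMOR], c[B_CELL], c[TH_CELL], c[TC_CELL], c[NK_CELL],
            c[DC_CELL], c[ANTIBODY], c[VACCINE], float(state.il12.sum()))


def run_mouse(params: SimParams, s: Schedule, seed: int) -> MouseResult:
    """Simulate one virtual mouse under a schedule.

    The schedule's grid must cover exactly the simulation horizon
    (``grid.T_days * 24 == horizon_steps * step_hours``).  Administration
    happens at the first step of each day carrying an ``x_i = 1`` slot.
    Bit-exact reproducible for identical (params, schedule, seed).
    """
    if s.grid.T_days * 24 != params.horizon_steps * params.step_hours:
        raise ValueError(
            f"schedule grid covers {s.grid.T_days} days but the simulation "
            f"horizon is {params.horizon_steps * params.step_hours / 24:g} days")
    spd = params.steps_per_day
    admin_day = np.zeros(s.grid.T_days + 1, bool)
    admin_day[s.administration_days()] = True

    state = init_state(params, seed)
    records = []
    peak = 0
    for i in range(params.horizon_steps):
        day = i // spd
        step(state, int(admin_day[day]), params)
        peak = max(peak, state.tumor_count)
        if state.stopped or (i + 1) % spd == 0:
            records.append(_record(state, day))
        if state.stopped:
            break
    survived = not state.stopped
    traj = np.array(records, dtype=[("day", np.int64), ("tumor_cells", np.int64),
                                    ("B", np.int64), ("Th", np.int64),
                                    ("Tc", np.int64), ("NK", np.int64),
                                    ("DC", np.int64), ("antibodies", np.int64),
                                    ("vaccine_cells", np.int64),
                                    ("il12_total", np.float64)])
    return MouseResult(seed=int(seed), survived=survived,
                       survival_step=(params.horizon_steps if survived
                                      else state.step),
                       trajectory=traj, peak_burden=int(peak),
                       final_counts=state.class_counts())


def run_cohort(params: SimParams, s: Schedule, seeds) -> list:
    """Independent virtual-mouse runs, one per seed, in seed order."""
    seeds = [int(x) for x in seeds]
    if len(set(seeds)) != len(seeds):
        raise ValueError(f"cohort seeds must be distinct, got {seeds}")
    return [run_mouse(params, s, seed) for seed in seeds]
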
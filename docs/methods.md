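# Methods

## Scope

`vaxopt` couples a stochastic lattice model of vaccine-elicited antitumor
immunity (the *virtual mouse*) to a parallel genetic algorithm over
binary administration schedules.  The virtual mouse is a deliberately
compact reconstruction in the Celada–Seiden tradition of immune-system
agent-based models: it is built to reproduce the *qualitative* experimental
contrast that motivates schedule optimization — untreated transgenic mice
develop palpable mammary tumors within the study horizon while chronically
vaccinated ones stay tumor-free — not any published quantitative
parameterization, and its constants are this package's own calibration.

## Schedule space

Time is discretized into `N = floor(T·24/Δt)` slots (`Δt` = 24 h by
default; sub-daily grids admit only the first slot of a day so the
twice-a-week constraint stays meaningful).  Slots are half-open intervals,
0-based, with slot 0 at day 0, hour 0.  A slot is *admissible* when its
calendar weekday is in the allowed set; log2 of the search-space
cardinality equals the admissible count.  With administrations allowed on
Mondays and Thursdays over 400 days the count depends on the calendar
anchor: the package anchors day 0 on a Friday, under which both weekdays
occur exactly `floor(400/7) = 57` times, giving the canonical 114 (a
Monday anchor would give 115).  The anchor is configurable and the count
is reported, never assumed.

The reference *chronic* protocol doses every admissible slot of the first
two weeks of each 4-week cycle (4 shots per full cycle), from week 6 to
week 57 on the default grid: 52 administrations.

## The virtual mouse

State: agents of eight classes (B, Th, Tc, NK, DC, tumor cells, vaccine
cells, antibodies) on a 32×32 toroidal lattice, plus a per-site IL-12
field and a conservation ledger for tumor cells.  One step is 8 h (three
per day); the horizon is 1200 steps = 400 days.  All randomness of a run
comes from one `numpy` PCG64 stream seeded with the mouse's seed, so a
(parameters, schedule, seed) triple reproduces a trajectory bit for bit
and cohort results are independent of evaluation order and worker count.

Each step applies, in fixed order: (1) vaccine injection at the first
step of a scheduled day — `vaccine_dose` cells carrying the tumor
antigen and an allogeneic flag at random sites, depositing IL-12 there;
(2) movement of mobile agents to a uniformly random Moore neighbor;
(3) site interactions (below); (4) ageing, death and homeostatic
replenishment of immune classes toward baseline with fresh random
receptors; (5) carcinogenesis — `tumor_birth` newborn cells at random
sites, then each tumor cell duplicates with probability `p_dup`, the
daughter settling on a random Moore neighbor (local solid-tumor growth);
(6) IL-12 decay; (7) stop when the tumor count reaches the palpable
threshold θ.

Recognition and effector strength are deliberately separated:

- *Recognition* is a binary Hamming-distance gate (complementarity
  convention): receptor and epitope interact specifically only when their
  distance `m ≥ m_min`.  Given recognition, priming/activation events
  succeed with a flat probability `p_specific`, multiplied for T-cell
  activation by the local adjuvant boost `1 + il12_boost·IL12(site)`.
- *Effector strength* uses the graded affinity `A(m) = c^(ℓ−m)`
  (`A = 1` at the perfect-complement distance `m = ℓ`, 0 below `m_min`):
  Tc kill a co-located tumor cell with probability `A`, antibodies with
  `min(1, opsonization·A)` — the opsonization factor models Fc-mediated
  clearance amplifying a binding event into a kill.

Interaction rules per step: naive DC take up antigen aspecifically from
vaccine cells (probability `p_aspecific`) or, much more weakly, from
tumor cells (`p_aspecific·tumor_visibility` — tumors are poorly
immunogenic); Th are activated by presenting DC, or directly by
allogeneic vaccine cells under a relaxed threshold `m_min − allo_relax`
(tolerance breaking by allo-MHC); Tc are cross-primed by presenting DC;
activated Th proliferate on antigen re-encounter and drive clonal bursts
(`clone_burst` copies) of antigen-experienced B and Tc; B primed by a
positive antigen encounter become plasma cells secreting
`antibodies_per_secretion` antibodies per step; killing of tumor cells
proceeds antibody → Tc → NK with sequential removal (each tumor cell
meets at most one random co-located killer per mechanism, a killer can
hit several cells at its site); cytotoxic clearance of vaccine cells
releases their antigen to co-located DC.  The tumor ledger
(born + duplicated − killed = alive) is maintained exactly and asserted
in tests.

### Parameters

Fixed structural choices: lattice 32×32, 8 h steps, ℓ = 12-bit receptors,
`m_min = 10`, `c = 0.3`, θ = 1000 cells, `tumor_birth = 1`/step,
`p_dup = 0.05`/step, `vaccine_dose = 50`, `il12_boost = 2.0`,
`il12_decay = 0.1`/step, baseline 50 cells per immune class except NK.

Calibrated by this package (sweeps over dedicated calibration seeds,
disjoint from every seed used in the test suite and acceptance script;
frozen once):

| parameter | default | role |
|---|---|---|
| NK baseline | 73 | innate surveillance strength |
| `p_aspecific` | 0.9 | NK/DC aspecific interaction probability |
| `p_specific` | 0.7 | interaction probability after recognition |
| `p_stimulation` | 0.8 | helper-driven proliferation probability |
| `clone_burst` | 3 | copies per helper stimulation event |
| `antibodies_per_secretion` | 12 | plasma-cell output per step |
| `opsonization` | 4.0 | antibody kill amplification |
| `tumor_visibility` | 0.005 | tumor antigenicity relative to vaccine |
| lifespans (steps) | B/Th/Tc 120, NK 60, DC 90, antibody 60, vaccine 45 | turnover |
| `max_class_size` | 4000 | numerical cap on clonal expansion |

Two calibration facts shaped these numbers.  First, slow-moving NK cells
over-harvest their own neighborhood (a predator–prey shadowing effect),
so their effective per-cell pressure is ~0.03/step rather than the
mean-field `n_NK/sites ≈ 0.047`; the NK compartment is therefore sized so
that net early tumor growth is slightly positive, which places untreated
escape at roughly day 70–330 — inside the horizon, but after the chronic
protocol's first dose (day 45) plus the ~1–2 week latency of the adaptive
cascade.  Second, with a 50-cell B repertoire the expected number of
clones passing the `m ≥ 10` gate is about one, so protection hinges on
fast priming and strong amplification of that clone; `p_specific`,
`clone_burst`, the plasma secretion rate and the opsonization factor are
set so that a single matched clone suffices.  Under the shipped defaults,
on calibration cohorts of 32 mice per arm, 31/32 untreated mice reached
the threshold and 31/32 chronically vaccinated mice were protected.

### What the generator does and does not emulate

The simulator reproduces: seed-driven individual variability, continuous
carcinogenesis with threshold-detected tumor onset, the two adjuvant
mechanisms of a Triplex-class vaccine, dose-timing sensitivity (early
cycles matter because escape is exponential), and cohort-level protection
statistics.  It does not emulate: real mammary-tissue anatomy or tumor
morphology, antibody isotypes, regulatory suppression (Treg/B-mediated),
immune ageing, repertoire sizes within orders of magnitude of reality, or
any quantitatively validated parameter set — so a passing two-arm
contrast demonstrates internal consistency of the optimization pipeline,
not a prediction about laboratory mice.

## Fitness

`scalar = w1·survivors − w2·burden_penalty − w3·dose_penalty` with
defaults (10, 1, 1).  `burden_penalty` is the cohort mean of
`min(peak_burden/θ, 1)`; `dose_penalty` is `n /` admissible-slot count.
`w1 > w2 + w3` is validated explicitly: since both penalties live in
[0, 1], a schedule protecting more mice always outranks one protecting
fewer.  Ties break by survivors, then lower dose penalty, lower burden
penalty, then lexicographic genome order, making every comparison
deterministic.  Cohort seeds are fixed once per optimization run — every
individual in every generation faces the same mice.

## Genetic algorithm

Population 80, 150 generations, 8-mouse cohorts by default (toy
configurations in tests).  Operators act on the compressed admissible-gene
vector, so admissibility can never be violated: Bernoulli(0.5)
initialization, size-2 tournament selection, uniform crossover at rate
0.7, per-gene flips at rate `1/L`, one elite copied unchanged (hence the
monotone best-fitness invariant).  A single evolution RNG stream derives
from `master_seed` and is touched only by master-phase operators;
evaluation randomness lives entirely in the cohort seeds, which is what
makes GA runs bit-reproducible under any evaluation backend.

## Parallel evaluation and the cost model

A generation's P·M (individual, mouse) tasks are partitioned into static
blocks differing by at most one task.  Backends implement one contract —
receive population, evaluate assigned tasks, return (task id, result)
pairs for master-side aggregation — and are bit-equivalent: a serial
reference, a process pool (pool reused across generations), and a
scripted backend that permutes gather order to exercise
order-independence.  A message-passing runtime would be one more backend
behind the same contract; none is required.

Wall-clock scaling is summarized analytically instead of by
hardware-bound measurements:

    T_g = T_master(P) + T_sync(c) + ceil(P·M/c) · T_fit

with defaults `T_fit = 30 s`, `T_master(P) = 0.05·P` (a linear
operation-count proxy for serial evolution work) and constant
`T_sync = 1 s` (no synchronization model is available to fit; an optional
`log2(c)` term exists but defaults to zero, keeping `T_g` exactly
non-increasing in `c`).  The model yields the expected linear-speedup
regime, the plateau `T_master + T_sync + T_fit` once `c ≥ P·M`, and a
plateau that grows with population size — the serial-master bottleneck.
`vaxopt benchmark` prints measured evaluation times next to these
predictions.

## Numerical choices and degenerate inputs

Empty admissible sets are legal (dose penalty defined as 0); empty
cohorts yield zero-survivor fitness; `generations = 0` produces a
single-entry history; stepping a stopped simulation raises; duplicate
cohort seeds are rejected; schedules are validated on file read and
before every run.  Trajectories are recorded once per simulated day to
bound output size, while `peak_burden` tracks the per-step maximum.  The
`max_class_size` cap bounds memory during clonal expansion; it binds only
in strongly stimulated runs and is configurable.

## Problem sizes used in the shipped checks

The test suite and acceptance script use: the full 400-day grid for
schedule accounting; 20 virtual mice per arm for the two-arm contrast;
toy simulations (16×16 lattice, 20 days, 2-mouse cohorts, population 8)
for backend-equivalence and end-to-end GA checks; a 50-gene surrogate
(hidden-target matching, population 40, ≤100 generations, 10 master
seeds) for convergence; and the analytic cost model over worker counts
4–256.  These sizes were chosen so the whole battery completes in a few
minutes on one CPU while every claim above is exercised directly.

## Known limitations

- The two-arm contrast is a property-based, scaled-down stand-in; its
  percentages are not comparable to published protection rates.
- The 114-slot count is calendar-anchor dependent (documented above).
- The affinity gate with a 50-cell repertoire makes specific immunity
  hinge on ~1 matched clone per mouse; protection percentages are
  therefore sensitive to repertoire-size parameters.
- Process-pool parallelism pays per-task pickling costs that dwarf toy
  workloads; it only pays off when one simulation takes seconds or more.
- The cost model's `T_sync` is a placeholder constant, fit to nothing.
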
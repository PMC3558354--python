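# vaxopt

In-silico optimization of cancer-immunoprevention vaccination schedules.

Cell vaccines such as the Triplex vaccine (HER-2/neu target antigen plus
IL-12 and allogeneic-MHC adjuvants) can almost completely prevent mammary
carcinogenesis in HER-2/neu transgenic mice — but only under an intensive,
life-long *chronic* protocol: 4-week cycles with four administrations in
the first two weeks of each cycle, from 6 weeks of age onward.  Finding a
leaner schedule in vivo is hopeless: each candidate protocol is a year-long
mouse experiment.  `vaxopt` is a virtual laboratory for this search,
aimed at computational and tumor immunologists who want to design and
stress-test administration schedules before committing animals to them.

## The model and the search problem

The horizon `[0, T]` (default T = 400 days) is discretized into N slots of
width Δt; a schedule is a binary vector **x** with `x_i = 1` meaning one
fixed-dose administration in slot *i*, and `n = Σ x_i` administrations in
total.  The unconstrained space has cardinality 2^400; the wet-lab
constraint that injections happen only on Mondays and Thursdays reduces it
to 2^114 — far beyond exhaustive search either way.

Three components work together:

- **Virtual mouse** (`vaxopt.simulator`): a seeded lattice agent-based
  model in the Celada–Seiden lineage.  B/Th/Tc/NK/dendritic cells, tumor
  cells, vaccine cells and antibodies inhabit a toroidal grid;
  co-located agents interact stochastically, with specific interactions
  gated by a Hamming-distance receptor/epitope affinity
  `A(m) = c^(ℓ−m)` for match `m ≥ m_min` (complementarity convention) and
  aspecific ones (NK killing, DC antigen uptake) by flat probabilities.
  Carcinogenesis is continuous — newborn tumor cells every step plus
  stochastic duplication — and a run stops when the burden reaches the
  palpable threshold θ.  One seed = one mouse; runs are bit-reproducible.
- **Cohort fitness** (`vaxopt.fitness`): a schedule is scored on a fixed
  cohort of mice by `w1·survivors − w2·burden − w3·doses` with
  `w1 > w2 + w3`, so protecting more of the cohort lexicographically
  dominates sparing doses.
- **Parallel GA** (`vaxopt.ga`, `vaxopt.parallel`): tournament selection,
  uniform crossover and per-gene mutation on the compressed 114-gene
  vector (constraint-preserving by construction), with elitism.  Fitness
  evaluation follows the master–slave broadcast → evaluate → gather
  pattern; serial, process-pool and scripted backends are bit-equivalent,
  so a run is reproducible for any worker count.  Per-generation runtime
  is described by the analytic cost model
  `T_g = T_master(P) + T_sync(c) + ceil(P·M/c)·T_fit`, which exhibits the
  expected linear-speedup regime and the serial-master plateau.

## Worked example

Write the chronic reference protocol and simulate one untreated and one
vaccinated mouse:

```
$ vaxopt chronic --config examples/default.yaml --out chronic.json
wrote chronic.json (52 administrations)

$ vaxopt simulate --config examples/default.yaml --schedule chronic.json \
      --seed 301 --outdir run_chronic
survived=True peak_burden=282 (outputs in run_chronic)
```

The same mouse without vaccination (an all-zero schedule) reaches the
palpable threshold of 1000 tumor cells after 73 days, while the chronic
protocol holds its burden to a peak of 282 cells over the full 400 days:
the protocol's 52 administrations convert a tumor-bearing mouse into a
protected one.  `run_chronic/trajectory.csv` holds the per-day counts of
every cell class for plotting.

A small optimization run (population 6, 3 generations, 2-mouse cohort on
a 20-day toy horizon, as in `tests/test_cli.py`):

```
$ vaxopt optimize --config tiny.yaml --outdir opt
best scalar 19.8900 with 0 administrations (2/2 mice protected); outputs in opt
```

(On this 20-day toy horizon the tumor cannot reach the threshold, so both
mice survive regardless and the GA correctly strips every administration;
scalar = 10·2 − burden − 0 doses.)  `opt/history.csv` records
per-generation best/mean fitness — best is non-decreasing thanks to
elitism — and `opt/best_schedule.json` the winning schedule, re-readable
with `vaxopt.read_schedule`.  A full-scale
campaign (population 80, 8 mice, 150 generations) costs
`8·80·150·T_fit ≈ 33 days` of single-CPU time at T_fit = 30 s, which is
exactly why the evaluation layer is parallel; `vaxopt benchmark` measures
and predicts the per-generation time for a list of worker counts.

## Layout

```
src/vaxopt/schedule.py    time grid, admissibility, chronic protocol, I/O
src/vaxopt/simulator.py   the virtual-mouse lattice ABM
src/vaxopt/fitness.py     cohort-level schedule scoring
src/vaxopt/ga.py          genetic algorithm over schedule genomes
src/vaxopt/parallel.py    master-slave backends + generation-time model
src/vaxopt/cli.py         simulate / optimize / chronic / benchmark
docs/methods.md           model description, calibration, limitations
```
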
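# Full-scale configuration: 400-day horizon, Mon/Thu dosing grid,
# default virtual-mouse parameters, published GA geometry.
grid:
  T_days: 400
  dt_hours: 24
  admissible_weekdays: [0, 3]   # Monday, Thursday
  start_weekday: 4              # Friday anchor -> 114 admissible slots
sim: {}                         # shipped SimParams defaults
ga:
  population_size: 80
  generations: 150
  cohort_size: 8
  master_seed: 0
chronic:
  start_week: 6
  end_week: 57
cohort_seeds: [101, 102, 103, 104, 105, 106, 107, 108]
workers: 1
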
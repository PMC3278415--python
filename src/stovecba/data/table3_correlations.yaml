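# Assumed rank correlations between model parameters.
#
# Each entry is [parameter_a, parameter_b, rank_correlation].  A name with
# the prefix "stove:" is expanded stove-by-stove: the pair applies within
# each stove's own parameter block (a more durable stove of type i costs
# more, etc.).  Fuel prices are addressed as fuel.<fuel_id>.price.
# Correlations are listed once; the matrix is symmetrized and, if needed,
# repaired to the nearest positive semidefinite correlation matrix before
# sampling.

pairs:
  # stove cost
  - [stove:capital_cost, stove:lifespan, 0.7]
  - [stove:capital_cost, wage, 0.5]
  - [stove:capital_cost, stove:time_efficiency, -0.5]
  - [stove:capital_cost, baseline_fuel_rate, 0.5]
  - [stove:capital_cost, stove:ari_effectiveness, 0.5]
  - [stove:capital_cost, stove:copd_effectiveness, 0.5]
  - [stove:capital_cost, alri_cfr, 0.5]
  - [stove:capital_cost, copd_death_rate, 0.5]
  # stove lifespan
  - [stove:lifespan, stove:maintenance_cost, 0.5]
  - [stove:lifespan, baseline_cooking_time, -0.5]
  - [stove:lifespan, stove:time_efficiency, -0.5]
  # program cost
  - [program_cost, ari_incidence, 0.5]
  - [program_cost, copd_prevalence, 0.5]
  - [program_cost, alri_cfr, 0.5]
  - [program_cost, copd_death_rate, 0.5]
  - [program_cost, wage, 0.5]
  # O&M cost (constant in the default catalog; kept for completeness)
  - [stove:maintenance_cost, baseline_cooking_time, 0.5]
  - [stove:maintenance_cost, wage, 0.5]
  # baseline cooking time
  - [baseline_cooking_time, baseline_fuel_rate, -0.5]
  - [baseline_cooking_time, time_value, -0.5]
  # solid-fuel prices
  - [fuel.wood.price, wage, 0.5]
  - [fuel.charcoal.price, wage, 0.5]
  # shadow value of time
  - [time_value, fuel.wood.price, 0.5]
  - [time_value, fuel.charcoal.price, 0.5]
  - [time_value, wage, 0.5]
  # health economics
  - [ari_incidence, wage, -0.5]
  - [coi_ari, wage, 0.5]
  - [coi_copd, wage, 0.5]
  - [vsl, wage, 0.7]
  - [alri_cfr, wage, -0.5]
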
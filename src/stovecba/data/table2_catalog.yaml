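# Parameter catalog for the household cookstove cost-benefit model.
#
# Values are stored exactly as printed in the source literature review
# (percentages as percentages, death rates per 10,000); the loader
# normalizes units to fractions/probabilities.  Schema:
#   constants:  scalar model conventions
#   globals:    household / economic / health parameters (ranges)
#   fuels:      per-fuel price ranges and physical constants
#   stoves:     per-stove parameter blocks
#   correlations: see table3_correlations.yaml (merged at load time)

constants:
  days_per_month: 30
  learning_hours: 0.0

globals:
  discount_rate_social: {low: 3, mid: 4.5, high: 6, units: percent/yr}
  discount_rate_private: {low: 10, mid: 15, high: 20, units: percent/yr}
  program_cost: {low: 0.2, mid: 2.0, high: 3.8, units: USD/hh-yr}
  sustained_use: {low: 0.2, mid: 0.5, high: 0.8, units: fraction}
  baseline_cooking_time: {low: 2, mid: 3, high: 4, units: hr/day}
  baseline_fuel_rate: {low: 0.3, mid: 0.6, high: 1.0, units: kg/hr}
  collection_time: {low: 0.3, mid: 1.0, high: 3.0, units: hr/day}
  prep_time: {low: 0.17, mid: 0.33, high: 0.50, units: hr/day}
  wood_purchased_fraction: {low: 0, mid: 25, high: 50, units: percent}
  household_size: {low: 4, mid: 5, high: 6, units: persons/hh}
  ari_incidence: {low: 0.1, mid: 0.5, high: 1.0, units: cases/person-yr}
  copd_prevalence: {low: 1, mid: 4.5, high: 8, units: percent}
  coi_ari: {low: 2, mid: 15, high: 60, units: USD/case}
  coi_copd: {low: 30, mid: 35, high: 40, units: USD/yr}
  copd_onset_delay: {low: 10, mid: 15, high: 20, units: yr}
  vsl: {low: 10000, mid: 30000, high: 50000, units: USD/life}
  alri_fraction: {low: 0.04, mid: 0.15, high: 0.25, units: fraction}
  alri_cfr: {low: 0.01, mid: 0.03, high: 0.05, units: deaths/case}
  copd_death_rate: {low: 0, mid: 1, high: 2, units: deaths/10000-yr}
  time_value: {low: 0.1, mid: 0.3, high: 0.5, units: fraction-of-wage}
  wage: {low: 0.13, mid: 0.2, high: 0.5, units: USD/hr}
  carbon_price: {low: 5, mid: 20, high: 35, units: USD/ton-CO2eq}
  tree_replacement_cost: {low: 0.002, mid: 0.01, high: 0.02, units: USD/kg-wood}

fuels:
  wood:
    price: {low: 0.03, mid: 0.12, high: 0.2, units: USD/kg}
    energy_content: {value: 16, units: MJ/kg}
    carbon_intensity_basic: {value: 12.1, units: g-CO2eq/MJ}
    carbon_intensity_extended: {value: 225, units: g-CO2eq/MJ}
  charcoal:
    price: {low: 0.1, mid: 0.45, high: 0.8, units: USD/kg}
    energy_content: {value: 30, units: MJ/kg}
    carbon_intensity_basic: {value: 5.6, units: g-CO2eq/MJ}
    carbon_intensity_extended: {value: 410, units: g-CO2eq/MJ}
  kerosene:
    price: {low: 0.3, mid: 0.5, high: 0.7, units: USD/kg}
    energy_content: {value: 35, units: MJ/kg}
    carbon_intensity_basic: {value: 157.4, units: g-CO2eq/MJ}
    carbon_intensity_extended: {value: 157.4, units: g-CO2eq/MJ}
  propane:
    price: {low: 0.4, mid: 0.7, high: 1.0, units: USD/kg}
    energy_content: {value: 45, units: MJ/kg}
    carbon_intensity_basic: {value: 107.9, units: g-CO2eq/MJ}
    carbon_intensity_extended: {value: 107.9, units: g-CO2eq/MJ}
  electricity:
    price: {low: 0.03, mid: 0.065, high: 0.10, units: USD/kW-hr}
    energy_content: {value: 3.6, units: MJ/kW-hr}
    # varies by the source of power; extended accounting adds nothing for grid power
    carbon_intensity_basic: {low: 70, mid: 170, high: 270, units: g-CO2eq/kW-hr}
    carbon_intensity_extended: {low: 70, mid: 170, high: 270, units: g-CO2eq/kW-hr}

stoves:
  wood_traditional:
    fuel: wood
    # baseline capital and upkeep are sunk / zero by convention
    capital_cost: {value: 0, units: USD}
    lifespan: {value: 3, units: yr}
    time_efficiency: {value: 1.0, units: fraction}
    heat_efficiency: {low: 7, mid: 11, high: 15, units: percent}
    maintenance_cost: {value: 0, units: USD/hh-yr}
    ari_effectiveness: {value: 0, units: percent}
    copd_effectiveness: {value: 0, units: percent}
  wood_ics:
    fuel: wood
    capital_cost: {low: 5, mid: 15, high: 50, units: USD}
    lifespan: {low: 2, mid: 3, high: 4, units: yr}
    time_efficiency: {low: 0.7, mid: 0.95, high: 1.5, units: fraction}
    heat_efficiency: {low: 13, mid: 25, high: 40, units: percent}
    maintenance_cost: {value: 1.4, units: USD/hh-yr}
    ari_effectiveness: {low: 10, mid: 40, high: 70, units: percent}
    copd_effectiveness: {low: 0, mid: 15, high: 30, units: percent}
  charcoal_traditional:
    fuel: charcoal
    capital_cost: {low: 3, mid: 4.5, high: 6, units: USD}
    lifespan: {low: 2, mid: 3, high: 4, units: yr}
    time_efficiency: {low: 0.6, mid: 0.75, high: 1.0, units: fraction}
    heat_efficiency: {low: 18, mid: 20, high: 21, units: percent}
    maintenance_cost: {value: 1.4, units: USD/hh-yr}
    ari_effectiveness: {low: 0, mid: 20, high: 40, units: percent}
    copd_effectiveness: {low: 0, mid: 5, high: 10, units: percent}
  charcoal_ics:
    fuel: charcoal
    capital_cost: {low: 3, mid: 14, high: 50, units: USD}
    lifespan: {low: 2, mid: 3, high: 4, units: yr}
    time_efficiency: {low: 0.6, mid: 0.75, high: 1.0, units: fraction}
    heat_efficiency: {low: 15, mid: 26, high: 37, units: percent}
    maintenance_cost: {value: 1.4, units: USD/hh-yr}
    ari_effectiveness: {low: 10, mid: 40, high: 70, units: percent}
    copd_effectiveness: {low: 0, mid: 15, high: 30, units: percent}
  kerosene:
    fuel: kerosene
    capital_cost: {low: 10, mid: 30, high: 60, units: USD}
    lifespan: {low: 4, mid: 5, high: 6, units: yr}
    time_efficiency: {low: 0.5, mid: 0.7, high: 0.9, units: fraction}
    heat_efficiency: {low: 40, mid: 45, high: 50, units: percent}
    maintenance_cost: {value: 1.4, units: USD/hh-yr}
    ari_effectiveness: {low: 45, mid: 60, high: 75, units: percent}
    copd_effectiveness: {low: 0, mid: 20, high: 40, units: percent}
  lpg:
    fuel: propane
    capital_cost: {low: 60, mid: 90, high: 120, units: USD}
    lifespan: {low: 5, mid: 10, high: 15, units: yr}
    time_efficiency: {low: 0.45, mid: 0.67, high: 0.9, units: fraction}
    heat_efficiency: {low: 50, mid: 55, high: 60, units: percent}
    maintenance_cost: {value: 1.4, units: USD/hh-yr}
    ari_effectiveness: {low: 45, mid: 60, high: 75, units: percent}
    copd_effectiveness: {low: 0, mid: 20, high: 40, units: percent}
  electric:
    fuel: electricity
    capital_cost: {low: 100, mid: 300, high: 500, units: USD}
    lifespan: {low: 10, mid: 15, high: 20, units: yr}
    time_efficiency: {low: 0.35, mid: 0.63, high: 0.9, units: fraction}
    # for the electric stove this is electricity drawn per hour of cooking,
    # not a heat-transfer ratio
    heat_efficiency: {low: 1.10, mid: 1.65, high: 2.20, units: kW-hr/hr-cooking}
    maintenance_cost: {value: 1.4, units: USD/hh-yr}
    ari_effectiveness: {low: 45, mid: 60, high: 75, units: percent}
    copd_effectiveness: {low: 0, mid: 20, high: 40, units: percent}
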
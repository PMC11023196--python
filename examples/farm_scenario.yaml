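n_patches: 100
total_biomass_target: 1000.0
max_years: 500
convergence_tol: 1.0e-06
convergence_window: 10
density_dependent_movement: true
species:
  linf: 100.0
  k_growth: 0.2
  t0: 0.0
  b1: 3.0
  b2: 1.0e-05
  m_nat: 0.2
  max_age: 20
  age_mature: 4
  sigma_m: 2.0
  range_fraction: 0.08
  recruit_steepness: 0.2
  fecundity: 2.0
  legal_length: 45.11883639059736
fishery:
  regime: strong_msy
  total_effort: null
  price: 1.0
  cost_per_effort: 1.1
  catchability: 1.0
  selectivity_steepness: 0.25
  max_effort: 300.0
farm:
  total_fraction: 0.2
  layout: several_small
  farm_unit_size: 5
  attraction: 5.0
  k_multiplier: 3.0
  m_multiplier: 1.0
  zoi_halfwidth: null
  anchor: 0
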
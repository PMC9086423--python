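# Baseline inputs for the FOLFOX-HAIC vs TACE cost-effectiveness model.
# Costs in 2020 USD; survival times in months; probabilities per listed period.
os_tace:
  family: log_logistic
  params: {theta: 0.00272126, kappa: 2.184792}
pfs_tace:
  family: lognormal
  params: {mu: 1.682471, sigma: 1.119812}
hr_os: {baseline: 0.58, low: 0.45, high: 0.75, distribution: lognormal}
hr_pfs: {baseline: 0.57, low: 0.45, high: 0.72, distribution: lognormal}
recurrence_5yr: {baseline: 0.19, low: 0.15, high: 0.20, distribution: beta}
utilities:
  PFD: {baseline: 0.76, low: 0.61, high: 0.91, distribution: beta}
  RFD: {baseline: 0.76, low: 0.61, high: 0.91, distribution: beta}
  PD: {baseline: 0.68, low: 0.54, high: 0.82, distribution: beta}
shared_costs:
  hepatectomy: {baseline: 9022, low: 7218, high: 10827, distribution: gamma}
  hospitalization_per_cycle: {baseline: 384, low: 307, high: 460, distribution: gamma}
  bsc_per_cycle: {baseline: 363, low: 291, high: 436, distribution: gamma}
discount_rate_annual: {baseline: 0.03, low: 0.01, high: 0.05, distribution: uniform}
strategies:
  FOLFOX_HAIC:
    name: FOLFOX_HAIC
    per_session_costs:
      oxaliplatin: {baseline: 426, low: 340, high: 511, distribution: gamma}
      fluorouracil: {baseline: 524, low: 419, high: 629, distribution: gamma}
      leucovorin: {baseline: 24, low: 19, high: 29, distribution: gamma}
      haic_procedure: {baseline: 1850, low: 1480, high: 2220, distribution: gamma}
    n_sessions: 3.6
    session_interval_days: 21
    hepatectomy_proportion: {baseline: 0.24, low: 0.19, high: 0.29, distribution: beta}
    subsequent_mix:
      bsc: {baseline: 0.95, low: 0.76, high: 1.14, distribution: beta}
      crossover: {baseline: 0.05, low: 0.04, high: 0.06, distribution: beta}
    ae_profile:
      - label: elevated_alt
        incidence: {baseline: 0.08, low: 0.06, high: 0.10, distribution: beta}
        unit_cost: {baseline: 43, low: 35, high: 52, distribution: gamma}
        disutility: {baseline: 0, low: 0, high: 0, distribution: beta}
      - label: elevated_ast
        incidence: {baseline: 0.18, low: 0.14, high: 0.22, distribution: beta}
        unit_cost: {baseline: 43, low: 35, high: 52, distribution: gamma}
        disutility: {baseline: 0, low: 0, high: 0, distribution: beta}
      - label: vomiting
        incidence: {baseline: 0.06, low: 0.05, high: 0.07, distribution: beta}
        unit_cost: {baseline: 49, low: 39, high: 59, distribution: gamma}
        disutility: {baseline: 0.05, low: 0.04, high: 0.06, distribution: beta}
  TACE:
    name: TACE
    per_session_costs:
      tace_procedure: {baseline: 1929, low: 1543, high: 2315, distribution: gamma}
    n_sessions: 2
    session_interval_days: 42
    hepatectomy_proportion: {baseline: 0.12, low: 0.10, high: 0.14, distribution: beta}
    subsequent_mix:
      bsc: {baseline: 0.87, low: 0.70, high: 1.04, distribution: beta}
      crossover: {baseline: 0.13, low: 0.10, high: 0.16, distribution: beta}
    ae_profile:
      - label: elevated_alt
        incidence: {baseline: 0.19, low: 0.15, high: 0.23, distribution: beta}
        unit_cost: {baseline: 43, low: 35, high: 52, distribution: gamma}
        disutility: {baseline: 0, low: 0, high: 0, distribution: beta}
      - label: elevated_ast
        incidence: {baseline: 0.29, low: 0.23, high: 0.35, distribution: beta}
        unit_cost: {baseline: 43, low: 35, high: 52, distribution: gamma}
        disutility: {baseline: 0, low: 0, high: 0, distribution: beta}
      - label: vomiting
        incidence: {baseline: 0.05, low: 0.04, high: 0.06, distribution: beta}
        unit_cost: {baseline: 49, low: 39, high: 59, distribution: gamma}
        disutility: {baseline: 0.05, low: 0.04, high: 0.06, distribution: beta}
life_table:
  age_bands:
    - [0, 1, 0.006763658]
    - [1, 5, 0.001144414]
    - [5, 10, 0.000924507]
    - [10, 15, 0.000969999]
    - [15, 20, 0.00179698]
    - [20, 25, 0.002810805]
    - [25, 30, 0.003052746]
    - [30, 35, 0.004239707]
    - [35, 40, 0.006187994]
    - [40, 45, 0.009315495]
    - [45, 50, 0.012327216]
    - [50, 55, 0.01956602]
    - [55, 60, 0.030500498]
    - [60, 65, 0.048778564]
    - [65, 70, 0.078138957]
    - [70, 75, 0.137236768]
    - [75, 80, 0.221445846]
    - [80, 85, 0.371374039]
    - [85, .inf, 1]
structural:
  cycle_length_days: 21
  start_age_years: 55
  horizon_years: 30
  wtp_per_qaly: 30552
  half_cycle_correction: false
  rfd_mortality: os_hazard
  background_mortality: floor
  hospitalization: per_session
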
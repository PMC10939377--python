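# Shipped default run configuration: the two-member cooperator/cheater
# system under a day-4 antibiotic pulse, serial dilution back to a fixed
# total density.  All values can be overridden; unknown keys are rejected.
model:
  members:
    - {name: cooperator_A, role: cooperator, max_growth_rate: 0.5, allee_constant: 0.0}
    - {name: cheater_B, role: cheater, max_growth_rate: 0.75, allee_constant: 0.0}
  interactions:
    coefficients: [[0.0, 1.9], [1.75, 0.0]]
    symmetric_regulator: false
  deaths:
    # cooperator: hormetic growth boost during the pulse
    - {kind: constant, constant_rate: -0.6}
    # cheater: kill rate max(0, 1.0 - 5.0 * D), fully protected at D = 0.2
    - {kind: linear_in_density, slope: -5.0, intercept: 1.0}
protocol:
  cycle_hours: 24.0
  n_cycles: 7
  dilution_mode: to_fixed_total
  dilution_factor: 10.0
  initial_total_density: 0.03
  initial_proportions: null
  antibiotic_window: [72.0, 96.0]
sweep:
  n_points: 25
  cheater_rate_min: 0.3
  cheater_rate_max: 0.75
  density_min: 1.0e-4
  density_max: 1.0e-1
  alpha_min: -1.0
  alpha_max: 2.0
  phenotypes: [sensitive, detoxifying, intrinsic]
  regulator_rate: 0.75
  sweep_density: 0.03
  sweep_n_cycles: 7
synth:
  strains:
    - {name: cooperator_A, growth_rate: 0.5, smx_death_rate: -0.6}
    - {name: cheater_B, growth_rate: 0.75, smx_death_rate: 0.8}
  inoculum_min: 1.0e+5
  inoculum_max: 1.0e+9
  inoculum_n: 5
  smx_concentration: 200.0
  replicates: 6
  od_noise_sigma: 0.02
  sampling_interval: 0.5
  horizon: 72.0
  clearance_coefficient: 1.0e-6
  smx_noise_sigma: 5.0
  cooperator_density: 1.0e+7
solver:
  method: LSODA
  rtol: 1.0e-8
  atol: 1.0e-12
  output_resolution: 0.1
  extinction_floor: 1.0e-9
output:
  directory: kincoex_out
seed: 0
log_level: INFO
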
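# Sample run configuration: default study conditions, explicit overrides.
seed: 1
n_donors: 20000
strata: [age_group, sex]
bounds: [0.3, 3.0]
tol: 1.0e-6
max_iter: 50
offsets: {income: 0.0, welfare: 1.0, tax: 1.0}
counterfactual_method: regression   # or group_mean
preventable_fraction: 0.89
gdp:
  gdp_per_hour: 71.0          # AU$/hour, illustrative 2010 value
  hours_per_worker: 1700.0    # hours/year/worker
  employment_rate: 0.943
  participation_rate: 0.655
  population_15plus: 17800000.0
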
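# Demonstration configuration: a 2,000-patient synthetic trial analysed with
# reduced uncertainty settings (m=5 imputations, 200 bootstrap replicates,
# 100 coefficient draws) so the full pipeline runs in a few minutes on one CPU.
# Removing the imputation/bootstrap/simulation blocks restores the base-case
# defaults (m=28, B=800, 800 draws).
country: US
seed: 7
generator:
  n_patients: 2000
  missing_utility_rate: 0.28
imputation:
  m_utility: 5
  chained_iterations: 5
simulation:
  horizon: 40
  n_coefficient_draws: 100
bootstrap_replicates: 200
thresholds: [0, 300000, 61]
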
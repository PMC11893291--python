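# Planned 900-patient follow-up trial: which fraction pi of patients to
# recruit to subgroup B?  Posterior from the informative-delta analysis.
seed: 20240903
data:
  subgroups:
    - {name: B, label: bone metastases, hr: 0.54, ci: [0.34, 0.84]}
    - {name: C, label: no bone metastases, hr: 0.71, ci: [0.55, 0.91]}
  cov_BC: 0.0
prior:
  parameterization: muC_delta
  mu_C: {family: normal, mean: 0.0, sd: 10.0}
  delta: {family: normal, mean: -0.122, sd: 0.334}
mcmc:
  chains: 2
  iterations_per_chain: 50000
  burn_in: 20000
  thin: 2
design:
  n_total: 900
  pi: [0.333333333333, 0.5, 0.666666666667]
  event_rates:
    B: {active: 0.6, control: 0.8}
    C: {active: 0.5, control: 0.7}
  crit: -1.96
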
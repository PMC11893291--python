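# Renal-cell-cancer example: vague mu_C prior, informative delta prior
# N(-0.122, 0.334^2) derived from a companion trial's two subgroup HRs.
seed: 20240902
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
pi: [0.22]
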
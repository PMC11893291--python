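# Prostate-cancer example with vague independent priors on mu_C and delta.
seed: 20240901
data:
  subgroups:
    - {name: B, label: non-metastatic, hr: 0.75, ci: [0.48, 1.18]}
    - {name: C, label: metastatic, hr: 0.61, ci: [0.49, 0.75]}
  cov_BC: 0.0
prior:
  parameterization: muC_delta
  mu_C: {family: normal, mean: 0.0, sd: 10.0}
  delta: {family: normal, mean: 0.0, sd: 10.0}
mcmc:
  chains: 2
  iterations_per_chain: 50000
  burn_in: 20000
  thin: 2
pi: [0.52]
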
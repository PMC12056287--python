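# Demo pipeline manifest: small synthetic cohort, full stage chain.
seed: 11
stages: [simulate, phenotype, contacts, interactions, nests, cohort]
simulate:
  n_msi: 4
  n_mss: 4
  frac_msi_like: 0.0
interactions:
  n_perm: 200
  max_samples: 2
contacts:
  max_samples: 2
nests:
  eps_um: 40.0
  min_pts: 27
  max_samples: 2
cohort:
  k: 5
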
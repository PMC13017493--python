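# Two-stratum demonstration trial: 5 blocks of 25 plots per stratum,
# 40 replicated test genotypes, moderate spatial gradients and noise.
seed: 7
strata:
  - location: SF
    spacing: 76cm
    n_blocks: 5
  - location: EF
    spacing: 38cm
    n_blocks: 5
trial:
  n_test_genotypes: 40
  yield_noise_sd: 120.0
timecourse:
  noise_sd: 0.12
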
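# directional pleiotropy: biases IVW, detected by the Egger intercept
n_snp: 50
beta_causal: 0.1
pleiotropy_mode: directional
pleiotropy_mean: 0.02
pleiotropy_sd: 0.01
ld_blocks:
  - [5, 0.8]
  - [4, 0.3]
seed: 103
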
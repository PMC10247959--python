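# no causal effect, no pleiotropy: type-I error / coverage scenario
n_snp: 50
beta_causal: 0.0
pleiotropy_mode: none
seed: 101
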
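# moderate causal effect with balanced (InSIDE-respecting) pleiotropy
n_snp: 50
beta_causal: 0.1
pleiotropy_mode: balanced
pleiotropy_sd: 0.01
seed: 104
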
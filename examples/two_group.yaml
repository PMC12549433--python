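model: two_group
params:
  mu: 2.9
  kappa: 0.1
  lam1: 1.0
  lam2: 2.0
  nu1: 2.0
  nu2: 1.0
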
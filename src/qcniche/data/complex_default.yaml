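kind: ComplexParameterSet
parameters:
  alpha: 0.3
  gamma: 25.0
  eps_B: 0.5
  eps_W: 2.0
  K_B: 1.0
  K_W: 0.5
  W0: 1.0
  B0: 0.5
  B1: 1.0
  d_B: 1.0
  d_W: 1.0
  beta: 10.0
  lambda_BW: 5.0
  lambda_BS: 2.0
  lambda_WS: 2.0
  mu_BW: 0.2
  mu_BS: 1.0
  mu_WS: 1.0
  d_BW: 0.2
  d_BS: 1.0
  d_WS: 1.0
  d_S: 1.0
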
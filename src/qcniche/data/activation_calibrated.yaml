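kind: ParameterSet
parameters:
  alpha: 0.3
  gamma: 25.0
  eps_B: 0.7058161161553839
  eps_W: 2.234508112236187
  K_B: 1.0003980276078732
  K_W: 0.3204115820858725
  W0: 4.946260059027716
  B0: 0.34368317382388147
  B1: 0.9965282588383373
  d_B: 1.0005170682700586
  d_W: 0.9997079212638849
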
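kind: ParameterSet
parameters:
  alpha: 0.3
  gamma: 25.0
  eps_B: 0.6035247820487694
  eps_W: 2.288325404790292
  K_B: 1.0004191097313142
  K_W: 0.48631002569629694
  W0: 4.720439800985206
  B0: 0.462846189416399
  B1: 1.0005536307322904
  d_B: 0.9998165906397218
  d_W: 1.0005465806045686
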
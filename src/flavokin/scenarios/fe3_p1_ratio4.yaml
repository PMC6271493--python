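# Fe(III)-P1 two-step binding at 4 equiv. Fe(III) (50 uM pigment).
family: two_step
params:
  kb: 2670.0
  kr: 29.0e-3
  eps_L: {470: 15000.0, 620: 0.0}
  eps_1: {470: 10360.0, 620: 9710.0}
  eps_2: {470: 8900.0, 620: 9930.0}
conditions:
  L0: 5.0e-5
  M0: 2.0e-4
design:
  t_max: 120.0
  dt: 0.5
  wavelengths: [470, 620]
noise:
  kind: additive
  sigma: 0.002
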
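# Fe(III)-P1 two-step binding, equimolar iron and pigment (50 uM each,
# pH 4 acetate buffer).  Ground truth from the published simultaneous
# 470/620 nm fit; free-pigment absorptions are generator defaults.
family: two_step
params:
  kb: 17890.0          # M^-1 s^-1
  kr: 4.0e-3           # s^-1
  eps_L: {470: 15000.0, 620: 0.0}
  eps_1: {470: 10340.0, 620: 12270.0}
  eps_2: {470: 7910.0, 620: 10810.0}
conditions:
  L0: 5.0e-5           # M pigment
  M0: 5.0e-5           # M Fe(III)
design:
  t_max: 120.0         # s, sampled every 0.5 s
  dt: 0.5
  wavelengths: [470, 620]
noise:
  kind: additive
  sigma: 0.002         # AU
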
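# Fe(III)-P2 reversible 1:1 binding at equilibrium: dA(650 nm) vs total
# iron, 50 uM pigment, metal/pigment ratios 0.5-5.
family: isotherm
params:
  Kb: 21000.0          # M^-1
  delta_eps: 6500.0    # M^-1 cm^-1
conditions:
  Lt: 5.0e-5
design:
  ratios: [0.5, 1, 2, 3, 4, 5]
  wavelength: 650
noise:
  kind: additive
  sigma: 0.005
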
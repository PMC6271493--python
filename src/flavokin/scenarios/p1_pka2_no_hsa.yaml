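# A(550 nm) vs pH titration of the P1 quinonoid bases around neutrality
# (no HSA): two-state sigmoid in (pKa2, rA).
family: pka2
params:
  pKa2: 7.12
  rA: 6.3
  A_neutral: 0.3       # AU
design:
  pH_min: 6.0
  pH_max: 8.0
  pH_step: 0.2
  wavelength: 550
noise:
  kind: additive
  sigma: 0.005
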
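# Fe(II) added to P2 (50 uM) at 5 equiv.: autoxidation to Fe(III) then
# binding; chalcone formation negligible for the glucoside (kh_obs = 0).
# Slow-process acquisition: every 15 s over 15 min.
family: autox
params:
  kautox: 163.0e-5     # s^-1
  kb: 785.0            # M^-1 s^-1
  kh_obs: 0.0
  eps_L: {470: 15000.0, 650: 0.0}
  eps_ML: {470: 8810.0, 650: 7340.0}
  eps_CE: {}
conditions:
  L0: 5.0e-5
  M0: 2.5e-4
design:
  t_max: 900.0
  dt: 15.0
  wavelengths: [470, 650]
noise:
  kind: additive
  sigma: 0.002
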
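# Fe(II) added to P1 (50 uM) at 5 equiv.: autoxidation, binding and
# competing chalcone formation, followed at 470/630/375 nm.
family: autox
params:
  kautox: 58.0e-5
  kb: 250.0
  kh_obs: 95.0e-5
  eps_L: {470: 15000.0, 630: 0.0, 375: 3000.0}
  eps_ML: {470: 10700.0, 630: 11800.0, 375: 4200.0}
  eps_CE: {375: 33800.0}
conditions:
  L0: 5.0e-5
  M0: 2.5e-4
design:
  t_max: 900.0
  dt: 15.0
  wavelengths: [470, 630, 375]
noise:
  kind: additive
  sigma: 0.002
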
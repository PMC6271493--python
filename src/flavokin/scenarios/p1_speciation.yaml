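# Equilibrium constants of P1 (3',4',7-trihydroxyflavylium) used for
# mole-fraction diagrams; hydration rate at pH 4.
family: speciation
params:
  pKa1: 4.44
  pKa2: 7.12
  pKh_app: 3.45
  kh_obs: 120.0e-5     # s^-1, color loss at pH 4
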
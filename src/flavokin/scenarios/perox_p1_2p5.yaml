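# Metmyoglobin-induced linoleic-acid peroxidation inhibited by 2.5 uM P1
# (colored forms), pH 5.8 + Brij 35, 37 C; CD absorbance at 234 nm.
family: perox
params:
  ki1: 3.0e+3          # M^-1 s^-1, frozen in inhibited fits
  r2: 2.1              # M^-1/2 s^-1/2
  AE: 11.0
  n: 4.0
  eps_CD: 24.0e+3
conditions:
  LH0: 7.0e-4
  Mb0: 5.0e-7
  AH0: 2.5e-6
  LOOH0: 1.0e-6
design:
  t_max: 1800.0
  dt: 10.0
noise:
  kind: additive
  sigma: 0.005
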
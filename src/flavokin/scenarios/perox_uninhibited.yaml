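# Uninhibited metmyoglobin-induced peroxidation (no antioxidant), used
# to pin ki1 before inhibited fits.  r2 set to the low-antioxidant limit
# of the published fits.
family: perox
params:
  ki1: 3.0e+3
  r2: 2.8
  AE: 0.0
  n: 0.0
  eps_CD: 24.0e+3
conditions:
  LH0: 7.0e-4
  Mb0: 5.0e-7
  AH0: 0.0
  LOOH0: 1.0e-6
design:
  t_max: 1800.0
  dt: 10.0
noise:
  kind: additive
  sigma: 0.005
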
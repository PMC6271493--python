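# HSA (2 uM) fluorescence quenching titrations at pH 7.4, inner-filter
# path 0.65 cm; one ligand block per published row.  eps_ex/eps_em are
# the ligand Beer-plot absorptions at 295 and 340 nm.
family: quench
conditions:
  Pt: 2.0e-6
  path_l: 0.65
design:
  Lt_max: 2.0e-5
  n_points: 11
noise:
  kind: multiplicative
  sigma: 0.01
ligands:
  p1_colored:  {Kb: 273.0e+3, fP: 15.5e+6, eps_ex: 8900.0, eps_em: 5800.0}
  p1_chalcone: {Kb: 344.0e+3, fP: 14.2e+6, eps_ex: 15800.0, eps_em: 16400.0}
  p2_colored:  {Kb: 17.5e+3, fP: 14.1e+6, eps_ex: 3800.0, eps_em: 2800.0}
  p2_chalcone: {Kb: 58.4e+3, fP: 13.5e+6, eps_ex: 7200.0, eps_em: 7000.0}
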
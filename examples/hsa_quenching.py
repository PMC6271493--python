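"""Serum-albumin binding by Trp fluorescence quenching.

Titrates 2 uM HSA with the P1 colored forms (0-20 uM), generating the
inner-filter-corrected intensities, then refits (Kb, fP) with the
ligand absorptions fixed from their Beer plot — exactly the analysis a
fluorimeter titration needs.  Also shows the chalcone-mixture
deconvolution: the apparent constant of an equilibrated chalcone
solution still contains 25% colored forms.
"""

import numpy as np

import flavokin as fk

sc = fk.load_scenario("hsa_quench")
lig = sc["ligands"]["p1_colored"]
truth = fk.QuenchParams(Kb=lig["Kb"], fP=lig["fP"], epsL_ex=lig["eps_ex"],
                        epsL_em=lig["eps_em"], path_l=sc["conditions"]["path_l"])
Pt = sc["conditions"]["Pt"]
Lt = np.linspace(0.0, sc["design"]["Lt_max"], sc["design"]["n_points"])

tit = fk.make_quench_series(
    truth, Lt, Pt, fk.NoiseSpec("multiplicative", sc["noise"]["sigma"], seed=3))
res = fk.fit_quench(tit, truth.epsL_sum, path_l=truth.path_l)
print(res.summary())
print(f"\ntruth: Kb = {truth.Kb:g} M^-1 (fit without the inner-filter "
      "correction would overestimate it)")

kb_chalcone = fk.deconvolve_chalcone_kb(344e3, 273e3, chalcone_fraction=0.75)
print(f"chalcone-only constant from the 3:1 mixture: {kb_chalcone/1e3:.0f}e3 M^-1")
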
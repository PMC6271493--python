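"""Species distribution of a 3-deoxyanthocyanidin across pH.

Builds the P1 equilibrium constants, prints the mole fractions of the
flavylium cation, quinonoid bases and (E)-chalcone at gastric (pH 4)
and plasma (pH 7.4) acidity, and the pH-independent chalcone/base
ratio Ki.  The dominance of the colorless chalcone near neutrality is
what makes the colorless forms matter for albumin transport.
"""

import flavokin as fk

sc = fk.load_scenario("p1_speciation")["params"]
constants = fk.EquilibriumConstants(
    pKa1=sc["pKa1"], pKa2=sc["pKa2"], pKh_app=sc["pKh_app"])

print(f"Ki = (CE)/(A) = {constants.ki_implied:.2f}  (~10: chalcone-favored)")
for pH in (4.0, 7.4):
    f = fk.mole_fractions(constants, pH)
    parts = ", ".join(f"{s}: {v:.3f}" for s, v in f.items())
    print(f"pH {pH}: {parts}")

t_half = fk.half_life(sc["kh_obs"])
print(f"color-loss half-life at pH 4: {t_half:.0f} s (~{t_half/60:.0f} min)")
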
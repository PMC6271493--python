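"""Speciation equilibria, pH titration and first-order color loss."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flavokin as fk
from flavokin.speciation import EquilibriumConstants


class TestMoleFractions:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        pKa1=st.floats(2, 7), pKa2=st.floats(5, 10), pKh=st.floats(2, 7),
        pH=st.floats(0, 14),
    )
    def test_fractions_sum_to_one(self, pKa1, pKa2, pKh, pH):
        c = EquilibriumConstants(pKa1=pKa1, pKa2=pKa2, pKh_app=pKh)
        f = fk.mole_fractions(c, pH)
        assert math.isclose(sum(f.values()), 1.0, abs_tol=1e-12)
        assert all(v >= 0 for v in f.values())

    def test_symmetry_at_matching_constants(self):
        # pKa1 == pKh_app and pH at that value, anionic base negligible:
        # flavylium, neutral base and chalcone are equally populated
        c = EquilibriumConstants(pKa1=5.0, pKa2=13.5, pKh_app=5.0)
        f = fk.mole_fractions(c, 5.0)
        assert f["AH+"] == pytest.approx(f["A"], rel=1e-9)
        assert f["A"] == pytest.approx(f["CE"], rel=1e-9)

    def test_p1_neutral_ph_chalcone_dominates(self):
        # P1 constants: at pH 7.4 the chalcone outweighs the colored
        # bases roughly 3:1 (10^3.95 vs 10^2.96 * (1 + 10^0.28))
        c = EquilibriumConstants(pKa1=4.44, pKa2=7.12, pKh_app=3.45)
        f = fk.mole_fractions(c, 7.4)
        ratio = f["CE"] / (f["A"] + f["A-"])
        assert ratio == pytest.approx(3.36, abs=0.05)
        assert round(ratio) == 3

    @pytest.mark.parametrize("pH", [-0.5, 14.2])
    def test_ph_out_of_range_rejected(self, pH):
        c = EquilibriumConstants(pKa1=4.44, pKa2=7.12, pKh_app=3.45)
        with pytest.raises(ValueError):
            fk.mole_fractions(c, pH)


class TestChalconeBaseRatio:
    @pytest.mark.parametrize("pKa1, pKh, expected", [
        (4.44, 3.45, 9.772),   # P1: rounds to the reported ~10
        (5.0, 5.0, 1.0),
        (5.0, 3.0, 100.0),
    ])
    def test_values(self, pKa1, pKh, expected):
        assert fk.chalcone_base_ratio(pKa1, pKh) == pytest.approx(expected, rel=1e-3)

    def test_p1_ratio_rounds_to_ten(self):
        assert round(fk.chalcone_base_ratio(4.44, 3.45)) == 10

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a=st.floats(1, 8), b=st.floats(1, 8))
    def test_reciprocal_product_is_one(self, a, b):
        assert fk.chalcone_base_ratio(a, b) * fk.chalcone_base_ratio(b, a) == \
            pytest.approx(1.0, rel=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            fk.chalcone_base_ratio(float("nan"), 3.0)

    def test_consistency_invariant_enforced(self):
        with pytest.raises(ValueError):
            EquilibriumConstants(pKa1=4.44, pKa2=7.12, pKh_app=3.45, Ki=20.0)
        c = EquilibriumConstants(pKa1=4.44, pKa2=7.12, pKh_app=3.45, Ki=9.8)
        assert c.ki_implied == pytest.approx(9.772, rel=1e-3)


class TestTitrationCurve:
    def test_midpoint(self):
        a = fk.titration_curve(7.12, 6.3, 0.3, [7.12])
        assert a[0] == pytest.approx(0.3 * (1 + 6.3) / 2, rel=1e-12)

    def test_degenerate_ra_one_is_flat(self):
        a = fk.titration_curve(7.0, 1.0, 0.42, np.linspace(4, 10, 13))
        assert np.allclose(a, 0.42, rtol=1e-12)

    def test_known_endpoint_ratio(self):
        # closed form evaluated by hand at pH 8.0 and 6.0
        a = fk.titration_curve(7.12, 6.3, 0.3, [6.0, 8.0])
        assert a[1] == pytest.approx(1.7048100, rel=1e-6)
        assert a[0] == pytest.approx(0.4121095, rel=1e-6)
        assert a[1] / a[0] == pytest.approx(4.136789, rel=1e-6)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        pKa2=st.floats(5, 9), rA=st.floats(0.1, 20), A=st.floats(0.05, 2),
        pH=st.floats(0, 14),
    )
    def test_bounded_between_endpoint_absorbances(self, pKa2, rA, A, pH):
        val = fk.titration_curve(pKa2, rA, A, [pH])[0]
        lo, hi = sorted((A, rA * A))
        assert lo - 1e-9 <= val <= hi + 1e-9

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            fk.titration_curve(7.0, 2.0, 0.3, [])


class TestFitPka2:
    def test_noiseless_recovery(self):
        pH = np.arange(6.0, 8.01, 0.2)
        a = fk.titration_curve(7.12, 6.3, 0.3, pH)
        res = fk.fit_pka2(pH, a)
        assert res.converged
        assert res.estimates["pKa2"] == pytest.approx(7.12, abs=1e-6)
        assert res.estimates["rA"] == pytest.approx(6.3, rel=1e-6)
        assert res.estimates["A_neutral"] == pytest.approx(0.3, rel=1e-6)

    def test_flat_series_flagged_unidentifiable(self):
        pH = np.arange(6.0, 8.01, 0.2)
        a = fk.titration_curve(7.12, 1.0, 0.3, pH)  # rA = 1: no transition
        res = fk.fit_pka2(pH, a)
        assert not res.identifiable

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fk.fit_pka2([6.5, 7.0, 7.5], [0.3, 0.5, 0.7])


class TestFirstOrder:
    def test_initial_value(self):
        assert fk.first_order_decay(0.8, 0.1, 1e-3, 0.0) == pytest.approx(0.8)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            fk.first_order_decay(0.8, 0.1, 1e-3, -1.0)

    def test_half_life_at_ph4_is_about_ten_minutes(self):
        # kh_obs = 120e-5 s^-1 for free P1 at pH 4
        t_half = fk.half_life(120e-5)
        assert t_half == pytest.approx(577.62, abs=0.01)
        assert round(t_half / 60) == 10

    def test_half_life_matches_numerical_midpoint(self):
        # root of A(t) - (A0+Ainf)/2 for kh_obs = 88e-5 s^-1
        assert fk.half_life(88e-5) == pytest.approx(787.667, abs=1e-2)

    def test_two_wavelength_shared_rate_recovery(self):
        # decay at 530 nm, rise at 375 nm, one shared rate constant
        t = np.arange(0.0, 3600.0, 30.0)
        k = 88e-5
        curves = {
            "530": fk.first_order_decay(0.75, 0.05, k, t),
            "375": fk.first_order_decay(0.10, 0.95, k, t),
        }
        res = fk.fit_first_order(t, curves)
        assert res.converged
        assert res.estimates["kh_obs"] == pytest.approx(k, rel=1e-8)
        assert res.estimates["A0_530"] == pytest.approx(0.75, rel=1e-8)
        assert res.estimates["Ainf_375"] == pytest.approx(0.95, rel=1e-8)

    def test_hydration_kinetics_validation(self):
        with pytest.raises(ValueError):
            fk.HydrationKinetics(kh_obs=-1e-5)
        assert fk.HydrationKinetics(kh_obs=120e-5).half_life_s == \
            pytest.approx(577.62, abs=0.01)
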
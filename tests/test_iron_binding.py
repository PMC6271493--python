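"""Two-step Fe(III) binding, reversible isotherm, Fe(II) autoxidation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

import flavokin as fk


class TestSimulateTwoStep:
    def test_initial_condition(self, two_step_truth, kinetic_grid):
        ts, traj = fk.simulate_two_step(two_step_truth, 50e-6, 50e-6, kinetic_grid)
        assert traj["L"].iloc[0] == pytest.approx(50e-6)
        assert traj["FeL1"].iloc[0] == 0 and traj["FeL2"].iloc[0] == 0
        # A(470, 0) = eps_L * L0
        assert ts.traces[470.0][0] == pytest.approx(15000.0 * 50e-6, rel=1e-12)

    def test_equal_concentration_closed_form_at_kr_zero(self, kinetic_grid):
        # d[L]/dt = -kb L^2 when M0 = L0 and kr = 0: L = L0/(1 + kb L0 t)
        p = fk.TwoStepParams(kb=17890.0, kr=0.0,
                             eps_L={470: 15000.0}, eps_1={470: 10340.0},
                             eps_2={470: 7910.0})
        _, traj = fk.simulate_two_step(p, 50e-6, 50e-6, kinetic_grid)
        closed = 50e-6 / (1 + 17890.0 * 50e-6 * kinetic_grid)
        assert np.max(np.abs(traj["L"].to_numpy() - closed)) / 50e-6 < 1e-8

    def test_long_time_absorbance_reaches_thermodynamic_complex(self):
        # 4 equiv. Fe(III): all pigment ends as FeL2, A(470) -> eps_2 * L0
        p = fk.TwoStepParams(kb=2670.0, kr=29e-3,
                             eps_L={470: 15000.0, 620: 0.0},
                             eps_1={470: 10360.0, 620: 9710.0},
                             eps_2={470: 8900.0, 620: 9930.0})
        t = np.linspace(0.0, 3000.0, 200)
        ts, _ = fk.simulate_two_step(p, 50e-6, 200e-6, t)
        assert ts.traces[470.0][-1] == pytest.approx(0.445, abs=1e-3)

    def test_mass_conservation_and_positivity(self, two_step_truth, kinetic_grid):
        _, traj = fk.simulate_two_step(two_step_truth, 50e-6, 75e-6, kinetic_grid)
        pigment = traj["L"] + traj["FeL1"] + traj["FeL2"]
        iron = traj["Fe"] + traj["FeL1"] + traj["FeL2"]
        assert np.max(np.abs(pigment - 50e-6)) / 50e-6 < 1e-9
        assert np.max(np.abs(iron - 75e-6)) / 75e-6 < 1e-9
        assert (traj[["L", "Fe", "FeL1", "FeL2"]].to_numpy() >= -1e-12).all()

    def test_invalid_inputs_rejected(self, two_step_truth):
        with pytest.raises(ValueError):
            fk.simulate_two_step(two_step_truth, -1e-6, 50e-6, [0.0, 1.0])
        with pytest.raises(ValueError):
            fk.simulate_two_step(two_step_truth, 50e-6, 50e-6, [1.0, 2.0])


class TestFitTwoStep:
    def test_noiseless_recovery(self, two_step_truth, kinetic_grid):
        ts, _ = fk.simulate_two_step(two_step_truth, 50e-6, 50e-6, kinetic_grid)
        res = fk.fit_two_step(ts, 50e-6, 50e-6, eps_L=two_step_truth.eps_L)
        assert res.converged
        truth = {"kb": 17890.0, "kr": 4e-3,
                 "eps1_470": 10340.0, "eps2_470": 7910.0,
                 "eps1_620": 12270.0, "eps2_620": 10810.0}
        for k, v in truth.items():
            assert res.estimates[k] == pytest.approx(v, rel=1e-6), k
        assert res.residual_norm < 1e-8 * np.linalg.norm(
            np.concatenate(list(ts.traces.values())))

    def test_weak_rearrangement_has_large_reported_se(self, kinetic_grid):
        # kr * t_max << 1: the rearrangement is barely sampled, its SE
        # must say so rather than the estimate being clipped
        p = fk.TwoStepParams(kb=17890.0, kr=1e-6,
                             eps_L={470: 15000.0, 620: 0.0},
                             eps_1={470: 10340.0, 620: 12270.0},
                             eps_2={470: 7910.0, 620: 10810.0})
        ts, _ = fk.simulate_two_step(p, 50e-6, 50e-6, kinetic_grid)
        noisy = {wl: a + np.random.default_rng(0).normal(0, 2e-3, a.shape)
                 for wl, a in ts.traces.items()}
        ts_noisy = fk.SpectralTraceSet(times=ts.times, traces=noisy)
        res = fk.fit_two_step(ts_noisy, 50e-6, 50e-6, eps_L=p.eps_L)
        assert (not res.identifiable) or res.std_errors["kr"] > res.estimates["kr"]

    def test_too_short_trace_rejected(self, two_step_truth):
        t = np.linspace(0, 10, 10)
        ts, _ = fk.simulate_two_step(two_step_truth, 50e-6, 50e-6, t)
        with pytest.raises(ValueError):
            fk.fit_two_step(ts, 50e-6, 50e-6)


class TestIsotherm:
    def test_zero_metal_gives_zero_signal(self):
        p = fk.IsothermParams(Kb=21e3, delta_eps=6500.0)
        assert fk.isotherm_deltaA(p, 50e-6, 0.0) == pytest.approx(0.0)

    def test_stoichiometric_limit_at_large_kb(self):
        # Kb -> inf with Mt < Lt: every metal ion is bound
        p = fk.IsothermParams(Kb=1e12, delta_eps=6500.0)
        dA = fk.isotherm_deltaA(p, 50e-6, 30e-6)
        assert dA == pytest.approx(6500.0 * 30e-6, rel=1e-4)

    def test_published_conditions_value(self):
        # Fe(III)-P2: Kb=21e3, delta_eps=6500, 50 uM pigment, 5 equiv.
        # frozen from a bisection solve of the mass-balance equation
        p = fk.IsothermParams(Kb=21e3, delta_eps=6500.0)
        assert fk.isotherm_deltaA(p, 50e-6, 250e-6) == pytest.approx(
            0.264755, abs=1e-5)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        logKb=st.floats(2, 7), de=st.floats(500, 30000),
        Lt=st.floats(1e-6, 1e-3), ratio=st.floats(0.01, 20),
    )
    def test_matches_bisection_oracle(self, logKb, de, Lt, ratio):
        Kb = 10.0 ** logKb
        Mt = ratio * Lt
        p = fk.IsothermParams(Kb=Kb, delta_eps=de)
        dA = float(fk.isotherm_deltaA(p, Lt, Mt))
        free = brentq(lambda x: x * (1 + Kb * Lt / (1 + Kb * x)) - Mt,
                      0.0, Mt, xtol=1e-30, rtol=1e-15)
        expected = de * (Mt - free)
        assert dA == pytest.approx(expected, rel=1e-12, abs=1e-15)
        bound = Mt - free
        assert -1e-15 <= bound <= min(Mt, Lt) + 1e-12

    def test_monotone_in_metal_and_affinity(self):
        Mt = np.linspace(0, 300e-6, 40)
        p1 = fk.IsothermParams(Kb=1e4, delta_eps=6500.0)
        p2 = fk.IsothermParams(Kb=5e4, delta_eps=6500.0)
        a1 = fk.isotherm_deltaA(p1, 50e-6, Mt)
        a2 = fk.isotherm_deltaA(p2, 50e-6, Mt)
        assert np.all(np.diff(a1) >= -1e-15)
        assert np.all(a2[1:] >= a1[1:])

    def test_fit_noiseless_exact(self):
        truth = fk.IsothermParams(Kb=21e3, delta_eps=6500.0)
        Mt = np.array([0.5, 1, 2, 3, 4, 5]) * 50e-6
        iso = fk.make_isotherm(truth, 50e-6, Mt, fk.NoiseSpec("additive", 0.0, 0))
        res = fk.fit_isotherm(iso)
        assert res.converged
        assert res.estimates["Kb"] == pytest.approx(21e3, rel=1e-6)
        assert res.estimates["delta_eps"] == pytest.approx(6500.0, rel=1e-6)

    def test_linear_regime_flagged(self):
        # far from saturation dA ~ Kb*delta_eps*Lt*Mt: only the product
        # is determined and the condition number must say so
        truth = fk.IsothermParams(Kb=10.0, delta_eps=6500.0)
        Mt = np.linspace(1e-6, 10e-6, 8)
        iso = fk.make_isotherm(truth, 50e-6, Mt, fk.NoiseSpec("additive", 0.0, 0))
        res = fk.fit_isotherm(iso)
        assert not res.identifiable


class TestAutoxidation:
    def test_no_autoxidation_means_pure_hydration(self):
        p = fk.AutoxParams(kautox=0.0, kb=785.0, kh_obs=95e-5,
                           eps_L={470: 15000.0}, eps_ML={470: 8810.0})
        t = np.arange(0.0, 915.0, 15.0)
        _, traj = fk.simulate_autox(p, 50e-6, 250e-6, t)
        assert np.allclose(traj["L"], 50e-6 * np.exp(-95e-5 * t), rtol=1e-8)
        assert np.max(traj["LFe"]) < 1e-15

    def test_no_hydration_conserves_colored_pool(self, autox_truth_p2):
        t = np.arange(0.0, 915.0, 15.0)
        _, traj = fk.simulate_autox(autox_truth_p2, 50e-6, 250e-6, t)
        assert np.max(np.abs(traj["L"] + traj["LFe"] - 50e-6)) / 50e-6 < 1e-9
        iron = traj["FeII"] + traj["FeIII"] + traj["LFe"]
        assert np.max(np.abs(iron - 250e-6)) / 250e-6 < 1e-9

    def test_complex_band_shows_lag_phase(self, autox_truth_p2):
        # Fe(III) must first accumulate: initial slope of A(650) is far
        # below the maximal slope (fine sampling resolves the lag)
        t = np.arange(0.0, 905.0, 5.0)
        ts, _ = fk.simulate_autox(autox_truth_p2, 50e-6, 250e-6, t)
        a = ts.traces[650.0]
        slopes = np.diff(a) / np.diff(t)
        assert slopes[0] < 0.25 * slopes.max()

    def test_full_mode_noiseless_recovery(self, autox_truth_p2):
        t = np.arange(0.0, 915.0, 15.0)
        ts, _ = fk.simulate_autox(autox_truth_p2, 50e-6, 250e-6, t)
        res = fk.fit_autox(ts, 50e-6, 250e-6, "full")
        assert res.converged
        assert res.estimates["kautox"] == pytest.approx(163e-5, rel=1e-6)
        assert res.estimates["kb"] == pytest.approx(785.0, rel=1e-6)
        assert res.estimates["epsML_470"] == pytest.approx(8810.0, rel=1e-6)

    def test_three_wavelength_variant_recovers_chalcone_channel(self):
        # Fe(II)-P1: hydration competes with binding; chalcone detected
        # at 375 nm with its own absorption
        p = fk.AutoxParams(kautox=58e-5, kb=250.0, kh_obs=95e-5,
                           eps_L={470: 15000.0, 630: 0.0, 375: 3000.0},
                           eps_ML={470: 10700.0, 630: 11800.0, 375: 4200.0},
                           eps_CE={375: 33800.0})
        t = np.arange(0.0, 915.0, 15.0)
        ts, _ = fk.simulate_autox(p, 50e-6, 250e-6, t)
        res = fk.fit_autox(ts, 50e-6, 250e-6, "full",
                           eps_CE={375: 33800.0}, fit_kh_obs=True)
        assert res.converged
        assert res.estimates["kb"] == pytest.approx(250.0, rel=1e-5)
        assert res.estimates["kautox"] == pytest.approx(58e-5, rel=1e-5)
        assert res.estimates["kh_obs"] == pytest.approx(95e-5, rel=1e-5)

    def test_steady_state_mode_recovery_and_substoichiometric_flag(self):
        # at Mt/Lt <= 1 every Fe(III) formed binds at once; (kautox,
        # kh_obs) remain, kb is eliminated
        gen = fk.AutoxParams(kautox=215e-5, kb=1e6, kh_obs=13.7e-5,
                             eps_L={470: 15000.0, 650: 0.0},
                             eps_ML={470: 8800.0, 650: 7200.0})
        t = np.arange(0.0, 915.0, 15.0)
        ts, _ = fk.simulate_autox(gen, 50e-6, 25e-6, t)
        res = fk.fit_autox(ts, 50e-6, 25e-6, "steady_state_FeIII",
                           eps_ML={470: 8800.0, 650: 7200.0})
        assert res.converged
        assert res.estimates["kautox"] == pytest.approx(215e-5, rel=1e-3)
        assert res.estimates["kh_obs"] == pytest.approx(13.7e-5, rel=1e-3)
        # full mode is allowed there but must warn about kb
        res_full = fk.fit_autox(ts, 50e-6, 25e-6, "full")
        assert "weak-kb-identifiability" in res_full.flags

    def test_unknown_mode_rejected(self, autox_truth_p2):
        t = np.arange(0.0, 915.0, 15.0)
        ts, _ = fk.simulate_autox(autox_truth_p2, 50e-6, 250e-6, t)
        with pytest.raises(ValueError):
            fk.fit_autox(ts, 50e-6, 250e-6, "qss")
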
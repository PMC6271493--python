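import numpy as np
import pytest

import flavokin as fk


@pytest.fixture(scope="session")
def two_step_truth():
    """Published Fe(III)-P1 equimolar parameter set (50 uM each)."""
    return fk.TwoStepParams(
        kb=17890.0, kr=4e-3,
        eps_L={470: 15000.0, 620: 0.0},
        eps_1={470: 10340.0, 620: 12270.0},
        eps_2={470: 7910.0, 620: 10810.0},
    )


@pytest.fixture(scope="session")
def kinetic_grid():
    """0.5 s sampling over 2 min (binding-kinetics acquisition)."""
    return np.arange(0.0, 120.5, 0.5)


@pytest.fixture(scope="session")
def autox_truth_p2():
    """Fe(II)-P2 at 5 equiv. iron: autoxidation + binding, no chalcone."""
    return fk.AutoxParams(
        kautox=163e-5, kb=785.0, kh_obs=0.0,
        eps_L={470: 15000.0, 650: 0.0},
        eps_ML={470: 8810.0, 650: 7340.0},
    )


@pytest.fixture(scope="session")
def perox_inhibited_truth():
    """P1 colored forms at 2.5 uM in the peroxidation assay."""
    return fk.PeroxParams(ki1=3e3, r2=2.1, AE=11.0, n=4.0)


@pytest.fixture(scope="session")
def perox_grid():
    """10 s sampling over 30 min (conjugated-diene accumulation)."""
    return np.arange(0.0, 1810.0, 10.0)


@pytest.fixture(scope="session")
def quench_truth():
    """HSA quenching by the P1 colored forms."""
    return fk.QuenchParams(Kb=273e3, fP=15.5e6, epsL_ex=8900.0, epsL_em=5800.0)
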
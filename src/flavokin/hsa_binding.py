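"""Ligand binding to human serum albumin by fluorescence quenching.

The intrinsic Trp-214 fluorescence of HSA is quenched on 1:1 ligand
binding.  Because flavylium pigments and especially their chalcones
absorb at the excitation (295 nm) and emission (340 nm) wavelengths, the
raw intensity also carries an inner-filter attenuation; the observation
model is

    I_F = fP * [P] * exp(-eps_L * l * Lt)

where fP is the molar fluorescence of free protein, eps_L the sum of
the ligand molar absorptions at excitation and emission wavelengths
(fixed from an independent Beer plot), l the mean excitation path at the
detection point (0.65 cm for the instrument modelled here) and [P] the
free-protein concentration from the 1:1 mass-action equilibrium.

The chalcone titrations are performed on equilibrated mixtures that
still contain residual colored forms; ``deconvolve_chalcone_kb``
recovers the chalcone-only constant from the apparent one by linear
mole-fraction weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import FluorescenceTitration
from .fitting import FitResult, least_squares_fit
from .utils import stable_positive_root

__all__ = [
    "QuenchParams",
    "free_species",
    "predicted_fluorescence",
    "fit_quench",
    "deconvolve_chalcone_kb",
]


@dataclass(frozen=True)
class QuenchParams:
    """Parameters of the inner-filter-corrected quenching model."""

    Kb: float           # M^-1
    fP: float           # fluorescence units per M protein
    epsL_ex: float      # M^-1 cm^-1 at the excitation wavelength
    epsL_em: float      # M^-1 cm^-1 at the emission wavelength
    path_l: float = 0.65  # cm

    def __post_init__(self) -> None:
        if self.Kb < 0:
            raise ValueError("Kb must be nonnegative")
        if self.fP <= 0:
            raise ValueError("fP must be positive")
        if self.epsL_ex < 0 or self.epsL_em < 0:
            raise ValueError("molar absorptions must be nonnegative")
        if self.path_l <= 0:
            raise ValueError("path_l must be positive")

    @property
    def epsL_sum(self) -> float:
        return self.epsL_ex + self.epsL_em


def free_species(Kb: float, Lt, Pt: float):
    """Free and bound concentrations for 1:1 binding.

    Solves Lt = [L](1 + Kb[P]), Pt = [P](1 + Kb[L]) for the unique
    nonnegative root.  Both free concentrations are taken from their own
    cancellation-free quadratic root
    [X] = 2*Xt / (b_X + sqrt(b_X^2 + 4*Kb*Xt)), b_X = 1 + Kb*(Yt - Xt),
    so each stays accurate even when nearly fully bound; the complex is
    then [PL] = Kb[L][P].  Returns ([L], [P], [PL]).
    """
    if Kb < 0:
        raise ValueError("Kb must be nonnegative")
    Lt = np.asarray(Lt, dtype=float)
    if np.any(Lt < 0) or Pt < 0:
        raise ValueError("total concentrations must be nonnegative")
    if Kb == 0:
        L = Lt.copy()
        return L, np.full_like(L, Pt), np.zeros_like(L)
    L = stable_positive_root(Kb, 1.0 + Kb * (Pt - Lt), Lt)
    P = stable_positive_root(Kb, 1.0 + Kb * (Lt - Pt), np.full_like(L, Pt))
    PL = Kb * L * P
    return L, P, PL


def predicted_fluorescence(params: QuenchParams, Lt, Pt: float) -> np.ndarray:
    """Inner-filter-corrected protein fluorescence at total ligand Lt.

    The attenuation exponential is driven by the *total* ligand
    concentration (bound ligand absorbs too).
    """
    Lt = np.asarray(Lt, dtype=float)
    _, P, _ = free_species(params.Kb, Lt, Pt)
    return params.fP * P * np.exp(-params.epsL_sum * params.path_l * Lt)


def fit_quench(
    titration: FluorescenceTitration,
    epsL_sum: float,
    *,
    path_l: float = 0.65,
    init: dict | None = None,
) -> FitResult:
    """Fit (Kb, fP) to a fluorescence titration.

    ``epsL_sum`` (the Beer-plot ligand absorption, excitation + emission)
    and the inner-filter path are fixed inputs, never fitted.
    """
    Lt = titration.ligand_total
    IF = titration.intensity
    Pt = titration.protein_total
    if Lt.size < 5:
        raise ValueError("need at least 5 titration points")
    if epsL_sum < 0:
        raise ValueError("epsL_sum must be nonnegative")
    if init is None:
        f0 = float(IF[np.argmin(Lt)]) / Pt
        # half-quench concentration as a crude Kb scale
        corrected = IF * np.exp(epsL_sum * path_l * Lt)
        half = corrected < 0.5 * corrected.max()
        Lhalf = float(Lt[half][0]) if half.any() else float(Lt.max())
        init = {"Kb": 1.0 / max(Lhalf, 1e-12), "fP": max(f0, 1e-12)}

    def model(p):
        params = QuenchParams(
            Kb=p["Kb"], fP=p["fP"], epsL_ex=epsL_sum, epsL_em=0.0, path_l=path_l
        )
        return [predicted_fluorescence(params, Lt, Pt)]

    return least_squares_fit(model, [IF], init, log_params=("Kb", "fP"))


def deconvolve_chalcone_kb(
    Kb_apparent: float, Kb_colored: float, chalcone_fraction: float
) -> float:
    """Chalcone-only binding constant from an apparent mixed-species fit.

    The apparent constant of an equilibrated chalcone/colored-forms
    mixture is the mole-fraction-weighted mean
    Kb_apparent = f*Kb_chalcone + (1-f)*Kb_colored; solve for
    Kb_chalcone.
    """
    if not (0.0 < chalcone_fraction <= 1.0):
        raise ValueError("chalcone_fraction must lie in (0, 1]")
    f = chalcone_fraction
    return (Kb_apparent - (1.0 - f) * Kb_colored) / f
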
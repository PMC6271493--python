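"""Equilibrium speciation and slow hydration kinetics of flavylium pigments.

A 3-deoxyanthocyanidin in aqueous solution interconverts between the red
flavylium cation AH+, the neutral quinonoid base A (pKa1), the anionic
quinonoid base A- (pKa2) and the colorless (E)-chalcone CE.  The hemiketal
and (Z)-chalcone are transient, non-accumulating intermediates in this
family and are lumped into a single apparent hydration equilibrium
AH+ <=> CE + H+ with constant K'h (pKh_app).  The chalcone-to-base ratio
Ki = (CE)/(A) = 10**(pKa1 - pKh_app) is pH-independent.

Color loss by water addition (flavylium -> chalcone) is slow and first
order with apparent rate constant ``kh_obs``; the corresponding
absorbance decay/rise model and its fitter (optionally sharing kh_obs
across two wavelengths) live here as well, together with the two-state
absorbance-vs-pH sigmoid used to extract pKa2 and the anionic/neutral
absorption ratio rA from equilibrium titrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fitting import FitResult, least_squares_fit

__all__ = [
    "EquilibriumConstants",
    "HydrationKinetics",
    "mole_fractions",
    "chalcone_base_ratio",
    "titration_curve",
    "fit_pka2",
    "first_order_decay",
    "half_life",
    "fit_first_order",
]

SPECIES = ("AH+", "A", "A-", "CE")


@dataclass(frozen=True)
class EquilibriumConstants:
    """Thermodynamic constants of the multistate flavylium network.

    ``Ki`` and ``rA`` are optional; when ``Ki`` is supplied it must agree
    with 10**(pKa1 - pKh_app) within 5% (they parameterize the same
    equilibrium two ways).
    """

    pKa1: float
    pKa2: float
    pKh_app: float
    Ki: float | None = None
    rA: float | None = None

    def __post_init__(self) -> None:
        for name in ("pKa1", "pKa2", "pKh_app"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.Ki is not None:
            if self.Ki <= 0:
                raise ValueError("Ki must be positive")
            implied = 10.0 ** (self.pKa1 - self.pKh_app)
            if abs(self.Ki - implied) > 0.05 * implied:
                raise ValueError(
                    f"Ki={self.Ki:g} inconsistent with 10^(pKa1-pKh_app)={implied:g}"
                )
        if self.rA is not None and self.rA <= 0:
            raise ValueError("rA must be positive")

    @property
    def ki_implied(self) -> float:
        """Chalcone-to-base ratio implied by pKa1 and pKh_app."""
        return 10.0 ** (self.pKa1 - self.pKh_app)


@dataclass(frozen=True)
class HydrationKinetics:
    """Apparent first-order rate constant of color loss by water addition."""

    kh_obs: float

    def __post_init__(self) -> None:
        if not (self.kh_obs >= 0):
            raise ValueError("kh_obs must be nonnegative")

    @property
    def half_life_s(self) -> float:
        return half_life(self.kh_obs)


def mole_fractions(constants: EquilibriumConstants, pH: float) -> dict[str, float]:
    """Equilibrium mole fractions of AH+, A, A- and CE at a given pH.

    All species concentrations are expressed relative to the flavylium:
    [A]/[AH+] = Ka1/[H+], [A-]/[AH+] = Ka1*Ka2/[H+]^2,
    [CE]/[AH+] = K'h/[H+]; the four ratios are then normalized.
    """
    if not (0.0 <= pH <= 14.0):
        raise ValueError(f"pH must lie in [0, 14], got {pH}")
    # work with ratios of exponents to stay finite at extreme pH
    exps = np.array([
        0.0,                                    # AH+
        pH - constants.pKa1,                    # A
        2 * pH - constants.pKa1 - constants.pKa2,  # A-
        pH - constants.pKh_app,                 # CE
    ])
    rel = 10.0 ** (exps - exps.max())
    frac = rel / rel.sum()
    return dict(zip(SPECIES, frac.tolist()))


def chalcone_base_ratio(pKa1: float, pKh_app: float) -> float:
    """Ki = (CE)/(A) = 10**(pKa1 - pKh_app)."""
    if not (math.isfinite(pKa1) and math.isfinite(pKh_app)):
        raise ValueError("pKa1 and pKh_app must be finite")
    return 10.0 ** (pKa1 - pKh_app)


def titration_curve(
    pKa2: float, rA: float, A_neutral: float, pH_grid
) -> np.ndarray:
    """Two-state absorbance sigmoid across the A <=> A- transition.

    A(pH) = A_neutral * (1 + rA*10^(pH-pKa2)) / (1 + 10^(pH-pKa2)),
    interpolating between A_neutral (neutral base) and rA*A_neutral
    (anionic base).
    """
    pH_grid = np.atleast_1d(np.asarray(pH_grid, dtype=float))
    if pH_grid.size == 0:
        raise ValueError("pH grid must be nonempty")
    if A_neutral <= 0:
        raise ValueError("A_neutral must be positive")
    if rA <= 0:
        raise ValueError("rA must be positive")
    x = 10.0 ** (pH_grid - pKa2)
    return A_neutral * (1.0 + rA * x) / (1.0 + x)


def fit_pka2(pH, absorbance, *, init: dict | None = None) -> FitResult:
    """Fit (pKa2, rA, A_neutral) to an equilibrium A-vs-pH titration.

    Requires at least 4 points spanning the transition.  A flat series
    (rA ~ 1) makes pKa2 unidentifiable; this is surfaced through the
    covariance condition number ("ill-conditioned" flag), not by
    returning an arbitrary value silently.
    """
    pH = np.asarray(pH, dtype=float)
    absorbance = np.asarray(absorbance, dtype=float)
    if pH.size < 4:
        raise ValueError("need at least 4 titration points")
    if init is None:
        a0 = float(absorbance[np.argmin(pH)])
        a1 = float(absorbance[np.argmax(pH)])
        a0 = max(a0, 1e-6)
        init = {
            "pKa2": float(np.median(pH)),
            "rA": max(a1 / a0, 1e-3),
            "A_neutral": a0,
        }

    def model(p):
        return [titration_curve(p["pKa2"], p["rA"], p["A_neutral"], pH)]

    return least_squares_fit(
        model, [absorbance], init, log_params=("rA", "A_neutral"),
    )


def first_order_decay(A0: float, A_inf: float, kh_obs: float, t) -> np.ndarray:
    """Exponential approach A(t) = A_inf + (A0 - A_inf)*exp(-kh_obs*t)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    if kh_obs < 0:
        raise ValueError("kh_obs must be nonnegative")
    return A_inf + (A0 - A_inf) * np.exp(-kh_obs * t)


def half_life(kh_obs: float) -> float:
    """First-order half-life ln(2)/kh_obs in seconds."""
    if kh_obs <= 0:
        raise ValueError("kh_obs must be positive for a finite half-life")
    return math.log(2.0) / kh_obs


def fit_first_order(times, curves, *, init: dict | None = None) -> FitResult:
    """Fit first-order color-loss kinetics, one or several wavelengths.

    Parameters
    ----------
    times : array, s
    curves : array or dict
        A single absorbance trace, or a dict ``label -> trace`` fitted
        simultaneously with a shared rate constant ``kh_obs`` and
        per-curve amplitudes (the classic decay-at-one-wavelength /
        rise-at-another double fit).

    Returns estimates ``kh_obs`` plus ``A0_<label>`` / ``Ainf_<label>``
    per curve (plain ``A0``/``Ainf`` for a single anonymous trace).
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("time must be nonnegative")
    if not isinstance(curves, dict):
        curves = {"": np.asarray(curves, dtype=float)}
    labels = list(curves)
    data = [np.asarray(curves[k], dtype=float) for k in labels]

    def key(prefix: str, label) -> str:
        return f"{prefix}_{label}" if label != "" else prefix

    if init is None:
        span = times[-1] - times[0]
        init = {"kh_obs": math.log(2.0) / (span / 2.0)}
        for lab, y in zip(labels, data):
            init[key("A0", lab)] = float(y[0])
            init[key("Ainf", lab)] = float(y[-1])

    def model(p):
        k = p["kh_obs"]
        return [
            p[key("Ainf", lab)]
            + (p[key("A0", lab)] - p[key("Ainf", lab)]) * np.exp(-k * times)
            for lab in labels
        ]

    return least_squares_fit(model, data, init, log_params=("kh_obs",))
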
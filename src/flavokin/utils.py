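"""Small laboratory and numerical helpers."""

from __future__ import annotations

import numpy as np

__all__ = ["molar_concentration", "stable_positive_root"]


def stable_positive_root(a: float, b, c):
    """Positive root of a*x^2 + b*x - c = 0 (a > 0, c >= 0), without
    catastrophic cancellation.

    For b >= 0 the Citardauq form 2c/(b + sqrt(b^2 + 4ac)) is stable;
    for b < 0 the standard form (-b + sqrt(b^2 + 4ac))/(2a) is, since
    -b and the discriminant add.  Vectorized over b and c.
    """
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    disc = np.sqrt(b * b + 4.0 * a * c)
    return np.where(b >= 0,
                    2.0 * c / (b + disc + (c == 0)),  # guard 0/0 at c = 0
                    (disc - b) / (2.0 * a))


def molar_concentration(mass_g: float, mw_g_per_mol: float, volume_L: float) -> float:
    """Molarity of a stock prepared from a weighed solid.

    E.g. 17.6 mg of a 17,600 g/mol protein in 20 mL gives 50 uM.
    """
    if mass_g < 0:
        raise ValueError("mass must be nonnegative")
    if mw_g_per_mol <= 0 or volume_L <= 0:
        raise ValueError("molecular weight and volume must be positive")
    return mass_g / mw_g_per_mol / volume_L
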
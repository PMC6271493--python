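"""In-memory containers for the assay data handled by the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpectralTraceSet", "BindingIsotherm", "FluorescenceTitration"]


@dataclass
class SpectralTraceSet:
    """Synchronized absorbance-vs-time traces at one or more wavelengths.

    Parameters
    ----------
    times : array, s
        Strictly increasing acquisition times, starting at 0.
    traces : dict
        Wavelength (nm) -> absorbance array (AU), each aligned to ``times``.
    path_cm : float
        Optical path length; 1 cm quartz cell by default.
    """

    times: np.ndarray
    traces: dict[float, np.ndarray]
    path_cm: float = 1.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("times must be a 1-D array with at least 2 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.path_cm <= 0:
            raise ValueError("path_cm must be positive")
        if not self.traces:
            raise ValueError("at least one wavelength trace required")
        clean: dict[float, np.ndarray] = {}
        for wl, a in self.traces.items():
            a = np.asarray(a, dtype=float)
            if a.shape != self.times.shape:
                raise ValueError(
                    f"trace at {wl} nm has {a.size} points, expected {self.times.size}"
                )
            clean[float(wl)] = a
        self.traces = clean

    @property
    def wavelengths(self) -> list[float]:
        return sorted(self.traces)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.times})
        for wl in self.wavelengths:
            df[f"A_{wl:g}"] = self.traces[wl]
        return df


@dataclass
class BindingIsotherm:
    """Equilibrium titration: total titrant concentration vs absorbance change.

    ``ligand_total`` is the fixed pigment concentration (M); ``metal_total``
    the varied total metal (M); ``delta_A`` the absorbance change (AU) at
    ``wavelength`` nm.
    """

    metal_total: np.ndarray
    delta_A: np.ndarray
    ligand_total: float
    wavelength: float = 650.0

    def __post_init__(self) -> None:
        self.metal_total = np.asarray(self.metal_total, dtype=float)
        self.delta_A = np.asarray(self.delta_A, dtype=float)
        if self.metal_total.shape != self.delta_A.shape:
            raise ValueError("metal_total and delta_A must have equal length")
        if np.any(self.metal_total < 0):
            raise ValueError("total metal concentrations must be nonnegative")
        if self.ligand_total <= 0:
            raise ValueError("ligand_total must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"metal_total_M": self.metal_total, "delta_A": self.delta_A}
        )


@dataclass
class FluorescenceTitration:
    """Protein fluorescence vs total ligand concentration.

    ``protein_total`` (M) is fixed; intensities are in arbitrary units.
    """

    ligand_total: np.ndarray
    intensity: np.ndarray
    protein_total: float

    def __post_init__(self) -> None:
        self.ligand_total = np.asarray(self.ligand_total, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ligand_total.shape != self.intensity.shape:
            raise ValueError("ligand_total and intensity must have equal length")
        if np.any(self.ligand_total < 0):
            raise ValueError("ligand concentrations must be nonnegative")
        if self.protein_total <= 0:
            raise ValueError("protein_total must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ligand_total_M": self.ligand_total, "fluorescence": self.intensity}
        )
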
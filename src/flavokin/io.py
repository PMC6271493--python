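"""CSV readers/writers for the assay dialects, scenario files, reports.

Formats (all with a mandatory header row; concentrations in molar):

* kinetic trace:   ``time_s, A_<wavelength-nm>`` (one column per wavelength)
* pH titration:    ``pH, absorbance``
* binding isotherm: ``metal_total_M, delta_A``
* quench titration: ``ligand_total_M, fluorescence``

Malformed input is rejected with the offending line named, never parsed
into an empty or partial dataset.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import BindingIsotherm, FluorescenceTitration, SpectralTraceSet
from .fitting import FitResult

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_titration_csv",
    "read_isotherm_csv",
    "read_quench_csv",
    "read_scenario",
    "write_scenario",
    "write_report",
    "fitresult_to_csv",
]


class ParseError(ValueError):
    """Malformed assay file."""


def _read_table(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    rows = [r for r in rows if r and any(c.strip() for c in r)]
    if not rows:
        raise ParseError(f"{path}: empty file")
    header = [c.strip() for c in rows[0]]
    for col in required:
        if col not in header:
            raise ParseError(f"{path}: missing required column {col!r}")
    data: dict[str, list[float]] = {c: [] for c in header}
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ParseError(
                f"{path}: line {lineno}: expected {len(header)} cells, got {len(row)}"
            )
        for col, cell in zip(header, row):
            try:
                data[col].append(float(cell))
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric value {cell!r} in column {col!r}"
                ) from None
    if not data[required[0]]:
        raise ParseError(f"{path}: no data rows")
    return pd.DataFrame(data)


def read_trace_csv(path, path_cm: float = 1.0) -> SpectralTraceSet:
    """Read a kinetic trace file (``time_s`` plus ``A_<nm>`` columns)."""
    df = _read_table(path, ["time_s"])
    wl_cols = [c for c in df.columns if c.startswith("A_")]
    if not wl_cols:
        raise ParseError(f"{path}: no wavelength columns (expected 'A_<nm>')")
    t = df["time_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise ParseError(f"{path}: time_s must be strictly increasing")
    traces = {float(c[2:]): df[c].to_numpy() for c in wl_cols}
    return SpectralTraceSet(times=t, traces=traces, path_cm=path_cm)


def write_trace_csv(traces: SpectralTraceSet, path) -> None:
    traces.to_frame().to_csv(path, index=False)


def read_titration_csv(path) -> pd.DataFrame:
    """Read a pH titration (``pH, absorbance``)."""
    return _read_table(path, ["pH", "absorbance"])


def read_isotherm_csv(path, ligand_total: float, wavelength: float = 650.0) -> BindingIsotherm:
    """Read an equilibrium isotherm (``metal_total_M, delta_A``)."""
    df = _read_table(path, ["metal_total_M", "delta_A"])
    return BindingIsotherm(
        metal_total=df["metal_total_M"].to_numpy(),
        delta_A=df["delta_A"].to_numpy(),
        ligand_total=ligand_total,
        wavelength=wavelength,
    )


def read_quench_csv(path, protein_total: float) -> FluorescenceTitration:
    """Read a fluorescence titration (``ligand_total_M, fluorescence``)."""
    df = _read_table(path, ["ligand_total_M", "fluorescence"])
    return FluorescenceTitration(
        ligand_total=df["ligand_total_M"].to_numpy(),
        intensity=df["fluorescence"].to_numpy(),
        protein_total=protein_total,
    )


def read_scenario(path) -> dict:
    """Read a scenario/config file (YAML)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "family" not in data:
        raise ParseError(f"{path}: scenario must be a mapping with a 'family' key")
    return data


def write_scenario(scenario: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario, fh, sort_keys=False)


def fitresult_to_csv(result: FitResult, path) -> None:
    """Flat parameter/estimate/std_error table."""
    pd.DataFrame({
        "parameter": list(result.estimates),
        "estimate": [result.estimates[k] for k in result.estimates],
        "std_error": [result.std_errors.get(k, float("nan")) for k in result.estimates],
    }).to_csv(path, index=False)


def write_report(result: FitResult, path, *, fixed: dict | None = None) -> None:
    """Human-readable fit report, echoing any fixed parameters so the
    output is self-describing."""
    lines = [result.summary()]
    if fixed:
        lines.append("fixed parameters:")
        lines.extend(f"  {k} = {v:g}" for k, v in fixed.items())
    Path(path).write_text("\n".join(lines) + "\n")
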
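"""Synthetic assay data with known ground truth.

Every model family in the package can be exercised without any
experimental download: forward-simulate from a parameter set (the
shipped scenario presets carry the published fitted values), add
instrument-like noise, and refit.  :func:`recovery_study` automates the
replicate-fit-summarize loop used throughout the test suite.

Noise defaults emulate a diode-array spectrophotometer (additive
Gaussian, 0.002 AU on kinetic traces, 0.005 AU on equilibrium series)
and a fluorimeter (1% multiplicative).  All randomness flows from the
``NoiseSpec`` seed; identical seeds give identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .datatypes import BindingIsotherm, FluorescenceTitration, SpectralTraceSet
from .fitting import FitResult
from .hsa_binding import QuenchParams, fit_quench, predicted_fluorescence
from .iron_binding import (
    AutoxParams,
    IsothermParams,
    TwoStepParams,
    fit_isotherm,
    fit_two_step,
    isotherm_deltaA,
    simulate_autox,
    simulate_two_step,
)
from .peroxidation import PeroxConditions, PeroxParams, fit_inhibited, simulate_cd
from .speciation import first_order_decay, fit_pka2, titration_curve

__all__ = [
    "NoiseSpec",
    "make_kinetic_traces",
    "make_isotherm",
    "make_titration",
    "make_quench_series",
    "recovery_study",
    "load_scenario",
    "list_scenarios",
]

_FAMILIES = ("two_step", "autox", "perox", "first_order")


@dataclass(frozen=True)
class NoiseSpec:
    """Instrument noise model: additive (AU) or multiplicative (fraction)."""

    kind: str = "additive"
    sigma: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("additive", "multiplicative"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")

    def apply(self, values: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.sigma == 0:
            return values.copy()
        if rng is None:
            rng = np.random.default_rng(self.seed)
        draw = rng.normal(0.0, self.sigma, size=values.shape)
        if self.kind == "additive":
            return values + draw
        return values * (1.0 + draw)


def _rng(noise: NoiseSpec) -> np.random.Generator:
    return np.random.default_rng(noise.seed)


def make_kinetic_traces(
    model_family: str,
    params,
    conditions: dict,
    time_grid,
    noise: NoiseSpec,
) -> SpectralTraceSet:
    """Forward-simulate one kinetic assay and add noise.

    ``model_family`` is one of ``two_step``, ``autox``, ``perox`` or
    ``first_order``; ``params`` the matching parameter object (or, for
    ``first_order``, a dict with ``kh_obs`` and per-wavelength
    ``(A0, A_inf)`` amplitudes); ``conditions`` supplies initial
    concentrations (``L0``/``M0``, or a :class:`PeroxConditions`).
    """
    if model_family not in _FAMILIES:
        raise ValueError(f"unknown model family {model_family!r}")
    time_grid = np.asarray(time_grid, dtype=float)
    rng = _rng(noise)

    if model_family == "two_step":
        clean, _ = simulate_two_step(params, conditions["L0"], conditions["M0"], time_grid)
    elif model_family == "autox":
        clean, _ = simulate_autox(params, conditions["L0"], conditions["M0"], time_grid)
    elif model_family == "perox":
        cond = conditions if isinstance(conditions, PeroxConditions) else PeroxConditions(**conditions)
        df = simulate_cd(params, cond, time_grid)
        clean = SpectralTraceSet(
            times=time_grid, traces={234.0: df["A_234"].to_numpy()}
        )
    else:  # first_order
        traces = {
            float(wl): first_order_decay(a0, ainf, params["kh_obs"], time_grid)
            for wl, (a0, ainf) in params["amplitudes"].items()
        }
        clean = SpectralTraceSet(times=time_grid, traces=traces)

    noisy = {wl: noise.apply(a, rng) for wl, a in clean.traces.items()}
    return SpectralTraceSet(times=clean.times, traces=noisy, path_cm=clean.path_cm)


def make_isotherm(
    params: IsothermParams, Lt: float, Mt_grid, noise: NoiseSpec
) -> BindingIsotherm:
    """Noisy equilibrium titration from the reversible 1:1 model."""
    Mt_grid = np.asarray(Mt_grid, dtype=float)
    clean = isotherm_deltaA(params, Lt, Mt_grid)
    return BindingIsotherm(
        metal_total=Mt_grid, delta_A=noise.apply(clean, _rng(noise)), ligand_total=Lt
    )


def make_titration(
    pKa2: float, rA: float, A_neutral: float, pH_grid, noise: NoiseSpec
) -> pd.DataFrame:
    """Noisy A-vs-pH series from the two-state sigmoid."""
    pH_grid = np.asarray(pH_grid, dtype=float)
    clean = titration_curve(pKa2, rA, A_neutral, pH_grid)
    return pd.DataFrame(
        {"pH": pH_grid, "absorbance": noise.apply(clean, _rng(noise))}
    )


def make_quench_series(
    params: QuenchParams, Lt_grid, Pt: float, noise: NoiseSpec
) -> FluorescenceTitration:
    """Noisy fluorescence titration from the inner-filter quenching model."""
    Lt_grid = np.asarray(Lt_grid, dtype=float)
    clean = predicted_fluorescence(params, Lt_grid, Pt)
    return FluorescenceTitration(
        ligand_total=Lt_grid,
        intensity=noise.apply(clean, _rng(noise)),
        protein_total=Pt,
    )


def _replicate_seeds(noise: NoiseSpec, n: int) -> list[int]:
    rng = np.random.default_rng(noise.seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _fit_one(family: str, truth, conditions, design, noise: NoiseSpec) -> tuple[dict, FitResult]:
    """Generate one noisy replicate, fit it, return (truth map, result)."""
    if family == "two_step":
        L0, M0 = conditions["L0"], conditions["M0"]
        grid = design["times"]
        traces = make_kinetic_traces("two_step", truth, conditions, grid, noise)
        res = fit_two_step(traces, L0, M0, eps_L=truth.eps_L)
        tmap = {"kb": truth.kb, "kr": truth.kr}
        for wl in truth.eps_1:
            tmap[f"eps1_{wl:g}"] = truth.eps_1[wl]
            tmap[f"eps2_{wl:g}"] = truth.eps_2[wl]
        return tmap, res
    if family == "isotherm":
        iso = make_isotherm(truth, conditions["Lt"], design["Mt_grid"], noise)
        return {"Kb": truth.Kb, "delta_eps": truth.delta_eps}, fit_isotherm(iso)
    if family == "pka2":
        df = make_titration(truth["pKa2"], truth["rA"], truth["A_neutral"],
                            design["pH_grid"], noise)
        res = fit_pka2(df["pH"], df["absorbance"])
        return dict(truth), res
    if family == "quench":
        tit = make_quench_series(truth, design["Lt_grid"], conditions["Pt"], noise)
        res = fit_quench(tit, truth.epsL_sum, path_l=truth.path_l)
        return {"Kb": truth.Kb, "fP": truth.fP}, res
    if family == "perox_inhibited":
        cond = conditions if isinstance(conditions, PeroxConditions) else PeroxConditions(**conditions)
        grid = design["times"]
        traces = make_kinetic_traces("perox", truth, cond, grid, noise)
        res = fit_inhibited(traces.times, traces.traces[234.0], cond,
                            ki1=truth.ki1, eps_CD=truth.eps_CD)
        return {"r2": truth.r2, "AE": truth.AE, "n": truth.n}, res
    raise ValueError(f"unknown recovery family {family!r}")


def recovery_study(
    family: str,
    true_params,
    conditions,
    design: dict,
    noise: NoiseSpec,
    n_replicates: int,
) -> pd.DataFrame:
    """Replicate parameter-recovery experiment.

    Generates ``n_replicates`` noisy datasets (independent sub-seeds
    derived deterministically from ``noise.seed``), fits each with the
    family's fitter, and returns one row per parameter with columns
    ``truth, mean, sd, bias, rmse, n_converged, n_replicates``.
    Non-converged replicates are counted and excluded from the summary,
    never silently dropped.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    seeds = _replicate_seeds(noise, n_replicates)
    rows: dict[str, list[float]] = {}
    truth_map: dict[str, float] = {}
    n_converged = 0
    for s in seeds:
        tmap, res = _fit_one(family, true_params, conditions, design,
                             replace(noise, seed=s))
        if not res.converged:
            continue
        n_converged += 1
        truth_map = tmap
        for k in tmap:
            rows.setdefault(k, []).append(res.estimates[k])
    if n_converged < 2:
        raise RuntimeError(
            f"only {n_converged}/{n_replicates} replicates converged"
        )
    records = []
    for k, vals in rows.items():
        v = np.asarray(vals)
        t = truth_map[k]
        records.append({
            "parameter": k,
            "truth": t,
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)),
            "bias": float(v.mean() - t),
            "rmse": float(np.sqrt(np.mean((v - t) ** 2))),
            "n_converged": n_converged,
            "n_replicates": n_replicates,
        })
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# scenario presets

def list_scenarios() -> list[str]:
    """Names of the shipped scenario presets."""
    pkg = resources.files("flavokin") / "scenarios"
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def load_scenario(name: str) -> dict:
    """Load a named scenario preset (plain dict mirroring the YAML)."""
    path = resources.files("flavokin") / "scenarios" / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(list_scenarios())}"
        ) from None
    return yaml.safe_load(text)


def scenario_params(scenario: dict):
    """Build the typed parameter object for a loaded scenario."""
    fam = scenario["family"]
    p = scenario.get("params", {})
    if fam == "two_step":
        return TwoStepParams(kb=p["kb"], kr=p["kr"], eps_L=p["eps_L"],
                             eps_1=p["eps_1"], eps_2=p["eps_2"])
    if fam == "autox":
        return AutoxParams(kautox=p["kautox"], kb=p["kb"], kh_obs=p.get("kh_obs", 0.0),
                           eps_L=p["eps_L"], eps_ML=p["eps_ML"],
                           eps_CE=p.get("eps_CE") or {})
    if fam == "isotherm":
        return IsothermParams(Kb=p["Kb"], delta_eps=p["delta_eps"])
    if fam == "perox":
        return PeroxParams(ki1=p["ki1"], r2=p["r2"], AE=p["AE"], n=p["n"],
                           eps_CD=p["eps_CD"])
    if fam in ("pka2", "speciation"):
        return dict(p)
    raise ValueError(f"no typed parameters for family {fam!r}")
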
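"""Kinetics and thermodynamics of iron binding to flavylium pigments.

Three complementary models, observed as absorbance at the wavelengths
where the free pigment (~470 nm), the iron chelate (620-650 nm) and the
chalcone (375 nm) absorb:

* **Two-step Fe(III) binding** — irreversible second-order 1:1 binding
  of the pooled colored forms L (rate constant ``kb``), followed by
  first-order rearrangement of the kinetic complex FeL1 into the
  thermodynamic complex FeL2 (``kr``).  Fitted simultaneously at two
  wavelengths.
* **Reversible 1:1 isotherm** — equilibrium absorbance change vs total
  metal, parameterized by the binding constant ``Kb`` and the molar
  absorption difference ``delta_eps`` between complex and free pigment.
* **Fe(II) autoxidation/binding** — apparent first-order autoxidation of
  Fe(II) to Fe(III) (``kautox``), second-order binding of the Fe(III)
  formed (``kb``), and competing water addition on the free pigment
  (``kh_obs``, chalcone formation; negligible for the glucoside in
  excess iron).  A steady-state variant for metal/pigment ratios <= 1
  assumes every Fe(III) produced binds immediately, eliminating ``kb``.

Conservation of total iron and total pigment is built into the state
reduction (bound/chalcone amounts are integrated, free species obtained
by difference), so the conservation laws hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .datatypes import BindingIsotherm, SpectralTraceSet
from .fitting import FitResult, least_squares_fit
from .utils import stable_positive_root

__all__ = [
    "TwoStepParams",
    "AutoxParams",
    "IsothermParams",
    "simulate_two_step",
    "fit_two_step",
    "isotherm_deltaA",
    "fit_isotherm",
    "simulate_autox",
    "fit_autox",
]

_IVP_OPTS = dict(method="LSODA", rtol=1e-10, atol=1e-16)


def _check_eps(name: str, eps: dict) -> dict[float, float]:
    out = {}
    for wl, v in eps.items():
        if v < 0:
            raise ValueError(f"{name}[{wl}] must be nonnegative")
        out[float(wl)] = float(v)
    return out


@dataclass
class TwoStepParams:
    """Rate constants and molar absorptions of the two-step binding model.

    ``eps_L``, ``eps_1``, ``eps_2`` map wavelength (nm) to the molar
    absorption coefficient (M^-1 cm^-1) of the free colored pigment, the
    kinetic complex and the thermodynamic complex.
    """

    kb: float            # M^-1 s^-1
    kr: float            # s^-1
    eps_L: dict[float, float] = field(default_factory=dict)
    eps_1: dict[float, float] = field(default_factory=dict)
    eps_2: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kb <= 0:
            raise ValueError("kb must be positive")
        if self.kr < 0:
            raise ValueError("kr must be nonnegative")
        self.eps_L = _check_eps("eps_L", self.eps_L)
        self.eps_1 = _check_eps("eps_1", self.eps_1)
        self.eps_2 = _check_eps("eps_2", self.eps_2)


@dataclass
class AutoxParams:
    """Parameters of the Fe(II) autoxidation -> binding -> hydration model."""

    kautox: float        # s^-1
    kb: float            # M^-1 s^-1
    kh_obs: float = 0.0  # s^-1; 0 when chalcone formation is negligible
    eps_L: dict[float, float] = field(default_factory=dict)
    eps_ML: dict[float, float] = field(default_factory=dict)
    eps_CE: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kautox < 0 or self.kb < 0 or self.kh_obs < 0:
            raise ValueError("rate constants must be nonnegative")
        self.eps_L = _check_eps("eps_L", self.eps_L)
        self.eps_ML = _check_eps("eps_ML", self.eps_ML)
        self.eps_CE = _check_eps("eps_CE", self.eps_CE)


@dataclass(frozen=True)
class IsothermParams:
    """Equilibrium 1:1 binding constant and absorption contrast."""

    Kb: float            # M^-1
    delta_eps: float     # M^-1 cm^-1

    def __post_init__(self) -> None:
        if self.Kb <= 0:
            raise ValueError("Kb must be positive")


def _validate_sim_inputs(L0: float, M0: float, times) -> np.ndarray:
    if L0 <= 0 or M0 <= 0:
        raise ValueError("initial concentrations must be positive")
    times = np.asarray(times, dtype=float)
    if times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if times[0] != 0.0:
        raise ValueError("times must start at 0")
    return times


def _integrate(rhs, y0, times):
    sol = solve_ivp(rhs, (times[0], times[-1]), y0, t_eval=times, **_IVP_OPTS)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y


def simulate_two_step(
    params: TwoStepParams,
    L0: float,
    M0: float,
    times,
    wavelengths=None,
    path_cm: float = 1.0,
) -> tuple[SpectralTraceSet, pd.DataFrame]:
    """Integrate the irreversible two-step binding system.

        dL/dt    = -kb * Fe * L
        dFeL1/dt =  kb * Fe * L - kr * FeL1
        dFeL2/dt =  kr * FeL1

    with Fe = M0 - FeL1 - FeL2 and L = L0 - FeL1 - FeL2 eliminated by
    conservation.  Returns the absorbance traces
    A(lam, t) = (eps_L*L + eps_1*FeL1 + eps_2*FeL2) * path and the
    concentration trajectories.
    """
    times = _validate_sim_inputs(L0, M0, times)
    if wavelengths is None:
        wavelengths = sorted(params.eps_1)

    def rhs(_t, y):
        fel1, fel2 = y
        L = L0 - fel1 - fel2
        Fe = M0 - fel1 - fel2
        flux = params.kb * Fe * L
        return [flux - params.kr * fel1, params.kr * fel1]

    fel1, fel2 = _integrate(rhs, [0.0, 0.0], times)
    L = L0 - fel1 - fel2
    Fe = M0 - fel1 - fel2
    traj = pd.DataFrame(
        {"time_s": times, "L": L, "Fe": Fe, "FeL1": fel1, "FeL2": fel2}
    )
    traces = {}
    for wl in wavelengths:
        wl = float(wl)
        traces[wl] = path_cm * (
            params.eps_L.get(wl, 0.0) * L
            + params.eps_1.get(wl, 0.0) * fel1
            + params.eps_2.get(wl, 0.0) * fel2
        )
    return SpectralTraceSet(times=times, traces=traces, path_cm=path_cm), traj


def fit_two_step(
    traces: SpectralTraceSet,
    L0: float,
    M0: float,
    *,
    eps_L: dict[float, float] | None = None,
    init: dict | None = None,
) -> FitResult:
    """Simultaneous multi-wavelength fit of (kb, kr, eps_1, eps_2).

    The free-pigment absorption ``eps_L`` at each wavelength is fixed
    (default: from the t=0 absorbance, A0/L0), so only the complex
    absorptions are adjustable — one (eps_1, eps_2) pair per wavelength,
    named ``eps1_<nm>`` / ``eps2_<nm>`` in the result.
    """
    wls = traces.wavelengths
    times = traces.times
    if times.size < 20:
        raise ValueError("need at least 20 time points for the kinetic fit")
    if eps_L is None:
        eps_L = {wl: float(traces.traces[wl][0]) / (L0 * traces.path_cm) for wl in wls}
    data = [traces.traces[wl] for wl in wls]

    if init is None:
        # binding is the fast phase: read its half-completion time from the
        # trace with the largest early change; the early plateau then pins
        # eps_1 and the final level eps_2
        path = traces.path_cm
        c_max = min(L0, M0)          # complex concentration at completion
        L_rem = L0 - c_max           # unbound pigment left at completion
        i10 = max(int(0.1 * times.size), 2)
        deltas = {wl: abs(traces.traces[wl][i10] - traces.traces[wl][0]) for wl in wls}
        wl_fast = max(deltas, key=deltas.get)
        a_fast = traces.traces[wl_fast]
        half = a_fast[0] + 0.5 * (a_fast[i10] - a_fast[0])
        crossed = np.nonzero(
            np.sign(a_fast[: i10 + 1] - half) != np.sign(a_fast[0] - half)
        )[0]
        t_half = times[crossed[0]] if crossed.size else times[i10] / 2.0
        t_half = max(t_half, times[1])
        init = {"kb": 1.0 / (c_max * t_half), "kr": 1.0 / times[-1]}
        for wl in wls:
            a = traces.traces[wl]
            e1 = (a[i10] - eps_L.get(wl, 0.0) * L_rem * path) / (path * c_max)
            e2 = (a[-1] - eps_L.get(wl, 0.0) * L_rem * path) / (path * c_max)
            init[f"eps1_{wl:g}"] = max(float(e1), 1.0)
            init[f"eps2_{wl:g}"] = max(float(e2), 1.0)

    def model(p):
        pars = TwoStepParams(
            kb=p["kb"], kr=p["kr"], eps_L=eps_L,
            eps_1={wl: p[f"eps1_{wl:g}"] for wl in wls},
            eps_2={wl: p[f"eps2_{wl:g}"] for wl in wls},
        )
        sim, _ = simulate_two_step(pars, L0, M0, times, wls, traces.path_cm)
        return [sim.traces[wl] for wl in wls]

    log = ["kb", "kr"] + [f"eps1_{wl:g}" for wl in wls] + [f"eps2_{wl:g}" for wl in wls]
    return least_squares_fit(model, data, init, log_params=log, diff_step=1e-4)


def isotherm_deltaA(params: IsothermParams, Lt: float, Mt) -> np.ndarray:
    """Equilibrium absorbance change for reversible 1:1 binding.

    The free metal concentration solves
    Mt = [Fe](1 + Kb*Lt/(1 + Kb*[Fe])), i.e. the quadratic
    Kb*[Fe]^2 + (1 + Kb*(Lt - Mt))*[Fe] - Mt = 0, taken in the
    cancellation-free branch for either sign of the linear coefficient.
    Then dA = delta_eps * (Mt - [Fe]).
    """
    if Lt < 0:
        raise ValueError("Lt must be nonnegative")
    Mt = np.asarray(Mt, dtype=float)
    if np.any(Mt < 0):
        raise ValueError("Mt must be nonnegative")
    Kb = params.Kb
    free = stable_positive_root(Kb, 1.0 + Kb * (Lt - Mt), Mt)
    return params.delta_eps * (Mt - free)


def fit_isotherm(isotherm: BindingIsotherm, *, init: dict | None = None) -> FitResult:
    """Fit (Kb, delta_eps) to an equilibrium titration.

    Data far from saturation leave Kb and delta_eps strongly
    anti-correlated; the condition-number flag marks that case.
    """
    Mt = isotherm.metal_total
    dA = isotherm.delta_A
    if Mt.size < 4:
        raise ValueError("need at least 4 titration points")
    Lt = isotherm.ligand_total
    if init is None:
        pos = Mt[Mt > 0]
        init = {
            "Kb": 1.0 / float(np.median(pos)) if pos.size else 1e4,
            "delta_eps": float(np.max(dA)) / min(Lt, float(np.max(Mt))),
        }

    def model(p):
        return [isotherm_deltaA(IsothermParams(p["Kb"], p["delta_eps"]), Lt, Mt)]

    return least_squares_fit(model, [dA], init, log_params=("Kb", "delta_eps"))


def simulate_autox(
    params: AutoxParams,
    L0: float,
    M0_FeII: float,
    times,
    wavelengths=None,
    path_cm: float = 1.0,
) -> tuple[SpectralTraceSet, pd.DataFrame]:
    """Integrate the Fe(II) autoxidation -> Fe(III) binding -> hydration system.

        dFeII/dt = -kautox * FeII
        dFeIII/dt = kautox * FeII - kb * FeIII * L
        dL/dt    = -kb * FeIII * L - kh_obs * L
        dLFe/dt  =  kb * FeIII * L
        dCE/dt   =  kh_obs * L

    States (FeII, LFe, CE) are integrated; FeIII and L follow from iron
    and pigment conservation.  Absorbance
    A(lam, t) = (eps_L*L + eps_ML*LFe + eps_CE*CE) * path.
    """
    times = _validate_sim_inputs(L0, M0_FeII, times)
    if wavelengths is None:
        wavelengths = sorted(params.eps_ML)

    def rhs(_t, y):
        feII, lfe, ce = y
        feIII = M0_FeII - feII - lfe
        L = L0 - lfe - ce
        bind = params.kb * feIII * L
        return [-params.kautox * feII, bind, params.kh_obs * L]

    feII, lfe, ce = _integrate(rhs, [M0_FeII, 0.0, 0.0], times)
    feIII = M0_FeII - feII - lfe
    L = L0 - lfe - ce
    traj = pd.DataFrame(
        {"time_s": times, "FeII": feII, "FeIII": feIII, "L": L, "LFe": lfe, "CE": ce}
    )
    traces = {}
    for wl in wavelengths:
        wl = float(wl)
        traces[wl] = path_cm * (
            params.eps_L.get(wl, 0.0) * L
            + params.eps_ML.get(wl, 0.0) * lfe
            + params.eps_CE.get(wl, 0.0) * ce
        )
    return SpectralTraceSet(times=times, traces=traces, path_cm=path_cm), traj


def _simulate_autox_steady_state(
    kautox: float, kh_obs: float, L0: float, M0: float, times: np.ndarray
):
    """Limit in which every Fe(III) formed binds instantly (Mt/Lt <= 1)."""

    def rhs(_t, y):
        feII, lfe, ce = y
        L = L0 - lfe - ce
        return [-kautox * feII, kautox * feII, kh_obs * L]

    feII, lfe, ce = _integrate(rhs, [M0, 0.0, 0.0], times)
    L = L0 - lfe - ce
    return L, lfe, ce


def fit_autox(
    traces: SpectralTraceSet,
    L0: float,
    M0: float,
    mode: str = "full",
    *,
    eps_L: dict[float, float] | None = None,
    eps_CE: dict[float, float] | None = None,
    eps_ML: dict[float, float] | None = None,
    fit_kh_obs: bool = False,
    init: dict | None = None,
) -> FitResult:
    """Fit the Fe(II) autoxidation/binding model to multi-wavelength traces.

    Parameters
    ----------
    mode : {"full", "steady_state_FeIII"}
        ``full`` fits (kautox, kb, eps_ML per wavelength[, kh_obs]);
        ``steady_state_FeIII`` assumes Fe(III) binds as fast as it is
        produced (appropriate for Mt/Lt <= 1), eliminates kb, holds
        ``eps_ML`` fixed (required argument there) and fits
        (kautox, kh_obs).
    eps_L, eps_CE : dict, optional
        Fixed molar absorptions of the free pigment and chalcone; eps_L
        defaults to A0/L0 per wavelength, eps_CE to 0.
    fit_kh_obs : bool
        In ``full`` mode, also fit the water-addition rate constant
        (three-wavelength variant with chalcone detection); otherwise
        kh_obs is fixed at 0.
    """
    if mode not in ("full", "steady_state_FeIII"):
        raise ValueError(f"unknown mode {mode!r}")
    wls = traces.wavelengths
    times = traces.times
    if eps_L is None:
        eps_L = {wl: float(traces.traces[wl][0]) / (L0 * traces.path_cm) for wl in wls}
    eps_CE = {float(k): float(v) for k, v in (eps_CE or {}).items()}
    data = [traces.traces[wl] for wl in wls]
    path = traces.path_cm

    flags_extra: list[str] = []
    if mode == "full" and M0 <= L0:
        flags_extra.append("weak-kb-identifiability")

    if mode == "steady_state_FeIII":
        if eps_ML is None:
            raise ValueError("steady_state_FeIII mode requires fixed eps_ML")
        eps_ML = {float(k): float(v) for k, v in eps_ML.items()}
        if init is None:
            init = {"kautox": 1.0 / times[-1], "kh_obs": 1.0 / times[-1]}

        def model(p):
            L, lfe, ce = _simulate_autox_steady_state(
                p["kautox"], p["kh_obs"], L0, M0, times
            )
            return [
                path * (eps_L.get(wl, 0.0) * L + eps_ML.get(wl, 0.0) * lfe
                        + eps_CE.get(wl, 0.0) * ce)
                for wl in wls
            ]

        result = least_squares_fit(
            model, data, init, log_params=("kautox", "kh_obs"), diff_step=1e-4
        )
    else:
        if init is None:
            # the complex band (largest net rise) times the Fe(III) supply:
            # with fast binding, bound pigment ~ M0*(1 - exp(-kautox*t))
            # capped at L0, so its half-rise time pins kautox; the lag
            # sharpness scale 10/(M0*t_half) starts kb in the right decade
            rises = {wl: traces.traces[wl][-1] - traces.traces[wl][0] for wl in wls}
            wl_ml = max(rises, key=rises.get)
            a_ml = traces.traces[wl_ml]
            half = a_ml[0] + 0.5 * (a_ml[-1] - a_ml[0])
            above = np.nonzero(a_ml >= half)[0]
            t_half = times[above[0]] if above.size and above[0] > 0 else times[-1] / 2.0
            frac = min(L0 / (2.0 * M0), 0.95)
            init = {"kautox": -np.log1p(-frac) / t_half,
                    "kb": 10.0 / (M0 * t_half)}
            for wl in wls:
                a = traces.traces[wl]
                init[f"epsML_{wl:g}"] = max(
                    float(np.max(np.abs(a))) / (L0 * path), 1.0
                )
            if fit_kh_obs:
                init["kh_obs"] = 1.0 / times[-1]

        def model(p):
            pars = AutoxParams(
                kautox=p["kautox"], kb=p["kb"],
                kh_obs=p.get("kh_obs", 0.0),
                eps_L=eps_L,
                eps_ML={wl: p[f"epsML_{wl:g}"] for wl in wls},
                eps_CE=eps_CE,
            )
            sim, _ = simulate_autox(pars, L0, M0, times, wls, path)
            return [sim.traces[wl] for wl in wls]

        log = ["kautox", "kb"] + [f"epsML_{wl:g}" for wl in wls]
        if fit_kh_obs:
            log.append("kh_obs")
        result = least_squares_fit(model, data, init, log_params=log, diff_step=1e-4)

    result.flags.extend(flags_extra)
    return result
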
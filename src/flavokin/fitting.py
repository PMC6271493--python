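"""Shared nonlinear least-squares engine.

All model fits in this package funnel through :func:`least_squares_fit`:
a model maps a parameter dictionary to one or more predicted curves, the
engine stacks the residuals across curves (simultaneous multi-curve
fitting), minimises the unweighted sum of squares and reports linearized
(Gauss-Newton) standard errors plus the Pearson correlation between
pooled observed and predicted values — the diagnostics conventionally
printed alongside spectrophotometric curve fits.

Positivity constraints (rate constants, molar absorptions, binding
constants) are enforced by fitting those parameters in log space rather
than by hard bounds, which keeps the trust-region optimizer away from
boundary pathologies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize

__all__ = ["FitResult", "least_squares_fit", "multi_curve_residuals"]

#: covariance condition number above which estimates are flagged as
#: practically unidentifiable
CONDITION_THRESHOLD = 1e8


@dataclass
class FitResult:
    """Outcome of a nonlinear least-squares fit.

    Attributes
    ----------
    estimates : dict
        Point estimates of the free parameters, in their natural scale.
    std_errors : dict
        Linearized standard errors (residual variance times the diagonal
        of the inverse Gauss-Newton Hessian, square-rooted).  ``nan``
        when the Jacobian is singular or the fit is saturated.
    correlation_r : float
        Pearson correlation between pooled observed and predicted data.
    residual_norm : float
        Euclidean norm of the pooled residual vector.
    converged : bool
    n_obs, n_params : int
    covariance_condition : float
        Condition number of J'J at the optimum; large values signal
        unidentifiable parameter combinations.
    flags : list of str
        Human-readable warnings ("ill-conditioned", "at-bound", ...).
    """

    estimates: dict[str, float]
    std_errors: dict[str, float]
    correlation_r: float
    residual_norm: float
    converged: bool
    n_obs: int
    n_params: int
    covariance_condition: float
    message: str = ""
    flags: list[str] = field(default_factory=list)

    @property
    def identifiable(self) -> bool:
        return self.covariance_condition < CONDITION_THRESHOLD

    def summary(self) -> str:
        lines = ["parameter        estimate      std_error"]
        for k, v in self.estimates.items():
            se = self.std_errors.get(k, float("nan"))
            lines.append(f"{k:<15}{v:>12.6g}  {se:>12.3g}")
        lines.append(f"r = {self.correlation_r:.5f}   "
                     f"residual norm = {self.residual_norm:.4g}   "
                     f"converged = {self.converged}")
        if self.flags:
            lines.append("flags: " + ", ".join(self.flags))
        return "\n".join(lines)


def multi_curve_residuals(
    model: Callable[[Mapping[str, float]], Sequence[np.ndarray]],
    params: Mapping[str, float],
    datasets: Sequence[np.ndarray],
) -> np.ndarray:
    """Stack residuals (predicted - observed) across curves.

    Curves are concatenated in the order given; the residual vector
    length equals the total number of observations.  Each predicted
    curve must match its observed curve in length.
    """
    predicted = model(params)
    if len(predicted) != len(datasets):
        raise ValueError(
            f"model returned {len(predicted)} curves for {len(datasets)} datasets"
        )
    parts = []
    for i, (pred, obs) in enumerate(zip(predicted, datasets)):
        pred = np.asarray(pred, dtype=float)
        obs = np.asarray(obs, dtype=float)
        if pred.shape != obs.shape:
            raise ValueError(
                f"curve {i}: predicted length {pred.size} != observed {obs.size}"
            )
        parts.append(pred - obs)
    return np.concatenate(parts)


def _to_internal(values: np.ndarray, names: Sequence[str], log_set: set[str]) -> np.ndarray:
    out = values.copy()
    for i, n in enumerate(names):
        if n in log_set:
            if out[i] <= 0:
                raise ValueError(f"parameter {n!r} must be > 0 for log-space fitting")
            out[i] = np.log(out[i])
    return out


def _from_internal(x: np.ndarray, names: Sequence[str], log_set: set[str]) -> np.ndarray:
    out = x.copy()
    for i, n in enumerate(names):
        if n in log_set:
            out[i] = np.exp(out[i])
    return out


def least_squares_fit(
    model: Callable[[Mapping[str, float]], Sequence[np.ndarray]],
    datasets: Sequence[np.ndarray],
    init: Mapping[str, float],
    *,
    fixed: Mapping[str, float] | None = None,
    log_params: Iterable[str] = (),
    bounds: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    n_restarts: int = 3,
    xtol: float = 1e-12,
    ftol: float = 1e-12,
    gtol: float = 1e-12,
    diff_step: float | None = None,
    max_nfev: int | None = None,
) -> FitResult:
    """Fit free parameters of ``model`` to one or more observed curves.

    Parameters
    ----------
    model : callable
        Maps a full parameter dict (free + fixed) to a list of predicted
        curves, one per dataset.
    datasets : sequence of arrays
        Observed curves; all pooled with unit weight per point.
    init : mapping
        Starting values; its keys define the free parameters.
    fixed : mapping, optional
        Parameters held constant and passed through to the model.
    log_params : iterable of str
        Free parameters constrained positive via a log transform.
    bounds : mapping, optional
        ``name -> (lo, hi)`` box constraints in natural scale (applied
        on top of any log transform).
    seed, n_restarts :
        When the first solve fails to converge or parks a parameter at a
        bound, up to ``n_restarts`` jittered restarts are attempted and
        the lowest-objective solution is reported.
    diff_step : float, optional
        Relative finite-difference step for the numerical Jacobian.
        Models whose residuals embed an ODE solution carry integration
        error far above machine precision; a step large enough to
        dominate that error (~1e-4) keeps the gradient meaningful.
    """
    if len(datasets) == 0:
        raise ValueError("datasets must be nonempty")
    fixed = dict(fixed or {})
    names = list(init.keys())
    log_set = {n for n in log_params if n in names}
    x0_nat = np.array([float(init[n]) for n in names])

    obs = [np.asarray(d, dtype=float) for d in datasets]
    n_obs = int(sum(o.size for o in obs))
    n_par = len(names)
    if n_obs <= n_par:
        raise ValueError(f"need more observations ({n_obs}) than parameters ({n_par})")

    lo = np.full(n_par, -np.inf)
    hi = np.full(n_par, np.inf)
    if bounds:
        for i, n in enumerate(names):
            if n in bounds:
                blo, bhi = bounds[n]
                if n in log_set:
                    lo[i] = np.log(blo) if blo > 0 else -np.inf
                    hi[i] = np.log(bhi) if np.isfinite(bhi) else np.inf
                else:
                    lo[i], hi[i] = blo, bhi

    def residuals(x: np.ndarray) -> np.ndarray:
        nat = _from_internal(x, names, log_set)
        params = dict(zip(names, nat))
        params.update(fixed)
        return multi_curve_residuals(model, params, obs)

    def solve(x0_int: np.ndarray):
        return optimize.least_squares(
            residuals, x0_int, bounds=(lo, hi), method="trf",
            xtol=xtol, ftol=ftol, gtol=gtol, diff_step=diff_step,
            max_nfev=max_nfev,
        )

    x0_int = np.clip(_to_internal(x0_nat, names, log_set), lo, hi)
    res = solve(x0_int)

    def at_bound(r) -> bool:
        return bool(np.any(np.isclose(r.x, lo) | np.isclose(r.x, hi)))

    flags: list[str] = []
    if (not res.success) or at_bound(res):
        rng = np.random.default_rng(seed)
        best = res
        for _ in range(n_restarts):
            jitter = rng.normal(0.0, 0.3, size=n_par)
            x_try = np.clip(x0_int + jitter, lo, hi)
            try:
                r_try = solve(x_try)
            except Exception:
                continue
            if r_try.cost < best.cost:
                best = r_try
        res = best
        flags.append("restarted")
    if at_bound(res):
        flags.append("at-bound")

    x_nat = _from_internal(res.x, names, log_set)
    estimates = dict(zip(names, x_nat))

    # linearized covariance: s^2 (J'J)^-1, with the chain rule mapping
    # log-space variances back to the natural scale
    J = res.jac
    r = res.fun
    dof = n_obs - n_par
    JTJ = J.T @ J
    try:
        svals = np.linalg.svd(JTJ, compute_uv=False)
        cond = float(svals[0] / svals[-1]) if svals[-1] > 0 else np.inf
    except np.linalg.LinAlgError:
        cond = np.inf
    s2 = float(r @ r) / dof if dof > 0 else np.nan
    std_errors: dict[str, float] = {}
    try:
        cov = np.linalg.pinv(JTJ) * s2
        diag = np.sqrt(np.maximum(np.diag(cov), 0.0))
        for i, n in enumerate(names):
            se = diag[i]
            if n in log_set:
                se = se * x_nat[i]  # var(p) ~ p^2 var(log p)
            std_errors[n] = float(se)
    except np.linalg.LinAlgError:
        std_errors = {n: float("nan") for n in names}
        flags.append("singular-jacobian")
    if cond >= CONDITION_THRESHOLD:
        flags.append("ill-conditioned")

    pooled_obs = np.concatenate(obs)
    pooled_pred = pooled_obs + r  # residual = predicted - observed
    if pooled_obs.std() > 0 and pooled_pred.std() > 0:
        corr = float(np.corrcoef(pooled_obs, pooled_pred)[0, 1])
    else:
        corr = float("nan")

    return FitResult(
        estimates=estimates,
        std_errors=std_errors,
        correlation_r=corr,
        residual_norm=float(np.linalg.norm(r)),
        converged=bool(res.success),
        n_obs=n_obs,
        n_params=n_par,
        covariance_condition=cond,
        message=str(res.message),
        flags=flags,
    )
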
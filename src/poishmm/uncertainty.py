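"""Standard errors and confidence intervals for fitted Poisson HMMs.

Three routes are implemented:

* Wald-type intervals from the delta method: the covariance of the natural
  and derived parameters is Sigma = J H^{-1} J', with H the exact Hessian
  of the negative log-likelihood over the free working coordinates and J
  the exact Jacobian of the extended back-transform
  g_ext: working -> (Gamma, lambda, delta).
* Profile-likelihood intervals: the likelihood-ratio statistic
  R_p(v) = 2 (nll_profile(v) - nll_hat) is compared with the chi-square(1)
  quantile; the two roots are found by bracketing outward from the MLE and
  Brent root refinement, re-optimizing all nuisance parameters at every
  evaluation (warm-started from the nearest solved point).  Because
  likelihood-ratio intervals are invariant under monotone transforms, the
  natural-scale interval is the transform of the working-scale bounds.
  Profile intervals are undefined for the stationary distribution delta,
  which is not a coordinate of the likelihood.
* Parametric percentile bootstrap: simulate B series from the fitted model
  (stationary start), refit each, and take per-parameter percentiles.
  Refits start at the parameters that generated the sample: starting from
  data-driven values instead frequently strands short-series refits in
  label-degenerate local optima (both means high) and inflates the upper
  percentiles.  Replicates whose simulated state path does not visit every
  state, or whose refit fails, are replaced (with a budget) — degenerate
  paths make the model unidentifiable.  Label switching across refits is
  resolved by sorting states by ascending fitted mean before aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import linalg, optimize
from scipy.stats import chi2, norm

from .errors import ConvergenceError
from .fit import FIXED, ConstraintMap, FitOptions, FitResult, default_initial_params, fit_ml
from .model_core import NaturalParams, ObservationSeries
from .reparam import WorkingParams, working_to_natural
from .simulate import sample_is_valid, simulate_hmm

__all__ = [
    "SEReport",
    "CIReport",
    "ProfileTrace",
    "natural_param_names",
    "natural_param_vector",
    "align_states",
    "chi2_critical",
    "delta_method_cov",
    "wald_ci",
    "profile_ci",
    "profile_ci_tpm",
    "bootstrap_ci",
]


def natural_param_names(m: int) -> Tuple[str, ...]:
    """Report order: gamma row-major, then lambda, then delta (1-based)."""
    names = [f"gamma_{i + 1}{j + 1}" for i in range(m) for j in range(m)]
    names += [f"lambda_{i + 1}" for i in range(m)]
    names += [f"delta_{i + 1}" for i in range(m)]
    return tuple(names)


def natural_param_vector(params: NaturalParams) -> np.ndarray:
    """Flatten {Gamma, lambda, delta} in the report order."""
    return np.concatenate([params.tpm.ravel(), params.lam, params.delta])


def align_states(params: NaturalParams) -> NaturalParams:
    """Relabel states by ascending Poisson mean (ties: descending delta).

    Used to resolve label switching before aggregating across refits.
    """
    delta = params.delta
    order = np.lexsort((-delta, params.lam))
    if np.array_equal(order, np.arange(params.m)):
        return params
    init = params.init if isinstance(params.init, str) else np.asarray(params.init)[order]
    return NaturalParams(
        m=params.m,
        tpm=params.tpm[np.ix_(order, order)],
        lam=params.lam[order],
        init=init,
    )


def chi2_critical(level: float, df: int = 1) -> float:
    """Chi-square quantile used by the profile machinery (3.841 at 95%)."""
    return float(chi2.ppf(level, df))


@dataclass(frozen=True)
class SEReport:
    """Delta-method covariance over (Gamma, lambda, delta)."""

    names: Tuple[str, ...]
    estimates: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    reliable: bool = True

    def __getitem__(self, name: str) -> Tuple[float, float]:
        i = self.names.index(name)
        return float(self.estimates[i]), float(self.se[i])


@dataclass(frozen=True)
class ProfileTrace:
    """Evaluated points of one profile-likelihood search."""

    target: int
    grid: np.ndarray
    profile_nll: np.ndarray
    ratio: np.ndarray


@dataclass(frozen=True)
class CIReport:
    """Per-parameter confidence bounds for one method and level.

    NaN bounds mark parameters for which the method is unavailable (e.g.
    profile intervals for delta).
    """

    method: str
    level: float
    names: Tuple[str, ...]
    estimates: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    meta: Dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> Tuple[float, float]:
        i = self.names.index(name)
        return float(self.lower[i]), float(self.upper[i])

    def available(self, name: str) -> bool:
        i = self.names.index(name)
        return bool(np.isfinite(self.lower[i]) and np.isfinite(self.upper[i]))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "parameter": list(self.names),
                "estimate": self.estimates,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


def _extended_jacobian(fit: FitResult) -> np.ndarray:
    """Exact Jacobian of g_ext over free coordinates: (m^2 + 2m, n_free)."""
    from .reparam import transform_derivatives

    td = transform_derivatives(fit.working_hat, order=1)
    m = fit.m
    k = fit.layout.size
    p = m * m + 2 * m
    J = np.zeros((p, k))
    row = 0
    for i in range(m):
        for j in range(m):
            J[row] = td.dgamma[:, i, j]
            row += 1
    for i in range(m):
        J[row, fit.layout.eta_position(i)] = td.lam[i]  # d lambda / d eta
        row += 1
    for i in range(m):
        J[row] = td.ddelta[:, i]
        row += 1
    return J @ fit.selection


def delta_method_cov(fit: FitResult) -> SEReport:
    """Covariance of {Gamma, lambda, delta} by the delta method.

    Fixed working coordinates contribute zero columns, so fixed parameters
    get exact zero standard errors.  A singular Hessian yields a
    pseudo-inverse-based report flagged ``reliable=False``.
    """
    names = natural_param_names(fit.m)
    est = natural_param_vector(fit.natural_hat)
    J = _extended_jacobian(fit)
    nf = fit.n_free
    reliable = True
    if nf == 0:
        cov = np.zeros((len(names), len(names)))
    else:
        H = fit.hessian_working
        try:
            c, low = linalg.cho_factor(H)
            Hinv = linalg.cho_solve((c, low), np.eye(nf))
        except linalg.LinAlgError:
            Hinv = np.linalg.pinv(H)
            reliable = False
        cov = J @ Hinv @ J.T
        cov = 0.5 * (cov + cov.T)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return SEReport(names=names, estimates=est, se=se, cov=cov, reliable=reliable)


def wald_ci(se_report: SEReport, level: float = 0.95) -> CIReport:
    """Symmetric intervals estimate +/- z * SE on the natural scale.

    Bounds are stored unclipped; probabilities may stick out of [0, 1] and
    are clipped only for display.
    """
    # level -> 1 degenerates to z -> large but finite, so that the limiting
    # intervals still count as covering everything
    z = norm.ppf(0.5 + min(level, 1.0 - 1e-12) / 2.0)
    lower = se_report.estimates - z * se_report.se
    upper = se_report.estimates + z * se_report.se
    return CIReport(
        method="wald",
        level=level,
        names=se_report.names,
        estimates=se_report.estimates.copy(),
        lower=lower,
        upper=upper,
        meta={"reliable": se_report.reliable},
    )


# ---------------------------------------------------------------------------
# profile likelihood


class _ProfileObjective:
    """Profile nll of one working coordinate, with warm-started refits."""

    def __init__(self, fit: FitResult, pos: int, options: Optional[FitOptions] = None):
        cmap = fit.constraint_map
        lab = cmap.labels[pos]
        if lab == FIXED:
            raise ValueError("cannot profile a fixed coordinate")
        if sum(1 for x in cmap.labels if x == lab) > 1:
            raise ValueError("cannot profile a coordinate shared through an equality constraint")
        labels = list(cmap.labels)
        labels[pos] = FIXED
        self.cmap = ConstraintMap(tuple(labels))
        self.fit = fit
        self.pos = pos
        self.options = options or fit.options
        self.cache: Dict[float, Tuple[float, np.ndarray]] = {}
        theta_hat = fit.working_hat.to_vector()
        self.cache[theta_hat[pos]] = (fit.nll_value, theta_hat)

    def __call__(self, value: float) -> float:
        return self.solve(value)[0]

    def solve(self, value: float) -> Tuple[float, np.ndarray]:
        value = float(value)
        if value in self.cache:
            return self.cache[value]
        warm_key = min(self.cache, key=lambda v: abs(v - value))
        theta0 = self.cache[warm_key][1].copy()
        theta0[self.pos] = value
        init = working_to_natural(WorkingParams.from_vector(theta0, self.fit.layout))
        sub = fit_ml(
            self.fit.obs, self.fit.m, init=init,
            constraint_map=self.cmap, options=self.options,
        )
        out = (sub.nll_value, sub.working_hat.to_vector())
        self.cache[value] = out
        return out


def _working_se(fit: FitResult, pos: int) -> float:
    """Wald SE of one working coordinate, used to scale the bracket search."""
    free_cols = np.flatnonzero(fit.selection[pos])
    if free_cols.size != 1 or fit.n_free == 0:
        return 1.0
    try:
        Hinv = np.linalg.inv(fit.hessian_working)
        v = Hinv[free_cols[0], free_cols[0]]
        return float(np.sqrt(v)) if v > 0 else 1.0
    except np.linalg.LinAlgError:
        return 1.0


def _profile_bounds(fit, pos, level, options, max_se: float = 8.0):
    """Roots of R_p = chi2 quantile on both sides of the MLE.

    Returns (lo, hi, obj) where a side that could not be bracketed within
    ``max_se`` working-scale standard errors is None (an "open" bound).
    """
    obj = _ProfileObjective(fit, pos, options)
    crit = chi2_critical(level)
    mle = fit.working_hat.to_vector()[pos]
    se = _working_se(fit, pos)

    def ratio(v):
        return 2.0 * (obj(v) - fit.nll_value) - crit

    bounds = []
    for sign in (-1.0, 1.0):
        prev = mle
        found = None
        for u in (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 6.0, 8.0):
            v = mle + sign * u * se * np.sqrt(max(crit, 1.0))
            if ratio(v) > 0.0:
                found = (prev, v) if sign > 0 else (v, prev)
                break
            prev = v
        if found is None:
            bounds.append(None)
            continue
        root = optimize.brentq(ratio, found[0], found[1], xtol=1e-7 * max(se, 1e-3))
        bounds.append(float(root))
    return bounds[0], bounds[1], obj


def _natural_bound(fit: FitResult, obj: _ProfileObjective, pos: int, bound):
    """Map a working-scale profile bound to the natural scale.

    eta coordinates map through exp; tau coordinates map through the full
    row transform with the other row logits at their re-optimized values at
    the bound.  Initial-distribution logits have no single natural
    counterpart and map to NaN.
    """
    if bound is None:
        return np.nan
    m = fit.m
    if pos < m:
        return float(np.exp(bound))
    if pos < m + fit.layout.n_tau:
        _, theta = obj.solve(bound)
        nat = working_to_natural(WorkingParams.from_vector(theta, fit.layout))
        idx = pos - m
        i, off = divmod(idx, m - 1)
        j = off if off < i else off + 1
        return float(nat.tpm[i, j])
    return np.nan


def profile_ci(
    obs: Optional[ObservationSeries],
    fit: FitResult,
    target: int,
    level: float = 0.95,
    options: Optional[FitOptions] = None,
):
    """Profile-likelihood CI for one working coordinate.

    Returns ``(working_interval, natural_interval, trace)``; an interval
    side is NaN when no root was bracketed (parameter near a boundary).
    ``target`` is a full-layout position or a layout name such as "eta_2".
    """
    if isinstance(target, str):
        target = fit.layout.names.index(target)
    lo, hi, obj = _profile_bounds(fit, target, level, options)
    nat_lo = _natural_bound(fit, obj, target, lo)
    nat_hi = _natural_bound(fit, obj, target, hi)
    grid = np.array(sorted(obj.cache))
    pnll = np.array([obj.cache[v][0] for v in grid])
    trace = ProfileTrace(
        target=target,
        grid=grid,
        profile_nll=pnll,
        ratio=2.0 * (pnll - fit.nll_value),
    )
    working = (lo if lo is not None else np.nan, hi if hi is not None else np.nan)
    natural = tuple(sorted((nat_lo, nat_hi))) if np.isfinite([nat_lo, nat_hi]).all() else (nat_lo, nat_hi)
    return working, natural, trace


def profile_ci_tpm(
    obs: Optional[ObservationSeries],
    fit: FitResult,
    i: int,
    j: int,
    level: float = 0.95,
    options: Optional[FitOptions] = None,
):
    """Profile CI for gamma_ij (i != j, 0-based) via its working logit tau_ij.

    The bound for tau_ij is pushed through the row transform with the other
    logits of row i at their re-optimized values at that bound.  For models
    with more than two states this construction is biased by the dependence
    among row elements; the result carries ``use_with_care=True`` then.
    """
    pos = fit.layout.tau_position(i, j)
    working, natural, trace = profile_ci(obs, fit, pos, level, options)
    return {
        "working": working,
        "natural": natural,
        "trace": trace,
        "use_with_care": fit.m > 2,
    }


# ---------------------------------------------------------------------------
# parametric bootstrap


def bootstrap_ci(
    obs: ObservationSeries,
    fit: FitResult,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    budget_factor: int = 10,
    options: Optional[FitOptions] = None,
    refit_init: str = "fitted",
) -> CIReport:
    """Parametric percentile bootstrap CI for all natural parameters.

    B series of length T are simulated from the fitted model (stationary
    start) and refitted, starting at the generating parameters
    (``refit_init="fitted"``, default) or at the data-driven starting
    values (``refit_init="default"``).  Replicates
    with state paths that miss a state, or refits that do not converge, are
    replaced; exhausting ``budget_factor * B`` attempts raises an error
    carrying the attrition statistics.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    m = fit.m
    names = natural_param_names(m)
    est = natural_param_vector(fit.natural_hat)
    truth = NaturalParams(m=m, tpm=fit.natural_hat.tpm, lam=fit.natural_hat.lam, init="stationary")
    vals = np.empty((B, len(names)))
    attempts = 0
    replaced = {"state_visit": 0, "fit_failure": 0}
    b = 0
    while b < B:
        if attempts >= budget_factor * B:
            raise ConvergenceError(
                f"bootstrap replacement budget exhausted after {attempts} attempts "
                f"({replaced['state_visit']} state-visit, {replaced['fit_failure']} fit failures)"
            )
        sim, states = simulate_hmm(truth, obs.T, seed=[int(seed), attempts])
        attempts += 1
        if not sample_is_valid(states, m):
            replaced["state_visit"] += 1
            continue
        init = truth if refit_init == "fitted" else default_initial_params(sim, m)
        try:
            refit = fit_ml(sim, m, init=init, options=options)
        except Exception:
            replaced["fit_failure"] += 1
            continue
        if not refit.converged:
            replaced["fit_failure"] += 1
            continue
        vals[b] = natural_param_vector(align_states(refit.natural_hat))
        b += 1
    alpha = 1.0 - level
    lower = np.quantile(vals, alpha / 2.0, axis=0)
    upper = np.quantile(vals, 1.0 - alpha / 2.0, axis=0)
    return CIReport(
        method="bootstrap",
        level=level,
        names=names,
        estimates=est,
        lower=lower,
        upper=upper,
        meta={"B": B, "attempts": attempts, "replaced": replaced, "seed": int(seed)},
    )
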
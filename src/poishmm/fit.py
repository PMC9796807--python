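"""Maximum-likelihood estimation with exact derivatives.

The negative log-likelihood is minimized over the unconstrained working
parameters.  Exact gradients and Hessians come from the analytic
sensitivity recursions in ``_kernels`` (never finite differences), which
makes gradient-based quasi-Newton optimization fast and lets a final
Newton polish drive the gradient to machine-level accuracy.

Nested models are expressed through a :class:`ConstraintMap`: one label per
working-parameter position, where the label ``"FIXED"`` pins a position at
its initial value and identical non-FIXED labels force equality.  All
constraints act on the working scale; a natural-scale restriction (say
lambda_1 = 1) is imposed through its working-scale consequence
(eta_1 = log 1 = 0, i.e. fix eta_1 with an initial value of 1 for
lambda_1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from . import _kernels
from .errors import DegenerateChainError, EvaluationError, InvalidObservationError
from .model_core import NaturalParams, ObservationSeries, log_poisson_pmf_matrix
from .reparam import (
    ParamLayout,
    WorkingParams,
    natural_to_working,
    transform_derivatives,
    working_to_natural,
)

__all__ = [
    "ConstraintMap",
    "FitOptions",
    "FitResult",
    "default_initial_params",
    "nll_with_derivatives",
    "fit_ml",
    "information_criteria",
]

FIXED = "FIXED"

_BIG = 1e12  # objective value returned where the likelihood is not finite


@dataclass(frozen=True)
class ConstraintMap:
    """Working-scale parameter constraints for nested models.

    ``labels`` has one entry per working-parameter position (layout order:
    eta, tau, optional xi).  ``"FIXED"`` holds the position at its initial
    value; positions sharing any other label are constrained to be equal;
    distinct labels are free.
    """

    labels: Tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))

    @classmethod
    def all_free(cls, layout: ParamLayout) -> "ConstraintMap":
        return cls(tuple(layout.names))

    def validate(self, layout: ParamLayout) -> None:
        if len(self.labels) != layout.size:
            raise ValueError(
                f"constraint map has {len(self.labels)} labels, layout needs {layout.size}"
            )

    @property
    def n_free(self) -> int:
        seen = []
        for lab in self.labels:
            if lab != FIXED and lab not in seen:
                seen.append(lab)
        return len(seen)

    def reduction(self, theta0: np.ndarray):
        """Reduce to free coordinates: theta_full = S @ z + offset.

        Returns ``(S, offset, z0, free_labels)`` where z0 holds the initial
        value of each free coordinate (taken from the first position that
        carries its label).
        """
        k = len(self.labels)
        theta0 = np.asarray(theta0, dtype=float)
        if theta0.size != k:
            raise ValueError("theta0 length does not match constraint map")
        free_labels = []
        for lab in self.labels:
            if lab != FIXED and lab not in free_labels:
                free_labels.append(lab)
        S = np.zeros((k, len(free_labels)))
        offset = np.zeros(k)
        z0 = np.zeros(len(free_labels))
        first_seen = set()
        for pos, lab in enumerate(self.labels):
            if lab == FIXED:
                offset[pos] = theta0[pos]
            else:
                j = free_labels.index(lab)
                S[pos, j] = 1.0
                if lab not in first_seen:
                    z0[j] = theta0[pos]
                    first_seen.add(lab)
        return S, offset, z0, free_labels


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings.

    optimizer : "lbfgs" (quasi-Newton with exact gradient, default),
        "newton" (trust-region with exact gradient and Hessian), or
        "lbfgs-fd" (no supplied derivatives; for comparisons only).
    """

    optimizer: str = "lbfgs"
    maxiter: int = 1000
    ftol: float = 1e-12
    gtol: float = 1e-8
    polish: bool = True
    polish_gtol: float = 1e-9
    polish_maxiter: int = 25
    convergence_grad_tol: float = 1e-5


@dataclass(frozen=True)
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    working_hat: WorkingParams
    natural_hat: NaturalParams
    nll_value: float
    iterations: int
    converged: bool
    hessian_working: np.ndarray  # over free coordinates
    gradient_norm: float
    constraint_map: ConstraintMap
    layout: ParamLayout
    selection: np.ndarray  # S with theta_full = S z + offset
    offset: np.ndarray
    free_labels: Tuple[str, ...]
    m: int
    T: int
    obs: ObservationSeries = field(repr=False)
    options: FitOptions = field(default_factory=FitOptions, repr=False)

    @property
    def delta_hat(self) -> np.ndarray:
        return self.natural_hat.delta

    @property
    def n_free(self) -> int:
        return len(self.free_labels)

    @property
    def log_likelihood(self) -> float:
        return -self.nll_value


def default_initial_params(obs: ObservationSeries, m: int) -> NaturalParams:
    """Deterministic starting values for optimization.

    Poisson means start at quantiles of the positive observations at levels
    (i - 0.5)/m, pushed apart if ties occur; the transition matrix starts
    with 0.8 on the diagonal and the remaining mass spread uniformly.
    """
    data = obs.dropna()
    positive = data[data > 0]
    if positive.size == 0:
        positive = np.array([0.5])
    levels = (np.arange(m) + 0.5) / m
    lam0 = np.maximum(np.quantile(positive, levels), 0.05)
    # enforce strictly increasing starts so states are distinguishable
    for i in range(1, m):
        if lam0[i] <= lam0[i - 1]:
            lam0[i] = lam0[i - 1] * 1.2 + 0.05
    if m == 1:
        tpm0 = np.ones((1, 1))
    else:
        tpm0 = np.full((m, m), 0.2 / (m - 1))
        np.fill_diagonal(tpm0, 0.8)
    return NaturalParams(m=m, tpm=tpm0, lam=lam0, init="stationary")


def _prepare_data(obs: ObservationSeries):
    if obs.n_missing == obs.T:
        raise InvalidObservationError("series is entirely missing; nothing to fit")
    x = obs.values
    miss = obs.missing_mask
    return x, miss


def _full_eval(obs_x, obs_miss, obs_series, wp: WorkingParams, order: int):
    """nll (and derivatives over full working coordinates) at ``wp``.

    Overflow during optimizer exploration (huge eta) is tolerated: the
    kernels detect the resulting non-finite likelihood and the caller maps
    it to a large objective value.  A transition matrix pushed to a
    reducible limit (no unique stationary distribution) is treated the
    same way rather than aborting the line search.
    """
    with np.errstate(over="ignore", invalid="ignore"):
        try:
            return _full_eval_inner(obs_x, obs_miss, obs_series, wp, order)
        except (DegenerateChainError, np.linalg.LinAlgError):
            k = wp.layout.size
            if order == 0:
                return np.inf, None, None
            if order == 1:
                return np.inf, np.zeros(k), None
            return np.inf, np.zeros(k), np.zeros((k, k))


def _full_eval_inner(obs_x, obs_miss, obs_series, wp: WorkingParams, order: int):
    td = transform_derivatives(wp, order=max(order, 1))
    logp = log_poisson_pmf_matrix(obs_series, td.lam)
    if order == 0:
        val = _kernels.forward_nll(logp, td.gamma, td.delta)
        return val, None, None
    d1 = obs_x[:, None] - td.lam[None, :]
    d1 = np.where(obs_miss[:, None], 0.0, d1)
    if order == 1:
        val, g = _kernels.nll_grad(
            logp, d1, td.gamma, td.delta, td.dgamma, td.ddelta, td.eta_state
        )
        return val, g, None
    d2 = np.broadcast_to(-td.lam[None, :], logp.shape).copy()
    d2[obs_miss, :] = 0.0
    val, g, H = _kernels.nll_grad_hess(
        logp, d1, d2, td.gamma, td.delta, td.dgamma, td.d2gamma,
        td.ddelta, td.d2delta, td.eta_state,
    )
    return val, g, H


def nll_with_derivatives(
    obs: ObservationSeries,
    wp: WorkingParams,
    constraint_map: Optional[ConstraintMap] = None,
    order: int = 2,
):
    """Negative log-likelihood with exact gradient/Hessian over free coordinates.

    Returns ``(value, gradient, hessian)``; the derivative entries are
    ``None`` for lower orders.  Constraints are respected by construction:
    derivatives are computed in the reduced coordinate space
    theta_full = S z + offset via the chain rule (g_z = S' g, H_z = S' H S).
    """
    layout = wp.layout
    cmap = constraint_map or ConstraintMap.all_free(layout)
    cmap.validate(layout)
    theta = wp.to_vector()
    S, _, _, _ = cmap.reduction(theta)
    x, miss = _prepare_data(obs)
    val, g, H = _full_eval(x, miss, obs, wp, order)
    if not np.isfinite(val):
        raise EvaluationError("negative log-likelihood is not finite", working=theta)
    g_free = S.T @ g if g is not None else None
    H_free = S.T @ H @ S if H is not None else None
    return val, g_free, H_free


def _make_objective(obs, layout, S, offset, order):
    x, miss = _prepare_data(obs)

    def fun_grad(z):
        theta = S @ z + offset
        wp = WorkingParams.from_vector(theta, layout)
        val, g, _ = _full_eval(x, miss, obs, wp, 1)
        if not np.isfinite(val):
            return _BIG, np.zeros(S.shape[1])
        return val, S.T @ g

    def fun_only(z):
        theta = S @ z + offset
        wp = WorkingParams.from_vector(theta, layout)
        val, _, _ = _full_eval(x, miss, obs, wp, 0)
        return val if np.isfinite(val) else _BIG

    def hess(z):
        theta = S @ z + offset
        wp = WorkingParams.from_vector(theta, layout)
        _, _, H = _full_eval(x, miss, obs, wp, 2)
        return S.T @ H @ S

    def full(z):
        theta = S @ z + offset
        wp = WorkingParams.from_vector(theta, layout)
        val, g, H = _full_eval(x, miss, obs, wp, 2)
        return val, (S.T @ g if g is not None else None), (S.T @ H @ S if H is not None else None)

    return fun_grad, fun_only, hess, full


def _newton_polish(full, z, options: FitOptions):
    """Damped Newton refinement using the exact Hessian."""
    val, g, H = full(z)
    iters = 0
    while np.linalg.norm(g, np.inf) > options.polish_gtol and iters < options.polish_maxiter:
        mu = 0.0
        k = z.size
        step = None
        for _ in range(12):
            try:
                step = np.linalg.solve(H + mu * np.eye(k), -g)
            except np.linalg.LinAlgError:
                step = None
            if step is not None and g @ step < 0:
                break
            mu = max(10.0 * mu, 1e-8 * max(1.0, np.abs(np.diag(H)).max()))
        if step is None or not (g @ step < 0):
            break
        # backtracking line search
        alpha, accepted = 1.0, False
        for _ in range(30):
            z_new = z + alpha * step
            val_new, g_new, H_new = full(z_new)
            if np.isfinite(val_new) and val_new <= val + 1e-12 * abs(val):
                z, val, g, H = z_new, val_new, g_new, H_new
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break
        iters += 1
    return z, val, g, H, iters


def fit_ml(
    obs: ObservationSeries,
    m: int,
    init: Optional[NaturalParams] = None,
    constraint_map: Optional[ConstraintMap] = None,
    options: Optional[FitOptions] = None,
) -> FitResult:
    """Fit an m-state Poisson HMM by ML on the working scale.

    Deterministic given (obs, init, options).  Non-convergence is reported
    through ``FitResult.converged``, never silently.
    """
    options = options or FitOptions()
    if init is None:
        init = default_initial_params(obs, m)
    if init.m != m:
        raise ValueError("init has the wrong number of states")
    wp0 = natural_to_working(init)
    layout = wp0.layout
    cmap = constraint_map or ConstraintMap.all_free(layout)
    cmap.validate(layout)
    theta0 = wp0.to_vector()
    S, offset, z0, free_labels = cmap.reduction(theta0)
    fun_grad, fun_only, hess, full = _make_objective(obs, layout, S, offset, 1)

    iterations = 0
    if z0.size == 0:
        z = z0
        success = True
    elif options.optimizer == "lbfgs":
        res = optimize.minimize(
            fun_grad, z0, jac=True, method="L-BFGS-B",
            options=dict(maxiter=options.maxiter, ftol=options.ftol, gtol=options.gtol),
        )
        z, iterations, success = res.x, int(res.nit), bool(res.success)
    elif options.optimizer == "newton":
        res = optimize.minimize(
            fun_grad, z0, jac=True, hess=hess, method="trust-exact",
            options=dict(maxiter=options.maxiter, gtol=options.gtol),
        )
        z, iterations, success = res.x, int(res.nit), bool(res.success)
    elif options.optimizer == "lbfgs-fd":
        res = optimize.minimize(
            fun_only, z0, method="L-BFGS-B",
            options=dict(maxiter=options.maxiter, ftol=options.ftol, gtol=options.gtol),
        )
        z, iterations, success = res.x, int(res.nit), bool(res.success)
    else:
        raise ValueError(f"unknown optimizer {options.optimizer!r}")

    if options.polish and z.size:
        z, val, g, H, extra = _newton_polish(full, z, options)
        iterations += extra
    else:
        val, g, H = full(z)
        g = np.zeros(0) if g is None else g
        H = np.zeros((0, 0)) if H is None else H

    gradient_norm = float(np.linalg.norm(g, np.inf)) if z.size else 0.0
    converged = bool(np.isfinite(val)) and (
        z.size == 0 or gradient_norm < options.convergence_grad_tol
    )

    theta_hat = S @ z + offset
    working_hat = WorkingParams.from_vector(theta_hat, layout)
    natural_hat = working_to_natural(working_hat)
    return FitResult(
        working_hat=working_hat,
        natural_hat=natural_hat,
        nll_value=float(val),
        iterations=iterations,
        converged=converged,
        hessian_working=H,
        gradient_norm=gradient_norm,
        constraint_map=cmap,
        layout=layout,
        selection=S,
        offset=offset,
        free_labels=tuple(free_labels),
        m=m,
        T=obs.T,
        obs=obs,
        options=options,
    )


def information_criteria(fit: FitResult) -> Tuple[float, float]:
    """(AIC, BIC) with k = number of free working parameters."""
    k = fit.n_free
    aic = 2.0 * fit.nll_value + 2.0 * k
    bic = 2.0 * fit.nll_value + k * np.log(fit.T)
    return float(aic), float(bic)
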
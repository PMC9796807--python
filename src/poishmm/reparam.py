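"""Bijective transforms between natural and working parameters.

Unconstrained optimization of the HMM likelihood works on "working"
parameters: eta_i = log(lambda_i) for the Poisson means, and for each row
of the transition matrix a multinomial-logit parameterization with the
diagonal element as reference category,

    gamma_ij = exp(tau_ij) / (1 + sum_{k != i} exp(tau_ik)),  i != j,

with inverse tau_ij = log(gamma_ij / gamma_ii).  A model with a freely
estimated (non-stationary) initial distribution appends m - 1 extra logits
xi with state 1 as reference.

Layout of the flattened working vector (fixed package-wide):
eta first (length m), then tau row-major skipping the diagonal
(length m(m-1)), then the optional initial-distribution logits
(length m - 1).  Constraint maps, Hessians, and reports all refer to this
order.

This module also provides the exact first/second derivatives of the map
g: working -> (Gamma, lambda, delta) consumed by the likelihood-derivative
kernels and by the delta method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import BoundaryError
from .model_core import NaturalParams, stationary_distribution

__all__ = [
    "ParamLayout",
    "WorkingParams",
    "natural_to_working",
    "working_to_natural",
    "transform_derivatives",
    "TransformDerivatives",
]


@dataclass(frozen=True)
class ParamLayout:
    """Index bookkeeping for the flattened working-parameter vector."""

    m: int
    free_init: bool = False

    @property
    def n_eta(self) -> int:
        return self.m

    @property
    def n_tau(self) -> int:
        return self.m * (self.m - 1)

    @property
    def n_xi(self) -> int:
        return self.m - 1 if self.free_init else 0

    @property
    def size(self) -> int:
        return self.n_eta + self.n_tau + self.n_xi

    def eta_position(self, i: int) -> int:
        """Position of eta_i (0-based state index)."""
        return i

    def tau_position(self, i: int, j: int) -> int:
        """Position of tau_ij (0-based state indices, i != j)."""
        if i == j:
            raise ValueError("tau has no diagonal elements")
        offset = j if j < i else j - 1
        return self.m + i * (self.m - 1) + offset

    def xi_position(self, i: int) -> int:
        """Position of the initial-distribution logit for state i (i >= 1)."""
        if not self.free_init:
            raise ValueError("layout has no free initial distribution")
        if not 1 <= i < self.m:
            raise ValueError("xi exists for states 2..m only")
        return self.m + self.n_tau + (i - 1)

    @property
    def names(self) -> list:
        """Human-readable coordinate names, 1-based as printed in reports."""
        out = [f"eta_{i + 1}" for i in range(self.m)]
        for i in range(self.m):
            for j in range(self.m):
                if j != i:
                    out.append(f"tau_{i + 1}{j + 1}")
        if self.free_init:
            out += [f"xi_{i + 1}" for i in range(1, self.m)]
        return out


@dataclass(frozen=True)
class WorkingParams:
    """Unconstrained working parameters {eta, tau, optional xi}."""

    eta: np.ndarray
    tau: np.ndarray
    xi: Optional[np.ndarray] = None

    def __post_init__(self):
        eta = np.atleast_1d(np.asarray(self.eta, dtype=float))
        tau = np.asarray(self.tau, dtype=float).ravel()
        m = eta.size
        if tau.size != m * (m - 1):
            raise ValueError(f"tau must have length m(m-1) = {m * (m - 1)}")
        xi = self.xi
        if xi is not None:
            xi = np.atleast_1d(np.asarray(xi, dtype=float))
            if xi.size != m - 1:
                raise ValueError("xi must have length m - 1")
        vec = np.concatenate([eta, tau] + ([xi] if xi is not None else []))
        if not np.all(np.isfinite(vec)):
            raise ValueError("working parameters must be finite")
        object.__setattr__(self, "eta", eta)
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "xi", xi)

    @property
    def m(self) -> int:
        return self.eta.size

    @property
    def layout(self) -> ParamLayout:
        return ParamLayout(self.m, free_init=self.xi is not None)

    def to_vector(self) -> np.ndarray:
        parts = [self.eta, self.tau]
        if self.xi is not None:
            parts.append(self.xi)
        return np.concatenate(parts)

    @classmethod
    def from_vector(cls, vec: np.ndarray, layout: ParamLayout) -> "WorkingParams":
        vec = np.asarray(vec, dtype=float)
        if vec.size != layout.size:
            raise ValueError(f"expected vector of length {layout.size}")
        m = layout.m
        eta = vec[:m]
        tau = vec[m : m + layout.n_tau]
        xi = vec[m + layout.n_tau :] if layout.free_init else None
        return cls(eta=eta, tau=tau, xi=xi)


def _row_logits(m: int, tau: np.ndarray) -> np.ndarray:
    """(m, m) logit matrix with zero diagonal from the flattened tau."""
    Z = np.zeros((m, m))
    pos = 0
    for i in range(m):
        for j in range(m):
            if j != i:
                Z[i, j] = tau[pos]
                pos += 1
    return Z


def _softmax_rows(Z: np.ndarray) -> np.ndarray:
    Zs = Z - Z.max(axis=1, keepdims=True)
    E = np.exp(Zs)
    return E / E.sum(axis=1, keepdims=True)


def natural_to_working(params: NaturalParams) -> WorkingParams:
    """g^{-1}: tau_ij = log(gamma_ij / gamma_ii), eta_i = log(lambda_i)."""
    m = params.m
    diag = np.diag(params.tpm)
    if np.any(diag <= 0):
        raise BoundaryError("tau transform undefined: a diagonal entry of the TPM is zero")
    eta = np.log(params.lam)
    tau = np.empty(m * (m - 1))
    pos = 0
    with np.errstate(divide="ignore"):
        for i in range(m):
            for j in range(m):
                if j != i:
                    tau[pos] = np.log(params.tpm[i, j]) - np.log(diag[i])
                    pos += 1
    if not np.all(np.isfinite(tau)):
        raise BoundaryError("tau transform undefined: an off-diagonal TPM entry is zero")
    xi = None
    if not params.stationary_init:
        init = np.asarray(params.init, dtype=float)
        if init[0] <= 0:
            raise BoundaryError("initial-distribution logits undefined: delta_1 is zero")
        with np.errstate(divide="ignore"):
            xi = np.log(init[1:]) - np.log(init[0])
        if not np.all(np.isfinite(xi)):
            raise BoundaryError("initial-distribution logits undefined: a delta entry is zero")
    return WorkingParams(eta=eta, tau=tau, xi=xi)


def working_to_natural(wp: WorkingParams) -> NaturalParams:
    """g: back-transform working parameters to {Gamma, lambda, init}."""
    m = wp.m
    lam = np.exp(wp.eta)
    tpm = _softmax_rows(_row_logits(m, wp.tau))
    if wp.xi is None:
        init = "stationary"
    else:
        z = np.concatenate([[0.0], wp.xi])
        init = _softmax_rows(z[None, :])[0]
    return NaturalParams(m=m, tpm=tpm, lam=lam, init=init)


def _softmax_jacobian(p: np.ndarray, free_idx: np.ndarray) -> np.ndarray:
    """d p_j / d z_a for the free logit indices ``free_idx``: (n_free, n)."""
    J = np.empty((free_idx.size, p.size))
    for c, a in enumerate(free_idx):
        J[c] = -p[a] * p
        J[c, a] += p[a]
    return J


def _softmax_hessian(p: np.ndarray, free_idx: np.ndarray) -> np.ndarray:
    """d2 p_j / d z_a d z_b over free logits: (n_free, n_free, n)."""
    n = p.size
    H = np.empty((free_idx.size, free_idx.size, n))
    for c, a in enumerate(free_idx):
        for d, b in enumerate(free_idx):
            row = 2.0 * p[a] * p[b] * p
            row[a] -= p[a] * p[b]
            row[b] -= p[a] * p[b]
            if a == b:
                row -= p[a] * p
                row[a] += p[a]
            H[c, d] = row
    return H


@dataclass(frozen=True)
class TransformDerivatives:
    """Natural parameters and exact derivatives of g at a working point.

    Arrays are indexed by full working-coordinate positions (the
    ``ParamLayout`` order).  ``eta_state[q]`` is the 0-based state whose
    log-mean is coordinate q, or -1 for non-eta coordinates.
    """

    layout: ParamLayout
    lam: np.ndarray
    gamma: np.ndarray
    delta: np.ndarray
    dgamma: np.ndarray
    ddelta: np.ndarray
    eta_state: np.ndarray
    d2gamma: Optional[np.ndarray] = None
    d2delta: Optional[np.ndarray] = None


def transform_derivatives(wp: WorkingParams, order: int = 2) -> TransformDerivatives:
    """Evaluate g and its exact derivatives up to ``order`` (1 or 2)."""
    layout = wp.layout
    m, k = layout.m, layout.size
    nat = working_to_natural(wp)
    gamma = nat.tpm
    lam = nat.lam

    eta_state = np.full(k, -1, dtype=np.int64)
    eta_state[:m] = np.arange(m)

    dgamma = np.zeros((k, m, m))
    d2gamma = np.zeros((k, k, m, m)) if order >= 2 else None
    for i in range(m):
        free = np.array([j for j in range(m) if j != i], dtype=np.int64)
        if free.size == 0:
            continue
        pos = np.array([layout.tau_position(i, j) for j in free])
        J = _softmax_jacobian(gamma[i], free)
        for c, q in enumerate(pos):
            dgamma[q, i, :] = J[c]
        if order >= 2:
            H = _softmax_hessian(gamma[i], free)
            for c, q in enumerate(pos):
                for d, r in enumerate(pos):
                    d2gamma[q, r, i, :] = H[c, d]

    ddelta = np.zeros((k, m))
    d2delta = np.zeros((k, k, m)) if order >= 2 else None
    if wp.xi is None:
        delta = stationary_distribution(gamma)
        if m > 1:
            A = np.eye(m) - gamma + np.ones((m, m))
            Ainv = np.linalg.inv(A)
            for q in range(k):
                ddelta[q] = (delta @ dgamma[q]) @ Ainv
            if order >= 2:
                for q in range(k):
                    for r in range(q, k):
                        rhs = ddelta[q] @ dgamma[r] + ddelta[r] @ dgamma[q] + delta @ d2gamma[q, r]
                        d2delta[q, r] = rhs @ Ainv
                        d2delta[r, q] = d2delta[q, r]
    else:
        delta = np.asarray(nat.init, dtype=float)
        free = np.arange(1, m, dtype=np.int64)
        pos = np.array([layout.xi_position(i) for i in free])
        J = _softmax_jacobian(delta, free)
        for c, q in enumerate(pos):
            ddelta[q] = J[c]
        if order >= 2:
            H = _softmax_hessian(delta, free)
            for c, q in enumerate(pos):
                for d, r in enumerate(pos):
                    d2delta[q, r] = H[c, d]

    return TransformDerivatives(
        layout=layout,
        lam=lam,
        gamma=gamma,
        delta=delta,
        dgamma=dgamma,
        ddelta=ddelta,
        eta_state=eta_state,
        d2gamma=d2gamma,
        d2delta=d2delta,
    )
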
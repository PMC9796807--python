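"""Poisson hidden Markov model: data containers and the scaled likelihood.

An m-state Poisson HMM couples an unobserved homogeneous Markov chain
{C_t} with transition probability matrix Gamma to an observed count series
{X_t}, where conditionally on C_t = i the observation is Poisson with mean
lambda_i.  The likelihood is the matrix product

    L(theta) = delta P(x_1) Gamma P(x_2) ... Gamma P(x_T) 1',

with P(x) the diagonal matrix of the m Poisson pmf values at x and delta
the initial (by default stationary) state distribution.  This module holds
the parameter containers and evaluates the likelihood with a per-step
rescaled forward (and backward) recursion so that no intermediate quantity
underflows, even for very long series.

Missing observations are handled by setting P(x) to the identity matrix,
i.e. the corresponding factor drops out of the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np
from scipy.special import gammaln

from .errors import DegenerateChainError, InvalidObservationError
from . import _kernels

__all__ = [
    "ObservationSeries",
    "NaturalParams",
    "ForwardBackwardResult",
    "conditional_density_matrix",
    "log_poisson_pmf_matrix",
    "stationary_distribution",
    "negative_log_likelihood",
    "forward_backward",
]

#: Default textual markers interpreted as a missing observation.
DEFAULT_MISSING_SENTINELS = ("NA", "")


@dataclass(frozen=True)
class ObservationSeries:
    """A univariate series of non-negative integer counts with optional gaps.

    Internally the series is stored as a float array in which missing
    positions are NaN; the positions of missing values are therefore always
    recoverable.  All non-missing values must be non-negative integers.
    """

    values: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise InvalidObservationError("observation series must be a non-empty 1-d sequence")
        present = arr[~np.isnan(arr)]
        if present.size and (np.any(present < 0) or np.any(present != np.floor(present))):
            raise InvalidObservationError("observations must be non-negative integers")
        object.__setattr__(self, "values", arr)

    @classmethod
    def from_tokens(
        cls,
        tokens: Iterable[Union[int, float, str, None]],
        missing_sentinels: Sequence[str] = DEFAULT_MISSING_SENTINELS,
    ) -> "ObservationSeries":
        """Build a series from heterogeneous tokens, mapping sentinels to missing."""
        vals = []
        for tok in tokens:
            if tok is None:
                vals.append(np.nan)
            elif isinstance(tok, str):
                s = tok.strip()
                if s in missing_sentinels:
                    vals.append(np.nan)
                else:
                    try:
                        vals.append(float(s))
                    except ValueError as exc:
                        raise InvalidObservationError(f"cannot parse count token {tok!r}") from exc
            else:
                vals.append(float(tok))
        return cls(np.asarray(vals, dtype=float))

    @property
    def T(self) -> int:
        return self.values.size

    def __len__(self) -> int:
        return self.values.size

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def counts(self, fill: int = 0) -> np.ndarray:
        """Integer counts with missing positions replaced by ``fill``."""
        out = self.values.copy()
        out[np.isnan(out)] = fill
        return out.astype(np.int64)

    def dropna(self) -> np.ndarray:
        return self.values[~self.missing_mask]


def _as_prob_vector(v, m: int, what: str, tol: float = 1e-10) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (m,):
        raise ValueError(f"{what} must have length {m}")
    if np.any(v < -tol) or np.any(v > 1 + tol):
        raise ValueError(f"{what} entries must lie in [0, 1]")
    if abs(v.sum() - 1.0) > tol:
        raise ValueError(f"{what} must sum to 1 (got {v.sum()!r})")
    return v


@dataclass(frozen=True)
class NaturalParams:
    """Interpretable parameters of an m-state Poisson HMM.

    Parameters
    ----------
    m : int
        Number of hidden states (>= 1).
    tpm : (m, m) array
        Transition probability matrix Gamma; rows sum to one.
    lam : (m,) array
        Strictly positive conditional Poisson means.
    init : "stationary" or (m,) array
        Initial state distribution; the string ``"stationary"`` means it is
        derived from the transition matrix.
    """

    m: int
    tpm: np.ndarray
    lam: np.ndarray
    init: Union[str, np.ndarray] = "stationary"

    def __post_init__(self):
        m = int(self.m)
        if m < 1:
            raise ValueError("m must be >= 1")
        tpm = np.asarray(self.tpm, dtype=float)
        if tpm.shape != (m, m):
            raise ValueError(f"tpm must be {m}x{m}")
        if np.any(tpm < -1e-10) or np.any(tpm > 1 + 1e-10):
            raise ValueError("tpm entries must lie in [0, 1]")
        if np.max(np.abs(tpm.sum(axis=1) - 1.0)) > 1e-10:
            raise ValueError("tpm rows must sum to 1")
        lam = np.asarray(self.lam, dtype=float)
        if lam.shape != (m,):
            raise ValueError(f"lam must have length {m}")
        if np.any(lam <= 0):
            raise ValueError("all Poisson means must be strictly positive")
        init = self.init
        if isinstance(init, str):
            if init != "stationary":
                raise ValueError("init must be 'stationary' or an explicit probability vector")
        else:
            init = _as_prob_vector(init, m, "init")
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "tpm", tpm)
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "init", init)

    @property
    def stationary_init(self) -> bool:
        return isinstance(self.init, str)

    @property
    def delta(self) -> np.ndarray:
        """Initial state distribution (stationary distribution if derived)."""
        if self.stationary_init:
            return stationary_distribution(self.tpm)
        return np.asarray(self.init, dtype=float)


@dataclass(frozen=True)
class ForwardBackwardResult:
    """Scaled forward/backward quantities in log space.

    ``log_alpha[t, i]`` is log alpha_t(i) and ``log_beta[t, i]`` is
    log beta_t(i) of the unscaled recursions; combining them at any single
    time index t via logsumexp(log_alpha[t] + log_beta[t]) reproduces the
    log-likelihood.
    """

    log_alpha: np.ndarray
    log_beta: np.ndarray
    log_likelihood: float


def log_poisson_pmf_matrix(obs: ObservationSeries, lam: np.ndarray) -> np.ndarray:
    """(T, m) matrix of log p_i(x_t); rows of zeros at missing positions.

    The pmf is evaluated in log space via log-gamma so that large counts do
    not overflow a factorial.
    """
    lam = np.asarray(lam, dtype=float)
    x = obs.values[:, None]
    with np.errstate(invalid="ignore"):
        logp = x * np.log(lam)[None, :] - lam[None, :] - gammaln(x + 1.0)
    logp[obs.missing_mask, :] = 0.0  # missing rule: P(x) = I
    return logp


def conditional_density_matrix(x, lam) -> np.ndarray:
    """Diagonal matrix P(x) of the m Poisson pmf values at the count ``x``.

    A missing observation (``None`` or NaN) yields the identity matrix.
    """
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    if np.any(lam <= 0):
        raise ValueError("all Poisson means must be strictly positive")
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return np.eye(lam.size)
    xf = float(x)
    if xf < 0 or xf != np.floor(xf):
        raise InvalidObservationError(f"observation must be a non-negative integer, got {x!r}")
    logp = xf * np.log(lam) - lam - gammaln(xf + 1.0)
    return np.diag(np.exp(logp))


def stationary_distribution(tpm: np.ndarray) -> np.ndarray:
    """Stationary distribution delta with delta Gamma = delta, sum(delta) = 1.

    Solved through the augmented linear system delta (I - Gamma + U) = 1'
    (U the all-ones matrix), which is deterministic and differentiable,
    rather than by eigen-decomposition or power iteration.
    """
    tpm = np.asarray(tpm, dtype=float)
    m = tpm.shape[0]
    if m == 1:
        return np.ones(1)
    A = np.eye(m) - tpm + np.ones((m, m))
    try:
        delta = np.linalg.solve(A.T, np.ones(m))
    except np.linalg.LinAlgError as exc:
        raise DegenerateChainError("transition matrix has no unique stationary distribution") from exc
    if not np.all(np.isfinite(delta)) or np.any(delta < -1e-8):
        raise DegenerateChainError("transition matrix yields a degenerate stationary distribution")
    return delta


def negative_log_likelihood(obs: ObservationSeries, params: NaturalParams) -> float:
    """Negative log-likelihood -log L(theta) via the scaled forward recursion.

    The forward vector is renormalised at every step and each step's pmf row
    is shifted by its maximum before exponentiation, so no intermediate
    quantity underflows even for series of millions of observations.
    """
    logp = log_poisson_pmf_matrix(obs, params.lam)
    return float(_kernels.forward_nll(logp, params.tpm, params.delta))


def forward_backward(obs: ObservationSeries, params: NaturalParams) -> ForwardBackwardResult:
    """Scaled forward and backward recursions (log space).

    The forward- and backward-derived log-likelihoods agree to numerical
    precision; the stored log alpha/beta matrices feed state decoding.
    """
    logp = log_poisson_pmf_matrix(obs, params.lam)
    delta = params.delta
    log_alpha, ll_f = _kernels.forward_log_alpha(logp, params.tpm, delta)
    log_beta = _kernels.backward_log_beta(logp, params.tpm)
    # backward-derived log-likelihood: log(delta P(x1) beta_1)
    with np.errstate(divide="ignore"):
        ll_b = _logsumexp(np.log(delta) + logp[0] + log_beta[0])
    if not np.isclose(ll_f, ll_b, rtol=0, atol=1e-8 * max(1.0, abs(ll_f))):
        raise FloatingPointError("forward and backward log-likelihoods disagree")
    return ForwardBackwardResult(log_alpha=log_alpha, log_beta=log_beta, log_likelihood=float(ll_f))


def _logsumexp(v: np.ndarray) -> float:
    mx = np.max(v)
    if not np.isfinite(mx):
        return float(mx)
    return float(mx + np.log(np.sum(np.exp(v - mx))))
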
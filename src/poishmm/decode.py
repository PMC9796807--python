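"""Posterior state inference and forecasting for a fitted Poisson HMM.

Smoothing probabilities P(C_t = i | x_1..x_T) come from the scaled
forward/backward quantities; local decoding takes the per-time argmax;
the Viterbi dynamic program yields the jointly most probable state path;
and the h-step-ahead forecast pmf is phi_T Gamma^h P(x) 1' with phi_T the
normalised terminal forward vector (the state filter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import (
    ForwardBackwardResult,
    NaturalParams,
    ObservationSeries,
    forward_backward,
    log_poisson_pmf_matrix,
)

__all__ = [
    "DecodingResult",
    "smoothing_probabilities",
    "local_decode",
    "viterbi",
    "forecast",
    "filter_distribution",
    "decode",
]


@dataclass(frozen=True)
class DecodingResult:
    """State inference summary for one series under one parameter set.

    State indices are 0-based.  ``conditional_means`` holds
    lambda[local_path[t]], the data behind the usual regime-mean plot.
    """

    smoothing: np.ndarray  # (T, m)
    local_path: np.ndarray  # (T,)
    viterbi_path: np.ndarray  # (T,)
    conditional_means: np.ndarray  # (T,)
    log_likelihood: float


def smoothing_probabilities(obs: ObservationSeries, params: NaturalParams) -> np.ndarray:
    """(T, m) matrix of P(C_t = i | all observations); rows sum to one."""
    fb = forward_backward(obs, params)
    log_post = fb.log_alpha + fb.log_beta - fb.log_likelihood
    post = np.exp(log_post)
    return post / post.sum(axis=1, keepdims=True)


def local_decode(obs: ObservationSeries, params: NaturalParams) -> np.ndarray:
    """Per-time most probable state (ties broken toward the lower index)."""
    return np.argmax(smoothing_probabilities(obs, params), axis=1)


def viterbi(obs: ObservationSeries, params: NaturalParams) -> np.ndarray:
    """Jointly most probable state path (log-space dynamic program).

    Ties are broken deterministically toward the lower state index.
    """
    logp = log_poisson_pmf_matrix(obs, params.lam)
    with np.errstate(divide="ignore"):
        log_delta = np.log(params.delta)
        log_tpm = np.log(params.tpm)
    T, m = logp.shape
    score = log_delta + logp[0]
    back = np.zeros((T, m), dtype=np.int64)
    for t in range(1, T):
        cand = score[:, None] + log_tpm  # (from, to)
        # argmax returns the first (lowest) index on ties
        back[t] = np.argmax(cand, axis=0)
        score = cand[back[t], np.arange(m)] + logp[t]
    path = np.empty(T, dtype=np.int64)
    path[-1] = int(np.argmax(score))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def filter_distribution(obs: ObservationSeries, params: NaturalParams) -> np.ndarray:
    """phi_T = alpha_T / alpha_T 1', the state distribution given all data."""
    fb = forward_backward(obs, params)
    la = fb.log_alpha[-1]
    w = np.exp(la - la.max())
    return w / w.sum()


def forecast(obs: ObservationSeries, params: NaturalParams, h: int, x) -> np.ndarray:
    """h-step-ahead forecast pmf P(X_{T+h} = x | x_1..x_T).

    ``x`` may be a scalar count or an array of counts; Gamma^h is formed by
    repeated squaring.
    """
    if h < 1:
        raise ValueError("forecast horizon h must be >= 1")
    phi = filter_distribution(obs, params)
    state_probs = phi @ np.linalg.matrix_power(params.tpm, h)
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(xs < 0) or np.any(xs != np.floor(xs)):
        raise ValueError("forecast support values must be non-negative integers")
    grid = ObservationSeries(xs)
    pmf = np.exp(log_poisson_pmf_matrix(grid, params.lam))  # (n, m)
    out = pmf @ state_probs
    return out if np.ndim(x) else float(out[0])


def decode(obs: ObservationSeries, params: NaturalParams) -> DecodingResult:
    """Full decoding summary: smoothing, local path, Viterbi path, means."""
    fb = forward_backward(obs, params)
    log_post = fb.log_alpha + fb.log_beta - fb.log_likelihood
    post = np.exp(log_post)
    post /= post.sum(axis=1, keepdims=True)
    local = np.argmax(post, axis=1)
    vit = viterbi(obs, params)
    return DecodingResult(
        smoothing=post,
        local_path=local,
        viterbi_path=vit,
        conditional_means=params.lam[local],
        log_likelihood=fb.log_likelihood,
    )
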
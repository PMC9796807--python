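"""Seeded Poisson-HMM simulation and Monte-Carlo coverage studies.

``simulate_hmm`` draws a state path from the chain (initial state from the
stationary distribution unless an explicit one is given) and counts from
the state-conditional Poisson laws, fully reproducibly under a seed.

``coverage_study`` measures empirical coverage of the Wald, profile, and
bootstrap confidence intervals: simulate a series from a known truth, fit,
build the requested intervals, and record whether each interval contains
the true value.  Replicates are filtered for validity — a simulated state
path must sojourn in every state at least once, otherwise the model is not
identifiable from that sample — and invalid, non-converged, or
profile-failed replicates are replaced by freshly simulated ones (counted,
with a budget).  Each replicate draws from a child seed derived from
(master seed, attempt index), so replacement draws never collide with
retained ones.  Before checking coverage, fitted states are aligned to the
truth by ascending fitted mean (ties broken by descending stationary
probability).

The canonical truths are the two-, three-, and four-state parameter sets
of the accompanying coverage experiments, exposed via ``study_truth``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .errors import ConvergenceError
from .fit import FitOptions, default_initial_params, fit_ml
from .model_core import NaturalParams, ObservationSeries

__all__ = [
    "SimConfig",
    "CoverageStudyResult",
    "study_truth",
    "simulate_hmm",
    "sample_is_valid",
    "coverage_study",
]

_STUDY_TRUTHS = {
    2: (((0.95, 0.05), (0.15, 0.85)), (1.0, 7.0)),
    3: (
        ((0.95, 0.025, 0.025), (0.05, 0.90, 0.05), (0.075, 0.075, 0.85)),
        (1.0, 4.0, 7.0),
    ),
    4: (
        (
            (0.85, 0.05, 0.05, 0.05),
            (0.05, 0.85, 0.05, 0.05),
            (0.05, 0.10, 0.80, 0.05),
            (0.034, 0.033, 0.033, 0.90),
        ),
        (1.0, 5.0, 9.0, 13.0),
    ),
}


def study_truth(m: int) -> NaturalParams:
    """The m-state generating model of the coverage experiments (m in 2..4)."""
    if m not in _STUDY_TRUTHS:
        raise ValueError("study truths are defined for m in {2, 3, 4}")
    tpm, lam = _STUDY_TRUTHS[m]
    return NaturalParams(m=m, tpm=np.array(tpm), lam=np.array(lam), init="stationary")


def simulate_hmm(truth: NaturalParams, T: int, seed) -> Tuple[ObservationSeries, np.ndarray]:
    """Simulate (observations, 0-based state path) of length T.

    ``seed`` is anything ``numpy.random.default_rng`` accepts (an integer
    or a sequence of integers for derived streams).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    m = truth.m
    delta = truth.delta
    states = np.empty(T, dtype=np.int64)
    states[0] = rng.choice(m, p=delta)
    if m == 1:
        states[:] = 0
    else:
        # draw the whole path via inverse-cdf on per-row cumulative sums
        cum = np.cumsum(truth.tpm, axis=1)
        cum[:, -1] = 1.0
        u = rng.random(T)
        for t in range(1, T):
            states[t] = np.searchsorted(cum[states[t - 1]], u[t], side="right")
    counts = rng.poisson(truth.lam[states]).astype(float)
    return ObservationSeries(counts), states


def sample_is_valid(states: np.ndarray, m: int) -> bool:
    """True iff the state path visits every one of the m states."""
    return np.unique(np.asarray(states)).size == m


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one coverage study."""

    truth: NaturalParams
    T: int = 2000
    M: int = 1000
    level: float = 0.95
    methods: Tuple[str, ...] = ("wald",)
    seed: int = 0
    validity_filter: bool = True
    budget_factor: int = 10
    bootstrap_B: int = 200
    fit_options: Optional[FitOptions] = None

    def __post_init__(self):
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.budget_factor < 1:
            raise ValueError("replacement budget must be at least M")
        bad = set(self.methods) - {"wald", "profile", "bootstrap"}
        if bad:
            raise ValueError(f"unknown CI methods: {sorted(bad)}")


@dataclass(frozen=True)
class CoverageStudyResult:
    """Empirical coverage fractions plus replacement bookkeeping.

    ``coverage[method]`` is a vector over ``names`` with NaN where the
    method does not produce an interval for that parameter.
    """

    names: Tuple[str, ...]
    truth_values: np.ndarray
    level: float
    M: int
    coverage: Dict[str, np.ndarray]
    attempts: int
    replaced: Dict[str, int]
    partial: bool = False

    def to_frame(self):
        import pandas as pd

        data = {"parameter": list(self.names), "truth": self.truth_values}
        for method, cov in self.coverage.items():
            data[f"coverage_{method}"] = cov
        return pd.DataFrame(data)


def _permute_vector(vec: np.ndarray, perm: np.ndarray, m: int) -> np.ndarray:
    """Apply a state permutation to a flattened (Gamma, lambda, delta) vector."""
    G = vec[: m * m].reshape(m, m)[np.ix_(perm, perm)]
    lam = vec[m * m : m * m + m][perm]
    delta = vec[m * m + m :][perm]
    return np.concatenate([G.ravel(), lam, delta])


def _profile_interval_vector(fit, level, options, m: int):
    """Profile intervals for lambda and Gamma in report order (NaN elsewhere).

    Diagonal transition probabilities are covered only for m = 2, where the
    two-state row constraint gives gamma_ii = 1 - gamma_ij.  Returns None
    if any requested bound failed to bracket (the replicate is replaced).
    """
    from . import uncertainty as unc

    p = m * m + 2 * m
    lower = np.full(p, np.nan)
    upper = np.full(p, np.nan)
    for i in range(m):
        _, natural, _ = unc.profile_ci(None, fit, fit.layout.eta_position(i), level, options)
        if not np.all(np.isfinite(natural)):
            return None
        lower[m * m + i], upper[m * m + i] = natural
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            res = unc.profile_ci_tpm(None, fit, i, j, level, options)
            lo, hi = res["natural"]
            if not (np.isfinite(lo) and np.isfinite(hi)):
                return None
            lower[i * m + j], upper[i * m + j] = lo, hi
            if m == 2:
                lower[i * m + i], upper[i * m + i] = 1.0 - hi, 1.0 - lo
    return lower, upper


def coverage_study(config: SimConfig) -> CoverageStudyResult:
    """Run the Monte-Carlo coverage experiment described by ``config``."""
    from . import uncertainty as unc

    truth = unc.align_states(config.truth)
    m = truth.m
    names = unc.natural_param_names(m)
    truth_vec = unc.natural_param_vector(truth)
    p = len(names)

    hits = {meth: np.zeros(p) for meth in config.methods}
    evals = {meth: np.zeros(p) for meth in config.methods}
    replaced = {"state_visit": 0, "fit_failure": 0, "profile_failure": 0}
    attempts = 0
    retained = 0
    budget = config.budget_factor * config.M
    partial = False

    while retained < config.M:
        if attempts >= budget:
            partial = True
            break
        sim, states = simulate_hmm(truth, config.T, seed=[int(config.seed), attempts])
        attempts += 1
        if config.validity_filter and not sample_is_valid(states, m):
            replaced["state_visit"] += 1
            continue
        try:
            fit = fit_ml(sim, m, init=default_initial_params(sim, m), options=config.fit_options)
        except Exception:
            replaced["fit_failure"] += 1
            continue
        if not fit.converged:
            replaced["fit_failure"] += 1
            continue
        perm = np.lexsort((-fit.natural_hat.delta, fit.natural_hat.lam))

        intervals = {}
        failed = False
        for meth in config.methods:
            if meth == "wald":
                rep = unc.delta_method_cov(fit)
                ci = unc.wald_ci(rep, config.level)
                lower, upper = ci.lower, ci.upper
            elif meth == "bootstrap":
                try:
                    ci = unc.bootstrap_ci(
                        sim, fit, B=config.bootstrap_B, level=config.level,
                        seed=int(np.random.default_rng([int(config.seed), attempts, 1]).integers(2**31)),
                        options=config.fit_options,
                    )
                except ConvergenceError:
                    failed = True
                    break
                # bootstrap aggregation is already label-aligned (ascending
                # fitted mean), i.e. in the truth's canonical order
                intervals[meth] = (ci.lower.copy(), ci.upper.copy())
                continue
            elif meth == "profile":
                out = _profile_interval_vector(fit, config.level, config.fit_options, m)
                if out is None:
                    failed = True
                    break
                lower, upper = out
            intervals[meth] = (
                _permute_vector(lower, perm, m),
                _permute_vector(upper, perm, m),
            )
        if failed:
            replaced["profile_failure"] += 1
            continue

        for meth, (lower, upper) in intervals.items():
            ok = np.isfinite(lower) & np.isfinite(upper)
            evals[meth][ok] += 1
            hits[meth][ok & (lower <= truth_vec) & (truth_vec <= upper)] += 1
        retained += 1

    coverage = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for meth in config.methods:
            coverage[meth] = np.where(evals[meth] > 0, hits[meth] / evals[meth], np.nan)
    return CoverageStudyResult(
        names=names,
        truth_values=truth_vec,
        level=config.level,
        M=retained,
        coverage=coverage,
        attempts=attempts,
        replaced=replaced,
        partial=partial,
    )
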
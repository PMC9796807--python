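"""Independent reference implementations used as test oracles.

Everything here is deliberately naive: likelihoods by brute-force
enumeration of state paths, probabilities by direct factorial arithmetic,
derivatives by central finite differences.  None of it shares code with
the package internals.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def poisson_pmf(x, lam) -> float:
    """Direct factorial arithmetic, no library calls."""
    if math.isnan(x):
        return 1.0
    return math.exp(-lam) * lam ** x / math.factorial(int(x))


def path_sum_nll(values, tpm, lam, delta) -> float:
    """-log L by summing P(path) * P(obs | path) over all m^T paths."""
    values = np.asarray(values, dtype=float)
    m = len(lam)
    T = len(values)
    total = 0.0
    for path in itertools.product(range(m), repeat=T):
        p = delta[path[0]] * poisson_pmf(values[0], lam[path[0]])
        for t in range(1, T):
            p *= tpm[path[t - 1], path[t]] * poisson_pmf(values[t], lam[path[t]])
        total += p
    return -math.log(total)


def brute_posterior(values, tpm, lam, delta) -> np.ndarray:
    """P(C_t = i | all data) by path enumeration; rows t, columns i."""
    values = np.asarray(values, dtype=float)
    m = len(lam)
    T = len(values)
    post = np.zeros((T, m))
    total = 0.0
    for path in itertools.product(range(m), repeat=T):
        p = delta[path[0]] * poisson_pmf(values[0], lam[path[0]])
        for t in range(1, T):
            p *= tpm[path[t - 1], path[t]] * poisson_pmf(values[t], lam[path[t]])
        total += p
        for t in range(T):
            post[t, path[t]] += p
    return post / total


def brute_viterbi(values, tpm, lam, delta) -> np.ndarray:
    """Most probable path by enumeration; ties go to the lexicographically
    first path (which is what lowest-index tie-breaking produces)."""
    values = np.asarray(values, dtype=float)
    m = len(lam)
    T = len(values)
    best_p, best_path = -1.0, None
    for path in itertools.product(range(m), repeat=T):
        p = delta[path[0]] * poisson_pmf(values[0], lam[path[0]])
        for t in range(1, T):
            p *= tpm[path[t - 1], path[t]] * poisson_pmf(values[t], lam[path[t]])
        if p > best_p + 1e-300 and p > best_p * (1 + 1e-12):
            best_p, best_path = p, path
    return np.array(best_path)


def path_log_joint(values, path, tpm, lam, delta) -> float:
    """log P(path, data) for a given state path."""
    values = np.asarray(values, dtype=float)
    lp = math.log(delta[path[0]]) + math.log(poisson_pmf(values[0], lam[path[0]]))
    for t in range(1, len(values)):
        lp += math.log(tpm[path[t - 1], path[t]])
        lp += math.log(poisson_pmf(values[t], lam[path[t]]))
    return lp


def unscaled_forward(values, tpm, lam, delta) -> np.ndarray:
    """alpha_t = delta P(x1) Gamma P(x2) ... as raw (unscaled) vectors."""
    values = np.asarray(values, dtype=float)
    m = len(lam)
    P = lambda x: np.diag([poisson_pmf(x, l) for l in lam])
    alpha = np.asarray(delta, dtype=float) @ P(values[0])
    out = [alpha]
    for x in values[1:]:
        alpha = alpha @ np.asarray(tpm) @ P(x)
        out.append(alpha)
    return np.array(out)


def unscaled_backward(values, tpm, lam) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    m = len(lam)
    P = lambda x: np.diag([poisson_pmf(x, l) for l in lam])
    beta = np.ones(m)
    out = [beta]
    for x in values[:0:-1]:
        beta = np.asarray(tpm) @ P(x) @ beta
        out.append(beta)
    return np.array(out[::-1])


def eigen_stationary(tpm) -> np.ndarray:
    """Stationary distribution from the left unit eigenvector."""
    w, v = np.linalg.eig(np.asarray(tpm).T)
    k = np.argmin(np.abs(w - 1.0))
    vec = np.real(v[:, k])
    return vec / vec.sum()


def fd_gradient(f, x, h=1e-6) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    g = np.empty_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2 * h)
    return g


def fd_hessian(f, x, h=1e-4) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h * h)
    return H
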
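"""Compiled recursions: scaled forward/backward passes and their exact
first- and second-order sensitivities.

All kernels work on a (T, m) matrix ``logp`` of conditional log-pmf values
(rows of zeros at missing positions).  Each step shifts the pmf row by its
maximum and renormalises the forward vector, so the recursions are safe
against underflow; because a per-step rescaling by any constant leaves the
log-likelihood (and hence its derivatives) unchanged, the shift does not
enter the derivative bookkeeping.

The derivative kernels propagate d(phi)/d(theta) and d2(phi)/d(theta)2
alongside the normalised forward vector phi, where theta is the full
working-parameter vector.  They receive the derivatives of the transition
matrix and of the initial distribution with respect to theta, plus the map
``eta_state`` marking which coordinates are log-means (for which the log-pmf
has per-observation derivatives d logp/d eta = x - lambda and
d2 logp/d eta2 = -lambda).
"""

import numpy as np
from numba import njit

__all__ = [
    "forward_nll",
    "forward_log_alpha",
    "backward_log_beta",
    "nll_grad",
    "nll_grad_hess",
]


@njit(cache=True)
def forward_nll(logp, gamma, delta):
    T, m = logp.shape
    ll = 0.0
    phi = np.empty(m)
    v = np.empty(m)
    for t in range(T):
        s = logp[t, 0]
        for j in range(1, m):
            if logp[t, j] > s:
                s = logp[t, j]
        c = 0.0
        for j in range(m):
            if t == 0:
                a = delta[j]
            else:
                a = 0.0
                for i in range(m):
                    a += phi[i] * gamma[i, j]
            v[j] = a * np.exp(logp[t, j] - s)
            c += v[j]
        if c <= 0.0 or not np.isfinite(c):
            return np.inf
        ll += np.log(c) + s
        for j in range(m):
            phi[j] = v[j] / c
    return -ll


@njit(cache=True)
def forward_log_alpha(logp, gamma, delta):
    """Log of the unscaled forward vectors alpha_t, plus the log-likelihood."""
    T, m = logp.shape
    log_alpha = np.empty((T, m))
    phi = np.empty(m)
    v = np.empty(m)
    cum = 0.0
    for t in range(T):
        s = logp[t, 0]
        for j in range(1, m):
            if logp[t, j] > s:
                s = logp[t, j]
        c = 0.0
        for j in range(m):
            if t == 0:
                a = delta[j]
            else:
                a = 0.0
                for i in range(m):
                    a += phi[i] * gamma[i, j]
            v[j] = a * np.exp(logp[t, j] - s)
            c += v[j]
        cum += np.log(c) + s
        for j in range(m):
            phi[j] = v[j] / c
            log_alpha[t, j] = np.log(phi[j]) + cum
    return log_alpha, cum


@njit(cache=True)
def backward_log_beta(logp, gamma):
    """Log of the unscaled backward vectors beta_t (beta_T = 1)."""
    T, m = logp.shape
    log_beta = np.zeros((T, m))
    b = np.ones(m)
    w = np.empty(m)
    cum = 0.0
    for t in range(T - 2, -1, -1):
        s = logp[t + 1, 0]
        for j in range(1, m):
            if logp[t + 1, j] > s:
                s = logp[t + 1, j]
        c = 0.0
        for i in range(m):
            acc = 0.0
            for j in range(m):
                acc += gamma[i, j] * np.exp(logp[t + 1, j] - s) * b[j]
            w[i] = acc
            c += acc
        cum += np.log(c) + s
        for i in range(m):
            b[i] = w[i] / c
            log_beta[t, i] = np.log(b[i]) + cum
    return log_beta


@njit(cache=True)
def nll_grad(logp, d1, gamma, delta, dgamma, ddelta, eta_state):
    """Negative log-likelihood and its exact gradient.

    d1[t, j] holds d logp[t, j] / d eta_j (zero at missing positions);
    dgamma[q] and ddelta[q] are the derivatives of the transition matrix and
    the initial distribution with respect to working coordinate q.
    """
    T, m = logp.shape
    k = dgamma.shape[0]
    ll = 0.0
    g = np.zeros(k)
    phi = np.empty(m)
    dphi = np.zeros((k, m))
    v = np.empty(m)
    dv = np.empty((k, m))
    a = np.empty(m)
    da = np.empty((k, m))
    for t in range(T):
        s = logp[t, 0]
        for j in range(1, m):
            if logp[t, j] > s:
                s = logp[t, j]
        if t == 0:
            for j in range(m):
                a[j] = delta[j]
                for q in range(k):
                    da[q, j] = ddelta[q, j]
        else:
            for j in range(m):
                acc = 0.0
                for i in range(m):
                    acc += phi[i] * gamma[i, j]
                a[j] = acc
                for q in range(k):
                    acc = 0.0
                    for i in range(m):
                        acc += dphi[q, i] * gamma[i, j] + phi[i] * dgamma[q, i, j]
                    da[q, j] = acc
        c = 0.0
        for j in range(m):
            p = np.exp(logp[t, j] - s)
            v[j] = a[j] * p
            c += v[j]
            for q in range(k):
                e1 = d1[t, j] if eta_state[q] == j else 0.0
                dv[q, j] = p * (da[q, j] + a[j] * e1)
        if c <= 0.0 or not np.isfinite(c):
            return np.inf, g
        ll += np.log(c) + s
        for q in range(k):
            dc = 0.0
            for j in range(m):
                dc += dv[q, j]
            g[q] += dc / c
            for j in range(m):
                dphi[q, j] = dv[q, j] / c - (v[j] / c) * (dc / c)
        for j in range(m):
            phi[j] = v[j] / c
    return -ll, -g


@njit(cache=True)
def nll_grad_hess(logp, d1, d2, gamma, delta, dgamma, d2gamma, ddelta, d2delta, eta_state):
    """Negative log-likelihood with exact gradient and Hessian.

    d2[t, j] holds d2 logp[t, j] / d eta_j^2; d2gamma[q, r] and
    d2delta[q, r] are second derivatives of the transition matrix and the
    initial distribution with respect to working coordinates (q, r).
    """
    T, m = logp.shape
    k = dgamma.shape[0]
    ll = 0.0
    g = np.zeros(k)
    H = np.zeros((k, k))
    phi = np.empty(m)
    dphi = np.zeros((k, m))
    d2phi = np.zeros((k, k, m))
    v = np.empty(m)
    dv = np.empty((k, m))
    d2v = np.empty((k, k, m))
    a = np.empty(m)
    da = np.empty((k, m))
    d2a = np.empty((k, k, m))
    dc = np.empty(k)
    d2c = np.empty((k, k))
    for t in range(T):
        s = logp[t, 0]
        for j in range(1, m):
            if logp[t, j] > s:
                s = logp[t, j]
        if t == 0:
            for j in range(m):
                a[j] = delta[j]
                for q in range(k):
                    da[q, j] = ddelta[q, j]
                    for r in range(k):
                        d2a[q, r, j] = d2delta[q, r, j]
        else:
            for j in range(m):
                acc = 0.0
                for i in range(m):
                    acc += phi[i] * gamma[i, j]
                a[j] = acc
                for q in range(k):
                    acc = 0.0
                    for i in range(m):
                        acc += dphi[q, i] * gamma[i, j] + phi[i] * dgamma[q, i, j]
                    da[q, j] = acc
                for q in range(k):
                    for r in range(q, k):
                        acc = 0.0
                        for i in range(m):
                            acc += (
                                d2phi[q, r, i] * gamma[i, j]
                                + dphi[q, i] * dgamma[r, i, j]
                                + dphi[r, i] * dgamma[q, i, j]
                                + phi[i] * d2gamma[q, r, i, j]
                            )
                        d2a[q, r, j] = acc
                        d2a[r, q, j] = acc
        c = 0.0
        for j in range(m):
            p = np.exp(logp[t, j] - s)
            v[j] = a[j] * p
            c += v[j]
            for q in range(k):
                e1q = d1[t, j] if eta_state[q] == j else 0.0
                dv[q, j] = p * (da[q, j] + a[j] * e1q)
            for q in range(k):
                e1q = d1[t, j] if eta_state[q] == j else 0.0
                for r in range(q, k):
                    e1r = d1[t, j] if eta_state[r] == j else 0.0
                    e2 = d2[t, j] if (q == r and eta_state[q] == j) else 0.0
                    val = p * (
                        d2a[q, r, j]
                        + da[q, j] * e1r
                        + da[r, j] * e1q
                        + a[j] * (e1q * e1r + e2)
                    )
                    d2v[q, r, j] = val
                    d2v[r, q, j] = val
        if c <= 0.0 or not np.isfinite(c):
            return np.inf, g, H
        ll += np.log(c) + s
        for q in range(k):
            acc = 0.0
            for j in range(m):
                acc += dv[q, j]
            dc[q] = acc
        for q in range(k):
            for r in range(q, k):
                acc = 0.0
                for j in range(m):
                    acc += d2v[q, r, j]
                d2c[q, r] = acc
                d2c[r, q] = acc
        for q in range(k):
            g[q] += dc[q] / c
            for r in range(k):
                H[q, r] += d2c[q, r] / c - dc[q] * dc[r] / (c * c)
        for j in range(m):
            phi[j] = v[j] / c
        for q in range(k):
            for j in range(m):
                dphi[q, j] = dv[q, j] / c - phi[j] * dc[q] / c
        for q in range(k):
            for r in range(q, k):
                for j in range(m):
                    val = (
                        d2v[q, r, j] / c
                        - dphi[q, j] * dc[r] / c
                        - dphi[r, j] * dc[q] / c
                        - phi[j] * d2c[q, r] / c
                    )
                    d2phi[q, r, j] = val
                    d2phi[r, q, j] = val
    return -ll, -g, -H
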
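"""Compiled inner loops for the asynchronous random-sequential dynamics.

Each kernel consumes pre-drawn random numbers (agent indices and uniforms)
produced by a single numpy Generator on the Python side, so that a run is
bit-reproducible from its seed regardless of compilation details.  The
kernels mutate the expressed-opinion array in place, one elementary step at
a time: each step sees the outcome of all previous ones.
"""

from __future__ import annotations

import numba
import numpy as np

PARSE_SOCIAL = 0  # anchor = σb + (Σ A_ij ω_j)/(m+1)
PARSE_FULL = 1  # anchor = (σb + Σ A_ij ω_j)/(m+1)


@numba.njit(cache=True)
def exogenous_steps(indptr, indices, b, sigma, omega, has_expressed, agents, u_branch, u_coin):
    """Apply one conformity-model elementary step per entry of ``agents``."""
    for t in range(agents.shape[0]):
        i = agents[t]
        if u_branch[t] < sigma[i]:
            omega[i] = b[i]
            has_expressed[i] = True
        else:
            s = 0
            any_expressed = False
            for p in range(indptr[i], indptr[i + 1]):
                j = indices[p]
                s += omega[j]
                if has_expressed[j]:
                    any_expressed = True
            if s > 0:
                omega[i] = 1
                has_expressed[i] = True
            elif s < 0:
                omega[i] = -1
                has_expressed[i] = True
            elif any_expressed:
                omega[i] = 1 if u_coin[t] < 0.5 else -1
                has_expressed[i] = True
            else:
                omega[i] = 0


@numba.njit(cache=True)
def goal_anchor(indptr, indices, degree, b, sigma, omega, i, parse):
    """Anchor value v of the goal function G(ω) = −|v − ω| for agent i."""
    m = 0
    social = 0.0
    di = degree[i]
    for p in range(indptr[i], indptr[i + 1]):
        j = indices[p]
        oj = omega[j]
        if oj != 0:
            m += 1
        social += (degree[j] / di) * oj
    if parse == PARSE_SOCIAL:
        return sigma[i] * b[i] + social / (m + 1)
    return (sigma[i] * b[i] + social) / (m + 1)


@numba.njit(cache=True)
def nearest_candidate(v, u):
    """ω ∈ {−1,0,+1} minimizing |v − ω|; exact two-way ties broken by u."""
    d_minus = abs(v + 1.0)
    d_zero = abs(v)
    d_plus = abs(v - 1.0)
    dmin = min(d_minus, min(d_zero, d_plus))
    n_tied = 0
    if d_minus == dmin:
        n_tied += 1
    if d_zero == dmin:
        n_tied += 1
    if d_plus == dmin:
        n_tied += 1
    pick = int(u * n_tied)
    if pick >= n_tied:
        pick = n_tied - 1
    k = 0
    if d_minus == dmin:
        if k == pick:
            return -1
        k += 1
    if d_zero == dmin:
        if k == pick:
            return 0
        k += 1
    return 1


@numba.njit(cache=True)
def endogenous_steps(indptr, indices, degree, b, sigma, omega, is_hc, has_expressed, agents, u_coin, parse):
    """Apply one goal-function best-response step per entry of ``agents``.

    Hard-core agents bypass the maximization and always voice their belief.
    """
    for t in range(agents.shape[0]):
        i = agents[t]
        if is_hc[i]:
            omega[i] = -1
            has_expressed[i] = True
            continue
        v = goal_anchor(indptr, indices, degree, b, sigma, omega, i, parse)
        w = nearest_candidate(v, u_coin[t])
        omega[i] = w
        if w != 0:
            has_expressed[i] = True


@numba.njit(cache=True)
def local_climate(indptr, indices, omega):
    """r = mean over nodes of the neighborhood-average expressed opinion."""
    n = indptr.shape[0] - 1
    total = 0.0
    for i in range(n):
        lo, hi = indptr[i], indptr[i + 1]
        if hi == lo:
            continue
        s = 0
        for p in range(lo, hi):
            s += omega[indices[p]]
        total += s / (hi - lo)
    return total / n
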
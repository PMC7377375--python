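"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the algorithms used by the package: connectivity is
computed by boolean reachability-matrix closure plus exhaustive
mutual-reachability partitioning, and the signed-rank null distribution by
full enumeration of sign assignments.
"""

from __future__ import annotations

import itertools

import numpy as np
import scipy.stats as sps


def brute_force_measures(tokens, break_positions=()):
    """(edges, lcc, lsc) by transitive closure of the reachability matrix."""
    words = sorted(set(tokens))
    idx = {w: i for i, w in enumerate(words)}
    n = len(words)
    A = np.zeros((n, n), dtype=bool)
    breaks = set(break_positions)
    for i in range(len(tokens) - 1):
        if i not in breaks:
            A[idx[tokens[i]], idx[tokens[i + 1]]] = True
    edges = int(A.sum())

    # directed reachability closure (reflexive)
    R = np.eye(n, dtype=bool)
    for _ in range(n):
        R2 = R | (R @ A)
        if (R2 == R).all():
            break
        R = R2
    # weak: closure over symmetrized adjacency
    S = A | A.T
    W = np.eye(n, dtype=bool)
    for _ in range(n):
        W2 = W | (W @ S)
        if (W2 == W).all():
            break
        W = W2
    lcc = int(W.sum(axis=1).max())
    M = R & R.T  # mutual reachability -> strongly connected classes
    lsc = int(M.sum(axis=1).max())
    return edges, lcc, lsc


def enumerate_signed_rank_p(d):
    """Exact two-sided signed-rank p by enumerating all 2^n sign vectors."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws)
    eps = 1e-9
    p_le = np.mean(ws <= w_obs + eps)
    p_ge = np.mean(ws >= w_obs - eps)
    return min(1.0, 2 * min(p_le, p_ge))


def chi2_sf_by_integration(x, df):
    """Upper-tail chi-square probability by numeric integration of the density."""
    from math import gamma

    from scipy.integrate import quad

    def pdf(t):
        return t ** (df / 2 - 1) * np.exp(-t / 2) / (2 ** (df / 2) * gamma(df / 2))

    val, _ = quad(pdf, x, np.inf)
    return val
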
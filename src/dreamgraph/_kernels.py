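"""Numba kernels for sliding-window graph measures.

These kernels operate on integer-coded token arrays and compute, for every
window, the distinct-edge count, the largest weakly connected component
(union-find) and the largest strongly connected component (iterative Tarjan).
They exist purely for speed — shuffle nulls evaluate millions of windows —
and are verified against the networkx reference path in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_HASH_MULT = 2654435761  # Knuth multiplicative hashing


@njit(cache=True)
def window_measures_kernel(codes, noedge, w, step):  # pragma: no cover - jitted
    """Per-window (edges, lcc, lsc) for a coded token sequence.

    ``codes``: int64 token codes; ``noedge``: bool, ``noedge[i]`` suppresses the
    transition i -> i+1; ``w``: window length; ``step``: slide step.
    Returns an (n_windows, 3) int64 array.
    """
    n = codes.shape[0]
    k = (n - w) // step + 1
    out = np.empty((k, 3), np.int64)

    tsize = 1
    while tsize < 4 * w:
        tsize <<= 1
    mask = tsize - 1
    keys = np.full(tsize, -1, np.int64)
    vals = np.empty(tsize, np.int64)
    used = np.empty(w, np.int64)
    lid = np.empty(w, np.int64)
    seen = np.zeros((w, w), np.bool_)
    ea = np.empty(w, np.int64)
    eb = np.empty(w, np.int64)
    parent = np.empty(w, np.int64)
    csize = np.empty(w, np.int64)
    adj_start = np.empty(w + 1, np.int64)
    fillpos = np.empty(w, np.int64)
    adj = np.empty(w, np.int64)
    index = np.empty(w, np.int64)
    low = np.empty(w, np.int64)
    onstk = np.zeros(w, np.bool_)
    stk = np.empty(w, np.int64)
    callstk = np.empty(w, np.int64)
    eptr = np.empty(w, np.int64)

    for wi in range(k):
        s = wi * step

        # relabel window tokens to local ids 0..m-1 (open addressing)
        m = 0
        for t in range(w):
            c = codes[s + t]
            h = (c * _HASH_MULT) & mask
            while True:
                if keys[h] == -1:
                    keys[h] = c
                    vals[h] = m
                    used[m] = h
                    lid[t] = m
                    m += 1
                    break
                elif keys[h] == c:
                    lid[t] = vals[h]
                    break
                h = (h + 1) & mask

        # distinct directed edges
        ne = 0
        for t in range(w - 1):
            if not noedge[s + t]:
                a = lid[t]
                b = lid[t + 1]
                if not seen[a, b]:
                    seen[a, b] = True
                    ea[ne] = a
                    eb[ne] = b
                    ne += 1

        # largest weakly connected component via union-find
        for i in range(m):
            parent[i] = i
            csize[i] = 1
        for e in range(ne):
            ra = ea[e]
            while parent[ra] != ra:
                parent[ra] = parent[parent[ra]]
                ra = parent[ra]
            rb = eb[e]
            while parent[rb] != rb:
                parent[rb] = parent[parent[rb]]
                rb = parent[rb]
            if ra != rb:
                if csize[ra] < csize[rb]:
                    ra, rb = rb, ra
                parent[rb] = ra
                csize[ra] += csize[rb]
        lcc = 1
        for i in range(m):
            if parent[i] == i and csize[i] > lcc:
                lcc = csize[i]

        # CSR adjacency for Tarjan
        for i in range(m + 1):
            adj_start[i] = 0
        for e in range(ne):
            adj_start[ea[e] + 1] += 1
        for i in range(m):
            adj_start[i + 1] += adj_start[i]
            fillpos[i] = adj_start[i]
        for e in range(ne):
            adj[fillpos[ea[e]]] = eb[e]
            fillpos[ea[e]] += 1

        # largest strongly connected component via iterative Tarjan
        for i in range(m):
            index[i] = -1
        idx_counter = 0
        sp = 0
        lsc = 1
        for root in range(m):
            if index[root] != -1:
                continue
            index[root] = idx_counter
            low[root] = idx_counter
            idx_counter += 1
            stk[sp] = root
            sp += 1
            onstk[root] = True
            callstk[0] = root
            eptr[0] = adj_start[root]
            csp = 1
            while csp > 0:
                v = callstk[csp - 1]
                if eptr[csp - 1] < adj_start[v + 1]:
                    u = adj[eptr[csp - 1]]
                    eptr[csp - 1] += 1
                    if index[u] == -1:
                        index[u] = idx_counter
                        low[u] = idx_counter
                        idx_counter += 1
                        stk[sp] = u
                        sp += 1
                        onstk[u] = True
                        callstk[csp] = u
                        eptr[csp] = adj_start[u]
                        csp += 1
                    elif onstk[u]:
                        if index[u] < low[v]:
                            low[v] = index[u]
                else:
                    csp -= 1
                    if csp > 0:
                        p = callstk[csp - 1]
                        if low[v] < low[p]:
                            low[p] = low[v]
                    if low[v] == index[v]:
                        sz = 0
                        while True:
                            u2 = stk[sp - 1]
                            sp -= 1
                            onstk[u2] = False
                            sz += 1
                            if u2 == v:
                                break
                        if sz > lsc:
                            lsc = sz

        out[wi, 0] = ne
        out[wi, 1] = lcc
        out[wi, 2] = lsc

        # reset scratch
        for e in range(ne):
            seen[ea[e], eb[e]] = False
        for i in range(m):
            keys[used[i]] = -1

    return out


@njit(cache=True)
def shuffled_window_means_kernel(perms, noedge, w, step):  # pragma: no cover
    """Mean (edges, lcc, lsc) across windows for each permuted row of ``perms``."""
    n_shuffles = perms.shape[0]
    means = np.empty((n_shuffles, 3), np.float64)
    for s in range(n_shuffles):
        res = window_measures_kernel(perms[s], noedge, w, step)
        k = res.shape[0]
        for j in range(3):
            tot = 0.0
            for i in range(k):
                tot += res[i, j]
            means[s, j] = tot / k
    return means
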
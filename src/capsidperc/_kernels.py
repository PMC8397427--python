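"""Numba kernels for the Monte Carlo percolation core.

All kernels take the network as flat int32 edge-endpoint arrays and use
incremental union-find (path halving) per replicate, which dominates the
cost at 1e5+ replicates.  Randomness comes from numba's per-thread numpy
legacy RNG, seeded explicitly inside each kernel, so a (graph, count,
replicates, seed) quadruple maps to bit-identical output.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "pcon_vertex",
    "pcon_bond",
    "fragment_hist_vertex",
    "fragment_hist_bond",
]


@njit(cache=True, inline="always")
def _find(parent, x):
    while parent[x] != x:
        parent[x] = parent[parent[x]]
        x = parent[x]
    return x


@njit(cache=True)
def pcon_vertex(eu, ev, n_vertices, count, replicates, seed):
    """Number of replicates in which the survivors of removing exactly
    ``count`` vertices form a single connected component (states with at
    most one survivor count as connected)."""
    np.random.seed(seed)
    n_edges = eu.shape[0]
    parent = np.empty(n_vertices, np.int32)
    perm = np.empty(n_vertices, np.int32)
    removed = np.empty(n_vertices, np.uint8)
    hits = 0
    for _ in range(replicates):
        for i in range(n_vertices):
            perm[i] = i
            removed[i] = 0
            parent[i] = i
        for i in range(count):
            j = np.random.randint(i, n_vertices)
            t = perm[i]
            perm[i] = perm[j]
            perm[j] = t
            removed[perm[i]] = 1
        for e in range(n_edges):
            a = eu[e]
            b = ev[e]
            if removed[a] == 0 and removed[b] == 0:
                ra = _find(parent, a)
                rb = _find(parent, b)
                if ra != rb:
                    parent[ra] = rb
        comps = 0
        for i in range(n_vertices):
            if removed[i] == 0 and _find(parent, i) == i:
                comps += 1
        if comps <= 1:
            hits += 1
    return hits


@njit(cache=True)
def pcon_bond(eu, ev, n_vertices, count, replicates, seed):
    """Same as :func:`pcon_vertex` for removal of exactly ``count`` edges;
    every vertex is retained, so an isolated vertex means fragmentation."""
    np.random.seed(seed)
    n_edges = eu.shape[0]
    parent = np.empty(n_vertices, np.int32)
    eperm = np.empty(n_edges, np.int32)
    removed = np.empty(n_edges, np.uint8)
    hits = 0
    for _ in range(replicates):
        for i in range(n_vertices):
            parent[i] = i
        for e in range(n_edges):
            eperm[e] = e
            removed[e] = 0
        for i in range(count):
            j = np.random.randint(i, n_edges)
            t = eperm[i]
            eperm[i] = eperm[j]
            eperm[j] = t
            removed[eperm[i]] = 1
        for e in range(n_edges):
            if removed[e] == 0:
                ra = _find(parent, eu[e])
                rb = _find(parent, ev[e])
                if ra != rb:
                    parent[ra] = rb
        comps = 0
        for i in range(n_vertices):
            if _find(parent, i) == i:
                comps += 1
        if comps <= 1:
            hits += 1
    return hits


@njit(cache=True)
def fragment_hist_vertex(eu, ev, n_vertices, counts, seed):
    """Aggregate histogram of connected-fragment sizes over replicates.

    ``counts[r]`` is the number of vertices removed in replicate r (drawn
    by the caller, fixed or stochastic regime).  Removed vertices are
    excluded from the distribution.  Returns int64[n_vertices + 1], index
    = fragment size.
    """
    np.random.seed(seed)
    n_edges = eu.shape[0]
    parent = np.empty(n_vertices, np.int32)
    perm = np.empty(n_vertices, np.int32)
    removed = np.empty(n_vertices, np.uint8)
    size = np.empty(n_vertices, np.int64)
    hist = np.zeros(n_vertices + 1, np.int64)
    for r in range(counts.shape[0]):
        count = counts[r]
        for i in range(n_vertices):
            perm[i] = i
            removed[i] = 0
            parent[i] = i
            size[i] = 0
        for i in range(count):
            j = np.random.randint(i, n_vertices)
            t = perm[i]
            perm[i] = perm[j]
            perm[j] = t
            removed[perm[i]] = 1
        for e in range(n_edges):
            a = eu[e]
            b = ev[e]
            if removed[a] == 0 and removed[b] == 0:
                ra = _find(parent, a)
                rb = _find(parent, b)
                if ra != rb:
                    parent[ra] = rb
        for i in range(n_vertices):
            if removed[i] == 0:
                size[_find(parent, i)] += 1
        for i in range(n_vertices):
            if size[i] > 0:
                hist[size[i]] += 1
    return hist


@njit(cache=True)
def fragment_hist_bond(eu, ev, n_vertices, counts, seed):
    """Bond-breakage analogue of :func:`fragment_hist_vertex`; all
    vertices are accounted for, so singlets appear as size-1 fragments."""
    np.random.seed(seed)
    n_edges = eu.shape[0]
    parent = np.empty(n_vertices, np.int32)
    eperm = np.empty(n_edges, np.int32)
    removed = np.empty(n_edges, np.uint8)
    size = np.empty(n_vertices, np.int64)
    hist = np.zeros(n_vertices + 1, np.int64)
    for r in range(counts.shape[0]):
        count = counts[r]
        for i in range(n_vertices):
            parent[i] = i
            size[i] = 0
        for e in range(n_edges):
            eperm[e] = e
            removed[e] = 0
        for i in range(count):
            j = np.random.randint(i, n_edges)
            t = eperm[i]
            eperm[i] = eperm[j]
            eperm[j] = t
            removed[eperm[i]] = 1
        for e in range(n_edges):
            if removed[e] == 0:
                ra = _find(parent, eu[e])
                rb = _find(parent, ev[e])
                if ra != rb:
                    parent[ra] = rb
        for i in range(n_vertices):
            size[_find(parent, i)] += 1
        for i in range(n_vertices):
            if size[i] > 0:
                hist[size[i]] += 1
    return hist
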
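"""Compiled kernels for the null-model ensembles.

The pipeline evaluates thousands of degree-preserving random references
(double-edge swaps) per study, each needing clustering and shortest-path
summaries.  These inner loops are numba-compiled; everything user-facing
wraps them with validated containers.

All kernels are single-threaded and seeded through numba's own Mersenne
Twister (``np.random.seed`` inside nopython code), so results are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "local_clustering",
    "double_edge_swap",
    "bfs_mean_path",
    "null_ensemble",
]


@njit(cache=True)
def local_clustering(adj):
    """Per-node Watts-Strogatz clustering of a 0/1 adjacency matrix.

    node_C(i) = 2 t(i) / (k_i (k_i - 1)) with t(i) the number of triangles
    through i; nodes of degree < 2 get 0.
    """
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        k = 0
        for j in range(n):
            if adj[i, j]:
                k += 1
        if k < 2:
            continue
        t = 0
        for j in range(n):
            if not adj[i, j]:
                continue
            for l in range(j + 1, n):
                if adj[i, l] and adj[j, l]:
                    t += 1
        out[i] = 2.0 * t / (k * (k - 1))
    return out


@njit(cache=True)
def bfs_mean_path(adj):
    """Mean shortest-path length over reachable ordered pairs.

    Returns (mean_length, n_unreachable_ordered_pairs).  Pairs in different
    components are excluded from the mean; a graph with no reachable pair
    returns (nan, ...).
    """
    n = adj.shape[0]
    # adjacency lists for BFS speed
    deg = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                deg[i] += 1
    nbr = np.empty((n, n), dtype=np.int64)
    for i in range(n):
        c = 0
        for j in range(n):
            if adj[i, j]:
                nbr[i, c] = j
                c += 1
    total = 0.0
    n_pairs = 0
    n_unreach = 0
    dist = np.empty(n, dtype=np.int64)
    queue = np.empty(n, dtype=np.int64)
    for s in range(n):
        for i in range(n):
            dist[i] = -1
        dist[s] = 0
        queue[0] = s
        head = 0
        tail = 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[u]
            for c in range(deg[u]):
                v = nbr[u, c]
                if dist[v] < 0:
                    dist[v] = du + 1
                    queue[tail] = v
                    tail += 1
        for t in range(n):
            if t == s:
                continue
            if dist[t] < 0:
                n_unreach += 1
            else:
                total += dist[t]
                n_pairs += 1
    if n_pairs == 0:
        return np.nan, n_unreach
    return total / n_pairs, n_unreach


@njit(cache=True)
def n_components(adj):
    """Number of connected components of a 0/1 adjacency matrix."""
    n = adj.shape[0]
    label = np.full(n, -1, dtype=np.int64)
    queue = np.empty(n, dtype=np.int64)
    n_comp = 0
    for s in range(n):
        if label[s] >= 0:
            continue
        n_comp += 1
        label[s] = n_comp
        queue[0] = s
        head = 0
        tail = 1
        while head < tail:
            u = queue[head]
            head += 1
            for v in range(n):
                if adj[u, v] and label[v] < 0:
                    label[v] = n_comp
                    queue[tail] = v
                    tail += 1
    return n_comp


@njit(cache=True)
def _swap_attempts(adj, edges, n_attempts):
    """Maslov-Sneppen double-edge swaps on (adj, edge list), in place.

    Picks two distinct edges (a,b), (c,d) and rewires to (a,d), (c,b) when
    the result stays simple.  Returns the number of successful swaps.
    """
    m = edges.shape[0]
    n_success = 0
    for _ in range(n_attempts):
        e1 = np.random.randint(m)
        e2 = np.random.randint(m)
        if e1 == e2:
            continue
        a = edges[e1, 0]
        b = edges[e1, 1]
        c = edges[e2, 0]
        d = edges[e2, 1]
        # random orientation of the second edge
        if np.random.randint(2) == 1:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = 0
        adj[b, a] = 0
        adj[c, d] = 0
        adj[d, c] = 0
        adj[a, d] = 1
        adj[d, a] = 1
        adj[c, b] = 1
        adj[b, c] = 1
        edges[e1, 0] = a
        edges[e1, 1] = d
        edges[e2, 0] = c
        edges[e2, 1] = b
        n_success += 1
    return n_success


@njit(cache=True)
def double_edge_swap(adj, n_attempts, seed):
    """Return a degree-preserving randomization of ``adj``.

    Performs ``n_attempts`` swap attempts (failures skipped) and returns
    (rewired adjacency, n_successful_swaps).
    """
    np.random.seed(seed)
    n = adj.shape[0]
    out = adj.copy()
    m = 0
    for i in range(n):
        for j in range(i + 1, n):
            if out[i, j]:
                m += 1
    edges = np.empty((m, 2), dtype=np.int64)
    c = 0
    for i in range(n):
        for j in range(i + 1, n):
            if out[i, j]:
                edges[c, 0] = i
                edges[c, 1] = j
                c += 1
    if m < 2:
        return out, 0
    n_success = _swap_attempts(out, edges, n_attempts)
    return out, n_success


@njit(cache=True)
def null_ensemble(adj, n_null, swaps_per_edge, seed):
    """Clustering / path-length summaries over a random-reference ensemble.

    For each of ``n_null`` independent degree-preserving randomizations
    (seeded seed+index) records the mean clustering and the mean shortest
    path over reachable pairs.  Returns

    (node_C_null_mean, C_per_null, L_per_null, n_fragmented, n_swaps_total)

    where node_C_null_mean is the per-node clustering averaged over the
    ensemble (needed for node-level normalized clustering).
    """
    n = adj.shape[0]
    m = 0
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                m += 1
    n_attempts = swaps_per_edge * m
    node_acc = np.zeros(n)
    c_null = np.empty(n_null)
    l_null = np.empty(n_null)
    n_frag = 0
    n_swaps = 0
    for r in range(n_null):
        rnd, ns = double_edge_swap(adj, n_attempts, seed + r)
        n_swaps += ns
        nc = local_clustering(rnd)
        node_acc += nc
        c_null[r] = nc.mean()
        L, n_unreach = bfs_mean_path(rnd)
        l_null[r] = L
        if n_unreach > 0:
            n_frag += 1
    return node_acc / n_null, c_null, l_null, n_frag, n_swaps
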
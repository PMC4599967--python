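"""Brute-force reference implementations used only by the test suite.

These deliberately avoid the library code paths (and networkx's centrality
routines) so they can serve as independent oracles: plain BFS, explicit
shortest-path enumeration, truncated matrix series, Laplacian pseudo-inverse
electrical flows, and exhaustive pair counting.
"""

import itertools
import math

import numpy as np


def bfs_distances(adj, start):
    """adj: {node: set(neighbors)} -> {node: hop distance}."""
    dist = {start: 0}
    frontier = [start]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def graph_to_adj(edges, nodes=None):
    adj = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    for n in nodes or ():
        adj.setdefault(n, set())
    return adj


def eccentricity(adj, node):
    d = bfs_distances(adj, node)
    assert len(d) == len(adj), "graph must be connected"
    return max(d.values())


def closeness(adj, node):
    d = bfs_distances(adj, node)
    n = len(adj)
    return (n - 1) / sum(v for k, v in d.items() if k != node)


def second_degree(adj, node):
    d = bfs_distances(adj, node)
    return sum(1 for k, v in d.items() if v == 2)


def inverse_shortest_path(adj, a, b):
    return 1.0 / bfs_distances(adj, a)[b]


def count_shortest_paths(adj, s, t):
    """Number of shortest s-t paths, and those passing through each node."""
    dist = bfs_distances(adj, s)
    # count paths by DP over BFS layers
    npaths = {s: 1}
    order = sorted(dist, key=dist.get)
    for v in order:
        if v == s:
            continue
        npaths[v] = sum(
            npaths[u] for u in adj[v] if dist.get(u, -1) == dist[v] - 1
        )
    return dist, npaths


def betweenness(adj, normalized=True):
    """Exact betweenness by summing pair dependencies (Brandes-free DP)."""
    nodes = sorted(adj)
    n = len(nodes)
    bc = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        dist_s, paths_s = count_shortest_paths(adj, s, t)
        dist_t, paths_t = count_shortest_paths(adj, t, s)
        total = paths_s[t]
        for v in nodes:
            if v in (s, t):
                continue
            if dist_s[v] + dist_t[v] == dist_s[t]:
                bc[v] += paths_s[v] * paths_t[v] / total
    if normalized and n > 2:
        scale = 1.0 / ((n - 1) * (n - 2) / 2)
        bc = {v: b * scale for v, b in bc.items()}
    return bc


def communicability_series(edges, nodes, a, b, kmax=30):
    """Truncated walk series sum_k (A^k)_{ab} / k!."""
    nodes = sorted(nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for u, v in edges:
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = 1.0
    term = np.eye(n)
    total = np.eye(n)
    for k in range(1, kmax + 1):
        term = term @ A / k
        total += term
    return total[idx[a], idx[b]]


def eigenvector_power_iteration(edges, nodes, tol=1e-12, iters=10000):
    nodes = sorted(nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for u, v in edges:
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = 1.0
    x = np.ones(n) / math.sqrt(n)
    for _ in range(iters):
        y = A @ x
        y /= np.linalg.norm(y)
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    return dict(zip(nodes, np.abs(x)))


def pagerank_power_iteration(edges, nodes, alpha=0.85, tol=1e-12, iters=10000):
    nodes = sorted(nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for u, v in edges:
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = 1.0
    deg = A.sum(axis=1)
    P = A / deg[:, None]
    x = np.ones(n) / n
    for _ in range(iters):
        y = alpha * P.T @ x + (1 - alpha) / n
        if np.abs(y - x).sum() < tol:
            x = y
            break
        x = y
    return dict(zip(nodes, x / x.sum()))


def current_flow_betweenness(edges, nodes, normalized=True):
    """Electrical-flow betweenness via the Laplacian pseudo-inverse.

    For each source/sink pair (s, t) a unit current is injected; a node's
    throughput is half the absolute current over its incident edges
    (endpoints excluded, matching the normalized convention).
    """
    nodes = sorted(nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for u, v in edges:
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = 1.0
    L = np.diag(A.sum(axis=1)) - A
    Lp = np.linalg.pinv(L)
    cfb = {v: 0.0 for v in nodes}
    edge_list = [(idx[u], idx[v]) for u, v in edges]
    for s, t in itertools.combinations(range(n), 2):
        p = Lp[:, s] - Lp[:, t]  # node potentials for unit s->t current
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(
                abs(p[a] - p[b])
                for a, b in edge_list
                if v in (a, b)
            )
            cfb[nodes[v]] += through / 2.0
    if normalized and n > 2:
        scale = 1.0 / ((n - 1) * (n - 2) / 2)
        cfb = {v: b * scale for v, b in cfb.items()}
    return cfb


def auc_pair_counting(scores, labels):
    """AUC as the fraction of (pos, neg) pairs ranked correctly (ties 1/2)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def fisher_exact_two_sided(tp, fp, fn, tn):
    """Two-sided Fisher p by summing hypergeometric tables with p <= p_obs."""
    n = tp + fp + fn + tn
    row1 = tp + fp
    col1 = tp + fn

    def log_comb(a, b):
        return (
            math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)
        )

    def pmf(k):
        return math.exp(
            log_comb(col1, k)
            + log_comb(n - col1, row1 - k)
            - log_comb(n, row1)
        )

    kmin = max(0, row1 - (n - col1))
    kmax = min(row1, col1)
    p_obs = pmf(tp)
    total = 0.0
    for k in range(kmin, kmax + 1):
        pk = pmf(k)
        if pk <= p_obs * (1 + 1e-10):
            total += pk
    return min(total, 1.0)
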
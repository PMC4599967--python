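"""Connectivity-profile parameters: 8 per gene and 4 per gene pair.

A gene's connectivity profile is the vector of eight single-node graph
parameters (betweenness, closeness, current-flow betweenness, degree
centrality, eccentricity, eigenvector centrality, PageRank and the count of
second-degree neighbors). A gene pair adds four node-pair parameters
(communicability, inverse shortest path, shared neighbors and shared
non-neighbors), for 20 values per pair once both genes' profiles are
attached.

All parameters require a connected graph; callers prune with
:func:`sinatra.netio.largest_component` first. Column order is alphabetical
and fixed by :data:`NODE_PARAMS` / :data:`PAIR_PARAMS`.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse
import scipy.sparse.csgraph

__all__ = [
    "NODE_PARAMS",
    "PAIR_PARAMS",
    "node_profiles",
    "pair_profiles",
    "pair_parameter_matrices",
    "second_degree_neighbors",
    "communicability",
    "inverse_shortest_path",
    "shared_neighbors",
    "shared_non_neighbors",
]

NODE_PARAMS = [
    "betweenness_centrality",
    "closeness_centrality",
    "current_flow_betweenness",
    "degree_centrality",
    "eccentricity",
    "eigenvector_centrality",
    "pagerank",
    "second_degree_neighbors",
]

PAIR_PARAMS = [
    "communicability",
    "inverse_shortest_path",
    "shared_neighbors",
    "shared_non_neighbors",
]

#: PageRank damping factor.
PAGERANK_ALPHA = 0.85


def _check_connected(net):
    if net.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes")
    if not nx.is_connected(net):
        raise ValueError(
            "network must be a single connected component "
            "(eccentricity and shortest paths are undefined otherwise)"
        )


def _check_pair(net, pair):
    g1, g2 = pair
    if g1 == g2:
        raise ValueError(f"pair parameters are undefined for identical genes ({g1!r})")
    for g in (g1, g2):
        if g not in net:
            raise KeyError(f"gene {g!r} not in network")
    return g1, g2


def _adjacency(net):
    nodes = sorted(net.nodes())
    A = nx.to_numpy_array(net, nodelist=nodes, dtype=float)
    return nodes, A


def _eigenvector_centrality(A):
    """Dominant adjacency eigenvector, L2-normalized, non-negative.

    Dense symmetric eigendecomposition: deterministic, no power-iteration
    convergence concerns, fine for desk-scale graphs (n up to a few
    thousand). The Perron-Frobenius vector of a connected graph is strictly
    positive, so a global sign flip orients it.
    """
    w, v = np.linalg.eigh(A)
    vec = v[:, np.argmax(w)]
    if vec.sum() < 0:
        vec = -vec
    return np.abs(vec) / np.linalg.norm(vec)


def node_profiles(net, approx_current_flow=False):
    """Compute the 8 single-node parameters for every node.

    Parameters
    ----------
    net : networkx.Graph
        Connected simple graph.
    approx_current_flow : bool
        Use the sampled approximation of current-flow betweenness for very
        large graphs (exact computation is O(n^3) in the Laplacian solve).

    Returns
    -------
    pandas.DataFrame
        Indexed by gene, columns :data:`NODE_PARAMS` (alphabetical).
    """
    _check_connected(net)
    nodes, A = _adjacency(net)
    n = len(nodes)

    betweenness = nx.betweenness_centrality(net, normalized=True)
    closeness = nx.closeness_centrality(net)
    if approx_current_flow and n > 5000:
        cfb = nx.approximate_current_flow_betweenness_centrality(
            net, normalized=True, seed=0
        )
    else:
        cfb = nx.current_flow_betweenness_centrality(net, normalized=True)
    degree = nx.degree_centrality(net)
    ecc = nx.eccentricity(net)
    eig = dict(zip(nodes, _eigenvector_centrality(A)))
    pagerank = nx.pagerank(net, alpha=PAGERANK_ALPHA, tol=1e-10, max_iter=1000)

    # distance-2 counts straight from the adjacency matrix: reachable in two
    # hops but not adjacent and not the node itself
    two_step = (A @ A) > 0
    at_dist2 = two_step & (A == 0)
    np.fill_diagonal(at_dist2, False)
    second_deg = at_dist2.sum(axis=1)

    df = pd.DataFrame(
        {
            "betweenness_centrality": [betweenness[g] for g in nodes],
            "closeness_centrality": [closeness[g] for g in nodes],
            "current_flow_betweenness": [cfb[g] for g in nodes],
            "degree_centrality": [degree[g] for g in nodes],
            "eccentricity": [float(ecc[g]) for g in nodes],
            "eigenvector_centrality": [eig[g] for g in nodes],
            "pagerank": [pagerank[g] for g in nodes],
            "second_degree_neighbors": second_deg.astype(float),
        },
        index=pd.Index(nodes, name="gene"),
    )
    return df[NODE_PARAMS]


def pair_parameter_matrices(net, snn_mode="adjacent_to_neither"):
    """Dense n-by-n matrices of the four node-pair parameters.

    Returns ``(nodes, {param: matrix})`` with nodes sorted; only the
    off-diagonal entries are meaningful. Computing all pairs at once keeps
    whole-network rank translation cheap.
    """
    _check_connected(net)
    nodes, A = _adjacency(net)
    n = len(nodes)

    comm = scipy.linalg.expm(A)

    dist = scipy.sparse.csgraph.shortest_path(
        scipy.sparse.csr_matrix(A), method="D", unweighted=True
    )
    with np.errstate(divide="ignore"):
        isp = 1.0 / dist
    np.fill_diagonal(isp, 0.0)

    shared = A @ A  # (A^2)_ij = common neighbors of i and j (no self-loops)
    deg = A.sum(axis=1)
    if snn_mode == "adjacent_to_neither":
        # |V \ {i,j}| minus |N(i) u N(j) \ {i,j}|
        union = deg[:, None] + deg[None, :] - 2 * A - shared
        snn = (n - 2) - union
    elif snn_mode == "not_in_intersection":
        snn = (n - 2) - shared
    else:
        raise ValueError(f"unknown snn_mode {snn_mode!r}")

    return nodes, {
        "communicability": comm,
        "inverse_shortest_path": isp,
        "shared_neighbors": shared,
        "shared_non_neighbors": snn,
    }


def pair_profiles(net, pairs=None, snn_mode="adjacent_to_neither"):
    """The 4 node-pair parameters for the given pairs (default: all pairs).

    Returns a DataFrame with columns ``gene1, gene2`` (sorted within pair)
    plus :data:`PAIR_PARAMS`.
    """
    nodes, mats = pair_parameter_matrices(net, snn_mode=snn_mode)
    idx = {g: i for i, g in enumerate(nodes)}
    if pairs is None:
        iu, ju = np.triu_indices(len(nodes), k=1)
    else:
        pairs = [tuple(sorted(_check_pair(net, p))) for p in pairs]
        iu = np.array([idx[p[0]] for p in pairs], dtype=int)
        ju = np.array([idx[p[1]] for p in pairs], dtype=int)
    node_arr = np.array(nodes)
    df = pd.DataFrame({"gene1": node_arr[iu], "gene2": node_arr[ju]})
    for param in PAIR_PARAMS:
        df[param] = mats[param][iu, ju]
    return df


def second_degree_neighbors(net, gene):
    """Number of nodes at shortest-path distance exactly 2 from ``gene``."""
    if gene not in net:
        raise KeyError(f"gene {gene!r} not in network")
    first = set(net[gene])
    second = set()
    for nb in first:
        second.update(net[nb])
    second -= first
    second.discard(gene)
    return len(second)


def communicability(net, pair):
    """Walk-sum between the pair: the (i, j) entry of expm(A)."""
    g1, g2 = _check_pair(net, pair)
    nodes, A = _adjacency(net)
    E = scipy.linalg.expm(A)
    idx = {g: i for i, g in enumerate(nodes)}
    return float(E[idx[g1], idx[g2]])


def inverse_shortest_path(net, pair):
    """1 / d(i, j); equals 1 for adjacent pairs."""
    g1, g2 = _check_pair(net, pair)
    return 1.0 / nx.shortest_path_length(net, g1, g2)


def shared_neighbors(net, pair):
    """|N(i) ∩ N(j)|, excluding i and j themselves."""
    g1, g2 = _check_pair(net, pair)
    common = (set(net[g1]) & set(net[g2])) - {g1, g2}
    return len(common)


def shared_non_neighbors(net, pair, mode="adjacent_to_neither"):
    """Nodes (other than the pair) adjacent to neither gene.

    ``mode="not_in_intersection"`` switches to the looser reading (nodes
    missing from at least one neighborhood) for sensitivity analysis.
    """
    g1, g2 = _check_pair(net, pair)
    others = set(net.nodes()) - {g1, g2}
    n1, n2 = set(net[g1]), set(net[g2])
    if mode == "adjacent_to_neither":
        return len([v for v in others if v not in n1 and v not in n2])
    if mode == "not_in_intersection":
        return len([v for v in others if not (v in n1 and v in n2)])
    raise ValueError(f"unknown mode {mode!r}")
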
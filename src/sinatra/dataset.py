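"""Assemble labeled 20-column pair feature matrices.

A training or scoring row is one unordered gene pair carrying the 8
single-node parameters of each member (16 columns), the 4 node-pair
parameters, and a label in {SL, NSL, unlabeled}. Which gene occupies
position 1 vs position 2 is decided by a seeded fair coin per pair, so the
classifier cannot exploit positional bias (e.g. a single hub gene always
appearing first).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .features import NODE_PARAMS, PAIR_PARAMS

__all__ = [
    "FEATURE_COLUMNS",
    "load_sl_labels",
    "sample_negatives",
    "assemble_features",
    "write_feature_table",
    "read_feature_table",
]

logger = logging.getLogger(__name__)

G1_COLUMNS = [f"g1_{p}" for p in NODE_PARAMS]
G2_COLUMNS = [f"g2_{p}" for p in NODE_PARAMS]
#: the fixed 20-column feature schema
FEATURE_COLUMNS = G1_COLUMNS + G2_COLUMNS + list(PAIR_PARAMS)


def load_sl_labels(path, net):
    """Read a 2-column TSV of SL gene pairs, restricted to network genes.

    Pairs are unordered; duplicates (in either order) collapse. Pairs with a
    member outside the network are dropped and counted in the log — the SL
    label set of a species routinely names genes absent from its pruned PPI
    component.
    """
    pairs = set()
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}:{lineno}: expected two gene ids")
            a, b = parts[0], parts[1]
            if a == b:
                continue
            if a in net and b in net:
                pairs.add(frozenset((a, b)))
            else:
                dropped += 1
    if dropped:
        logger.info("load_sl_labels: dropped %d pairs with off-network genes", dropped)
    return pairs


def _decode_pair_index(k, n):
    """Map linear index k in [0, C(n,2)) to (i, j) with i < j (row-major)."""
    # row i starts at offset(i) = i*(2n-i-1)/2; invert the quadratic, then
    # nudge for float rounding at row boundaries
    i = int(((2 * n - 1) - np.sqrt((2 * n - 1) ** 2 - 8.0 * k)) // 2)
    while i * (2 * n - i - 1) // 2 > k:
        i -= 1
    while (i + 1) * (2 * n - i - 2) // 2 <= k:
        i += 1
    j = int(k - i * (2 * n - i - 1) // 2 + i + 1)
    return i, j


def sample_negatives(net, positives, ratio, seed):
    """Uniformly sample NSL pairs from all network pairs minus the SL set.

    Exactly ``round(ratio * |positives|)`` pairs, without replacement,
    reproducible under ``seed``. SL interactions are rare (~0.1% of pairs),
    so unlabeled pairs are treated as non-SL.
    """
    nodes = sorted(net.nodes())
    n = len(nodes)
    total = n * (n - 1) // 2
    needed = round(ratio * len(positives))
    available = total - len(positives)
    if needed > available:
        raise ValueError(
            f"requested {needed} negatives but only {available} non-SL pairs exist"
        )
    rng = np.random.default_rng(seed)
    negatives = set()
    # rejection sampling in growing batches; duplicates and positives are
    # discarded, so each accepted pair is uniform over the complement
    while len(negatives) < needed:
        batch = rng.integers(0, total, size=max(2 * (needed - len(negatives)), 64))
        for k in batch:
            i, j = _decode_pair_index(int(k), n)
            pair = frozenset((nodes[i], nodes[j]))
            if pair not in positives:
                negatives.add(pair)
                if len(negatives) == needed:
                    break
    return negatives


def assemble_features(
    node_profiles,
    pair_profiles,
    pairs,
    labels=None,
    shuffle_seed=0,
    order="shuffle",
):
    """Build the 20-column feature matrix for the given pairs.

    Parameters
    ----------
    node_profiles : pandas.DataFrame
        One row per gene, columns :data:`~sinatra.features.NODE_PARAMS`
        (translated or raw — assembly is scheme-agnostic).
    pair_profiles : pandas.DataFrame
        Columns ``gene1, gene2`` plus the four node-pair parameters,
        covering every requested pair.
    pairs : iterable of unordered pairs
    labels : mapping pair -> {"SL", "NSL"}, optional
        Unlisted pairs get the label ``unlabeled``.
    shuffle_seed : int
        Seed for the per-pair position coin flip.
    order : {"shuffle", "sorted", "degree"}
        ``shuffle`` (default) randomizes gene order per pair; ``sorted`` and
        ``degree`` are deterministic alternatives for ablation studies
        (``degree`` puts the higher-degree-centrality gene first).

    Returns
    -------
    pandas.DataFrame
        Columns ``gene1, gene2`` + :data:`FEATURE_COLUMNS` + ``label``.
    """
    pair_list = sorted(tuple(sorted(p)) for p in pairs)
    a = np.array([p[0] for p in pair_list], dtype=object)
    b = np.array([p[1] for p in pair_list], dtype=object)

    genes_needed = set(a) | set(b)
    missing = genes_needed - set(node_profiles.index)
    if missing:
        raise KeyError(f"no node profile for gene(s): {sorted(missing)[:5]}")

    rng = np.random.default_rng(shuffle_seed)
    if order == "shuffle":
        swap = rng.integers(0, 2, size=len(pair_list)).astype(bool)
    elif order == "sorted":
        swap = np.zeros(len(pair_list), dtype=bool)
    elif order == "degree":
        deg = node_profiles["degree_centrality"]
        swap = deg.loc[a].to_numpy() < deg.loc[b].to_numpy()
    else:
        raise ValueError(f"unknown order {order!r}")
    first = np.where(swap, b, a)
    second = np.where(swap, a, b)

    key_index = pd.MultiIndex.from_arrays(
        [pair_profiles["gene1"], pair_profiles["gene2"]]
    )
    indexed_pairs = pair_profiles.set_index(key_index)[list(PAIR_PARAMS)]
    want = pd.MultiIndex.from_arrays([a, b])
    pair_vals = indexed_pairs.reindex(want)
    if pair_vals.isna().any().any():
        bad = want[pair_vals.isna().any(axis=1)][0]
        raise KeyError(f"no pair profile for pair {tuple(bad)}")

    node_mat = node_profiles[NODE_PARAMS]
    g1_vals = node_mat.loc[first].to_numpy()
    g2_vals = node_mat.loc[second].to_numpy()

    out = pd.DataFrame({"gene1": first, "gene2": second})
    out[G1_COLUMNS] = g1_vals
    out[G2_COLUMNS] = g2_vals
    out[list(PAIR_PARAMS)] = pair_vals.to_numpy()
    if labels is None:
        out["label"] = "unlabeled"
    else:
        out["label"] = [
            labels.get(frozenset(p), "unlabeled") for p in pair_list
        ]
    return out[["gene1", "gene2"] + FEATURE_COLUMNS + ["label"]]


def write_feature_table(table, path):
    table.to_csv(path, sep="\t", index=False)


def read_feature_table(path):
    df = pd.read_csv(path, sep="\t", dtype={"gene1": str, "gene2": str})
    expected = ["gene1", "gene2"] + FEATURE_COLUMNS + ["label"]
    if list(df.columns) != expected:
        raise ValueError(f"feature table columns do not match schema: {list(df.columns)}")
    return df
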
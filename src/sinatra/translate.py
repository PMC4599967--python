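"""Within-species normalization ("translation") of parameter values.

Raw connectivity parameters live on species-specific scales: a dense,
well-studied network yields systematically larger degrees, communicabilities
and PageRank mass than a sparse one. Translation rescales each parameter
*within* a species so profiles become comparable *across* species. Four
schemes are supported:

``max``
    divide by the per-column maximum;
``rank``
    rank smallest-to-largest with ties broken at random, divide by n —
    every column becomes a permutation of {1/n, ..., 1};
``tied_rank``
    average ranks for ties, divide by n (deterministic);
``quantile``
    classic quantile normalization across species, with shorter vectors
    up-sampled by linear interpolation between order statistics.

``raw`` is the identity and serves as the untranslated control. Single-node
parameters are always normalized over the species' genes and node-pair
parameters over the species' gene pairs; the two universes are never mixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .features import NODE_PARAMS, PAIR_PARAMS

__all__ = [
    "SCHEMES",
    "TranslationScheme",
    "max_normalize",
    "rank_normalize",
    "tied_rank_normalize",
    "quantile_normalize",
    "translate_columns",
    "translate_table",
]

SCHEMES = ("raw", "max", "rank", "tied_rank", "quantile")


@dataclass(frozen=True)
class TranslationScheme:
    """Normalization scheme plus the seed consumed by random tie-breaking."""

    name: str = "rank"
    seed: int = 0

    def __post_init__(self):
        if self.name not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.name!r}")


def max_normalize(values):
    """Divide by the maximum value; requires non-negative, not-all-zero input."""
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("max normalization expects non-negative parameters")
    m = v.max(initial=0.0)
    if m == 0:
        raise ValueError("all-zero vector cannot be max-normalized")
    return v / m


def rank_normalize(values, seed):
    """Ranks divided by n, ties resolved at random (seed-reproducible).

    The output is a permutation of {1/n, 2/n, ..., 1}: equal raw values
    receive distinct adjacent ranks in an order drawn from the seeded RNG,
    so the translated column is exactly uniform on that grid.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n == 0:
        raise ValueError("empty vector")
    rng = np.random.default_rng(seed)
    tiebreak = rng.permutation(n)
    order = np.lexsort((tiebreak, v))
    ranks = np.empty(n, dtype=float)
    ranks[order] = np.arange(1, n + 1)
    return ranks / n


def tied_rank_normalize(values):
    """Average-rank normalization: equal inputs map to equal outputs."""
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise ValueError("empty vector")
    return scipy.stats.rankdata(v, method="average") / len(v)


def quantile_normalize(vectors):
    """Quantile-normalize one vector per species onto a common distribution.

    Shorter vectors are up-sampled to the longest length by linear
    interpolation between order statistics; the sorted columns are averaged
    across species and the averages re-assigned within each species by rank
    (average quantile position for ties).

    Returns a list of arrays in the input order.
    """
    vecs = [np.asarray(v, dtype=float) for v in vectors]
    if len(vecs) < 2:
        raise ValueError("quantile normalization needs at least 2 vectors")
    if any(len(v) == 0 for v in vecs):
        raise ValueError("empty vector")
    L = max(len(v) for v in vecs)
    grid = np.linspace(0.0, 1.0, L)
    upsampled = [
        np.interp(grid, np.linspace(0.0, 1.0, len(v)), np.sort(v)) for v in vecs
    ]
    mean_sorted = np.mean(upsampled, axis=0)
    out = []
    for v in vecs:
        n = len(v)
        # average quantile position of each value within its own species
        q = (scipy.stats.rankdata(v, method="average") - 1) / max(n - 1, 1)
        out.append(np.interp(q, grid, mean_sorted))
    return out


def _translate_one(values, scheme: TranslationScheme, column_seed):
    if scheme.name == "raw":
        return np.asarray(values, dtype=float)
    if scheme.name == "max":
        return max_normalize(values)
    if scheme.name == "rank":
        return rank_normalize(values, column_seed)
    if scheme.name == "tied_rank":
        return tied_rank_normalize(values)
    raise ValueError(
        f"scheme {scheme.name!r} cannot be applied to a single species vector"
    )


def translate_columns(df, scheme, copy=True):
    """Apply a within-species scheme to every column of a profile table.

    Each column consumes a dedicated RNG stream derived from the scheme seed
    and the column name, so tie randomization is reproducible and columns
    are independent.
    """
    if isinstance(scheme, str):
        scheme = TranslationScheme(scheme)
    out = df.copy() if copy else df
    for col in out.columns:
        col_seed = _column_seed(scheme.seed, col)
        out[col] = _translate_one(out[col].to_numpy(), scheme, col_seed)
    return out


def _column_seed(seed, column):
    ss = np.random.SeedSequence([int(seed), _stable_hash(column)])
    return ss.generate_state(1)[0]


def _stable_hash(text):
    import zlib

    return zlib.crc32(str(text).encode())


def translate_table(node_profiles, pair_profiles, scheme):
    """Translate a species' node and pair profile tables independently.

    Single-node columns are normalized over the genes of the network,
    node-pair columns over all pairs; the column name decides which table a
    parameter belongs to, and an unrecognized column is an error.

    For the cross-species ``quantile`` scheme use
    :func:`quantile_normalize` on matched columns of both species instead.
    """
    if isinstance(scheme, str):
        scheme = TranslationScheme(scheme)
    for col in node_profiles.columns:
        if col not in NODE_PARAMS:
            raise ValueError(f"unrecognized single-node column {col!r}")
    pair_cols = [c for c in pair_profiles.columns if c not in ("gene1", "gene2")]
    for col in pair_cols:
        if col not in PAIR_PARAMS:
            raise ValueError(f"unrecognized node-pair column {col!r}")
    nodes_t = translate_columns(node_profiles, scheme)
    pairs_t = pair_profiles.copy()
    for col in pair_cols:
        col_seed = _column_seed(scheme.seed, "pair:" + col)
        pairs_t[col] = _translate_one(pairs_t[col].to_numpy(), scheme, col_seed)
    return nodes_t, pairs_t
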
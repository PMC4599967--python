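"""Connectivity-homology distances between interspecies gene profiles.

Two genes (possibly from different species) are connectivity homologous
when their translated single-node parameter vectors are close in Euclidean
distance. This module computes those distances for interspecies gene pairs
and stratifies them by (a) orthology and (b) shared *specific* function —
GO terms annotating at most ``specificity_cutoff`` genes in each species —
to test whether network position tracks function independently of sequence
homology.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import scipy.stats

from .features import NODE_PARAMS

__all__ = [
    "profile_distance",
    "interspecies_distances",
    "stratified_distance_comparison",
    "SPECIFICITY_CUTOFFS",
]

#: the cutoff sweep used for the functional-specificity sensitivity analysis
SPECIFICITY_CUTOFFS = (10, 15, 20, 25, 50, 75, 100, 150, 200, 250, 500, 750)


def profile_distance(profile_a, profile_b):
    """Euclidean distance between two 8-parameter node profiles.

    Both profiles must carry the same parameter schema (and should be
    translated with the same scheme — raw scales are not comparable across
    species).
    """
    a = pd.Series(profile_a)
    b = pd.Series(profile_b)
    if list(a.index) != list(b.index):
        raise ValueError(
            f"profile schemas differ: {list(a.index)} vs {list(b.index)}"
        )
    return float(np.linalg.norm(a.to_numpy(dtype=float) - b.to_numpy(dtype=float)))


def interspecies_distances(profiles_a, profiles_b, max_pairs=1_000_000, seed=0):
    """All (or a seeded subsample of) interspecies gene-pair distances.

    Returns a DataFrame ``gene_a, gene_b, distance``. The full cross product
    is quadratic; above ``max_pairs`` a uniform subsample is drawn.
    """
    genes_a = list(profiles_a.index)
    genes_b = list(profiles_b.index)
    ma = profiles_a[NODE_PARAMS].to_numpy(dtype=float)
    mb = profiles_b[NODE_PARAMS].to_numpy(dtype=float)
    total = len(genes_a) * len(genes_b)
    if total <= max_pairs:
        ia, ib = np.meshgrid(np.arange(len(genes_a)), np.arange(len(genes_b)), indexing="ij")
        ia, ib = ia.ravel(), ib.ravel()
    else:
        rng = np.random.default_rng(seed)
        flat = rng.choice(total, size=max_pairs, replace=False)
        ia, ib = np.divmod(flat, len(genes_b))
    d = np.linalg.norm(ma[ia] - mb[ib], axis=1)
    return pd.DataFrame(
        {
            "gene_a": np.array(genes_a, dtype=object)[ia],
            "gene_b": np.array(genes_b, dtype=object)[ib],
            "distance": d,
        }
    )


def _specific_terms(go_a, go_b, cutoff):
    """GO terms annotating <= cutoff genes in each species."""
    def counts(go):
        c = {}
        for terms in go.values():
            for t in terms:
                c[t] = c.get(t, 0) + 1
        return c

    ca, cb = counts(go_a), counts(go_b)
    return {t for t in set(ca) & set(cb) if ca[t] <= cutoff and cb[t] <= cutoff}


def stratified_distance_comparison(
    profiles_a,
    profiles_b,
    orthology,
    go_a,
    go_b,
    specificity_cutoff=100,
    max_pairs=1_000_000,
    seed=0,
):
    """Distance medians in the 4 orthology-by-shared-function strata.

    A pair shares a *specific function* when the two genes have at least one
    common GO term annotating no more than ``specificity_cutoff`` genes in
    each species. Mann-Whitney comparisons: same- vs different-function
    (overall and within non-orthologs) and ortholog vs non-ortholog.
    Empty strata are flagged and their comparisons skipped.
    """
    if specificity_cutoff < 1:
        raise ValueError("specificity_cutoff must be >= 1")
    dist = interspecies_distances(profiles_a, profiles_b, max_pairs, seed)
    specific = _specific_terms(go_a, go_b, specificity_cutoff)
    ortho = np.array(
        [
            gb in orthology.targets(ga)
            for ga, gb in zip(dist["gene_a"], dist["gene_b"])
        ]
    )
    shared_fn = np.array(
        [
            bool((go_a.get(ga, set()) & go_b.get(gb, set())) & specific)
            for ga, gb in zip(dist["gene_a"], dist["gene_b"])
        ]
    )
    d = dist["distance"].to_numpy()

    groups = {
        "same_function_ortholog": d[shared_fn & ortho],
        "same_function_non_ortholog": d[shared_fn & ~ortho],
        "different_function_ortholog": d[~shared_fn & ortho],
        "different_function_non_ortholog": d[~shared_fn & ~ortho],
    }
    medians = {
        name: (float(np.median(v)) if len(v) else np.nan)
        for name, v in groups.items()
    }

    def mwu(x, y):
        if len(x) == 0 or len(y) == 0:
            return {"p": np.nan, "skipped": True}
        stat, p = scipy.stats.mannwhitneyu(x, y, alternative="two-sided")
        return {"p": float(p), "U": float(stat), "skipped": False}

    comparisons = {
        "same_vs_different_function": mwu(d[shared_fn], d[~shared_fn]),
        "same_vs_different_function_non_ortholog": mwu(
            groups["same_function_non_ortholog"],
            groups["different_function_non_ortholog"],
        ),
        "ortholog_vs_non_ortholog": mwu(d[ortho], d[~ortho]),
    }
    return {
        "cutoff": specificity_cutoff,
        "n_pairs": len(d),
        "group_sizes": {k: int(len(v)) for k, v in groups.items()},
        "medians": medians,
        "comparisons": comparisons,
    }
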
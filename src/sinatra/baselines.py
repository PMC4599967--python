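"""Comparison predictors the connectivity model is benchmarked against.

Each baseline scores a gene pair from a single kind of evidence:

- **homology transfer** — a target pair is SL if an orthologous source pair
  is SL (fraction of orthologous pairs labeled SL; any score > 0 classifies
  as SL);
- **functional similarity** — the number of shared GO terms (root terms
  ``molecular_function``/``biological_process`` excluded);
- **domain overlap** — the number of shared PFam domains, capped at 7;
- **structural similarity** — depth of the deepest shared SCOP level,
  0 (none) to 4 (same family);
- **bi-nodal information centrality** — the pairwise electrical information
  measure I(i,j) = 1 / (c_ii + c_jj - 2 c_ij) with C = (D - A + J)^-1,
  the standard pairwise information-centrality construction (used here as
  the closest-standard interpretation of the univariate network baseline).

Univariate baselines are wrapped in a logistic regression via
:func:`fit_baseline_model`.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

__all__ = [
    "OrthologyMap",
    "load_orthology",
    "load_annotations",
    "GO_ROOT_TERMS",
    "SCOP_LEVELS",
    "homology_transfer_score",
    "functional_similarity",
    "domain_overlap",
    "structural_similarity",
    "binodal_information_centrality",
    "information_centrality_matrix",
    "fit_baseline_model",
]

GO_ROOT_TERMS = frozenset({"molecular_function", "biological_process"})
SCOP_LEVELS = ("class", "fold", "superfamily", "family")
PFAM_OVERLAP_CAP = 7


class OrthologyMap:
    """Many-to-many source<->target gene correspondence with symmetric lookup."""

    def __init__(self, pairs):
        self._src2tgt = {}
        self._tgt2src = {}
        for s, t in pairs:
            self._src2tgt.setdefault(s, set()).add(t)
            self._tgt2src.setdefault(t, set()).add(s)

    def targets(self, source_gene):
        return frozenset(self._src2tgt.get(source_gene, ()))

    def sources(self, target_gene):
        return frozenset(self._tgt2src.get(target_gene, ()))

    def __len__(self):
        return sum(len(v) for v in self._src2tgt.values())


def load_orthology(path):
    """Orthology TSV ``source_gene<TAB>target_gene`` (duplicates collapse)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["source", "target"], comment="#", dtype=str
    )
    return OrthologyMap(df.itertuples(index=False))


def load_annotations(path, namespace=None):
    """Annotation TSV ``gene<TAB>namespace<TAB>term`` -> {gene: set(term)}."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["gene", "namespace", "term"],
        comment="#",
        dtype=str,
    )
    if namespace is not None:
        df = df[df["namespace"] == namespace]
    out = {}
    for gene, term in zip(df["gene"], df["term"]):
        out.setdefault(gene, set()).add(term)
    return out


def homology_transfer_score(target_pair, source_sl, orthology, whole_genome=False):
    """Fraction of orthologous source pairs labeled SL.

    Missing (None) when either target gene lacks an ortholog, unless
    ``whole_genome=True``, where the convention is a feature value of 0.
    A score > 0 classifies the pair as SL under the transfer rule.
    """
    t1, t2 = tuple(target_pair)
    s1s = orthology.sources(t1)
    s2s = orthology.sources(t2)
    if not s1s or not s2s:
        return 0.0 if whole_genome else None
    candidates = {
        frozenset((a, b)) for a in s1s for b in s2s if a != b
    }
    if not candidates:
        return 0.0 if whole_genome else None
    hits = sum(1 for p in candidates if p in source_sl)
    return hits / len(candidates)


def functional_similarity(pair, go):
    """Shared GO term count after root-term exclusion (0 if unannotated)."""
    g1, g2 = tuple(pair)
    t1 = go.get(g1, set()) - GO_ROOT_TERMS
    t2 = go.get(g2, set()) - GO_ROOT_TERMS
    return len(t1 & t2)


def domain_overlap(pair, pfam):
    """Shared PFam-domain count, capped at 7 (the model's [0, 8) range)."""
    g1, g2 = tuple(pair)
    overlap = len(pfam.get(g1, set()) & pfam.get(g2, set()))
    return min(overlap, PFAM_OVERLAP_CAP)


def structural_similarity(pair, scop):
    """Deepest shared SCOP level: 1=class, 2=fold, 3=superfamily, 4=family.

    ``scop`` maps gene -> 4-tuple (class, fold, superfamily, family).
    Returns 0 for no shared level and None (missing) when either gene lacks
    SCOP data; such pairs are skipped when fitting the structural baseline.
    """
    g1, g2 = tuple(pair)
    l1 = scop.get(g1)
    l2 = scop.get(g2)
    if l1 is None or l2 is None:
        return None
    depth = 0
    for a, b in zip(l1, l2):
        if a == b:
            depth += 1
        else:
            break
    return depth


def information_centrality_matrix(net):
    """Pairwise information matrix I(i,j) for all node pairs.

    Stephenson-Zelen construction: C = (D - A + J)^-1 over the connected
    graph (the all-ones matrix J removes the Laplacian's singularity);
    I(i,j) = 1 / (c_ii + c_jj - 2 c_ij), symmetric and positive.

    Returns ``(nodes, matrix)`` with nodes sorted.
    """
    import networkx as nx

    if not nx.is_connected(net):
        raise ValueError("information centrality requires a connected network")
    nodes = sorted(net.nodes())
    A = nx.to_numpy_array(net, nodelist=nodes, dtype=float)
    D = np.diag(A.sum(axis=1))
    C = np.linalg.inv(D - A + np.ones_like(A))
    diag = np.diag(C)
    denom = diag[:, None] + diag[None, :] - 2 * C
    with np.errstate(divide="ignore"):
        info = 1.0 / denom
    np.fill_diagonal(info, 0.0)
    return nodes, info


def binodal_information_centrality(net, pair):
    """I(i, j) for one pair (see :func:`information_centrality_matrix`)."""
    g1, g2 = tuple(pair)
    if g1 == g2:
        raise ValueError("pair must be two distinct genes")
    nodes, info = information_centrality_matrix(net)
    idx = {g: i for i, g in enumerate(nodes)}
    if g1 not in idx or g2 not in idx:
        raise KeyError(f"gene(s) not in network: {set(pair) - set(idx)}")
    return float(info[idx[g1], idx[g2]])


def fit_baseline_model(
    train_values, train_labels, test_values=None, test_labels=None
):
    """Univariate logistic regression baseline.

    Fit on the source species' feature values and labels; if a test set is
    given, score it (the translated-evaluation setting), otherwise score the
    training set (the within-species CV setting is handled by the caller
    splitting folds). Returns ``{"scores", "auc"}`` on the evaluated set.

    A degenerate (constant) feature cannot rank pairs: AUC 0.5 with a
    warning.
    """
    x = np.asarray(train_values, dtype=float).reshape(-1, 1)
    y = np.asarray(train_labels, dtype=int)
    if test_values is None:
        test_values, test_labels = train_values, train_labels
    xt = np.asarray(test_values, dtype=float).reshape(-1, 1)
    yt = np.asarray(test_labels, dtype=int)
    if np.ptp(x) == 0:
        warnings.warn("constant baseline feature; AUC is chance level")
        scores = np.full(len(xt), 0.5)
        return {"scores": scores, "auc": 0.5}
    lr = LogisticRegression(C=np.inf, max_iter=2000)
    lr.fit(x, y)
    scores = lr.predict_proba(xt)[:, list(lr.classes_).index(1)]
    return {"scores": scores, "auc": float(roc_auc_score(yt, scores))}
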
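"""Classifiers, cross-validation and the end-to-end translation pipeline.

The core algorithm: compute connectivity profiles independently for a
source and a target species, translate (normalize) each species' profiles
onto a common scale, train a classifier on the source species' SL/NSL
labels, and apply it to the target species' pairs. The classifier's class-1
probability is the score in [0, 1]: 0 means predicted non-SL, 1 predicted
SL.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import dataset, features, translate
from .dataset import FEATURE_COLUMNS

__all__ = [
    "SLModel",
    "train",
    "score",
    "cross_validate",
    "feature_importance",
    "sinatra_pipeline",
]

logger = logging.getLogger(__name__)

ALGORITHMS = ("random_forest", "logistic_regression")


@dataclass
class SLModel:
    """A fitted SL classifier plus the provenance needed to reuse it."""

    algorithm: str
    estimator: object
    feature_columns: list
    metadata: dict = field(default_factory=dict)


def _make_estimator(algorithm, seed, n_trees=100):
    if algorithm == "random_forest":
        return RandomForestClassifier(
            n_estimators=n_trees, random_state=int(seed), n_jobs=1
        )
    if algorithm == "logistic_regression":
        # plain (unregularized) logistic regression
        return LogisticRegression(C=np.inf, max_iter=2000)
    raise ValueError(f"algorithm must be one of {ALGORITHMS}, got {algorithm!r}")


def _xy(feature_table):
    labeled = feature_table[feature_table["label"].isin(["SL", "NSL"])]
    X = labeled[FEATURE_COLUMNS].to_numpy(dtype=float)
    y = (labeled["label"] == "SL").to_numpy(dtype=int)
    return X, y


def train(feature_table, algorithm="random_forest", seed=0, n_trees=100, metadata=None):
    """Fit a classifier on the SL/NSL rows of a feature table.

    Random forest uses 100 trees by default; other hyperparameters are the
    scikit-learn defaults, pinned in the model metadata.
    """
    X, y = _xy(feature_table)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both SL and NSL rows")
    est = _make_estimator(algorithm, seed, n_trees)
    est.fit(X, y)
    meta = {
        "algorithm": algorithm,
        "seed": int(seed),
        "n_trees": n_trees if algorithm == "random_forest" else None,
        "n_sl": int(y.sum()),
        "n_nsl": int(len(y) - y.sum()),
    }
    if metadata:
        meta.update(metadata)
    return SLModel(algorithm, est, list(FEATURE_COLUMNS), meta)


def score(model, feature_table):
    """Score pairs: per-pair probability of the SL class.

    Returns a DataFrame ``gene1, gene2, score`` carrying the model metadata
    in ``attrs["provenance"]``.
    """
    missing = [c for c in model.feature_columns if c not in feature_table.columns]
    extra = [
        c
        for c in feature_table.columns
        if c not in model.feature_columns + ["gene1", "gene2", "label"]
    ]
    if missing or extra:
        raise ValueError(
            f"feature schema mismatch: missing={missing} extra={extra}"
        )
    X = feature_table[model.feature_columns].to_numpy(dtype=float)
    proba = model.estimator.predict_proba(X)
    sl_col = list(model.estimator.classes_).index(1)
    out = feature_table[["gene1", "gene2"]].copy()
    out["score"] = proba[:, sl_col]
    out.attrs["provenance"] = dict(model.metadata)
    return out


def cross_validate(
    feature_table, algorithm="random_forest", k=5, mode="train80_test20", seed=0
):
    """Stratified k-fold cross-validation; returns per-fold AUCs and mean.

    ``train80_test20`` is standard k-fold (train on k-1 folds). The
    alternative ``train20_test80`` trains on a single fold and tests on the
    rest.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if mode not in ("train80_test20", "train20_test80"):
        raise ValueError(f"unknown CV mode {mode!r}")
    X, y = _xy(feature_table)
    if len(np.unique(y)) < 2:
        raise ValueError("cross-validation needs both classes")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed))
    aucs = []
    for fold, (big, small) in enumerate(skf.split(X, y)):
        train_idx, test_idx = (
            (big, small) if mode == "train80_test20" else (small, big)
        )
        if len(np.unique(y[test_idx])) < 2 or len(np.unique(y[train_idx])) < 2:
            raise ValueError(f"fold {fold} lost a class; too few labeled pairs")
        est = _make_estimator(algorithm, seed + fold)
        est.fit(X[train_idx], y[train_idx])
        sl_col = list(est.classes_).index(1)
        p = est.predict_proba(X[test_idx])[:, sl_col]
        aucs.append(roc_auc_score(y[test_idx], p))
    return {"fold_aucs": aucs, "mean_auc": float(np.mean(aucs)), "k": k, "mode": mode}


def feature_importance(model):
    """Gini importances of a random-forest model (sum to 1)."""
    if model.algorithm != "random_forest":
        raise ValueError("Gini importance is defined for random forests only")
    return pd.Series(
        model.estimator.feature_importances_, index=model.feature_columns
    )


def compute_profiles(net, snn_mode="adjacent_to_neither"):
    """Raw node and pair profiles of one species (the expensive step).

    Returns ``(node_profiles, pair_profiles)``; reuse across translation
    schemes via the ``profiles`` argument of :func:`sinatra_pipeline`.
    """
    return features.node_profiles(net), features.pair_profiles(net, snn_mode=snn_mode)


def _translated_profiles(net, scheme, profiles=None):
    """Node and pair profiles of one species, translated within-species."""
    nodes, pairs = profiles if profiles is not None else compute_profiles(net)
    if isinstance(scheme, str):
        scheme = translate.TranslationScheme(scheme)
    if scheme.name == "quantile":
        return nodes.copy(), pairs.copy()  # joint normalization across species
    return translate.translate_table(nodes, pairs, scheme)


def _quantile_join(profiles_a, profiles_b):
    """Quantile-normalize matched columns of two species jointly."""
    nodes_a, pairs_a = profiles_a
    nodes_b, pairs_b = profiles_b
    nodes_a, nodes_b = nodes_a.copy(), nodes_b.copy()
    pairs_a, pairs_b = pairs_a.copy(), pairs_b.copy()
    for col in features.NODE_PARAMS:
        qa, qb = translate.quantile_normalize(
            [nodes_a[col].to_numpy(), nodes_b[col].to_numpy()]
        )
        nodes_a[col], nodes_b[col] = qa, qb
    for col in features.PAIR_PARAMS:
        qa, qb = translate.quantile_normalize(
            [pairs_a[col].to_numpy(), pairs_b[col].to_numpy()]
        )
        pairs_a[col], pairs_b[col] = qa, qb
    return (nodes_a, pairs_a), (nodes_b, pairs_b)


def sinatra_pipeline(
    source_net,
    source_sl,
    target_net,
    scheme="rank",
    algorithm="random_forest",
    seed=0,
    negative_ratio=1.0,
    target_pairs=None,
    whole_genome=False,
    extra_genes=(),
    profiles=None,
):
    """End-to-end source-to-target scoring.

    1. compute node and pair profiles for each species independently;
    2. translate each species' parameter columns within-species (or jointly
       for the quantile scheme);
    3. train a classifier on the source species' SL pairs plus
       ``negative_ratio`` times as many uniformly sampled non-SL pairs;
    4. score the target species' pairs (all pairs by default).

    ``whole_genome=True`` additionally assigns the conventional score 0 to
    requested pairs involving ``extra_genes`` absent from the target
    network, so genome-wide comparisons with homology-based methods cover
    the same pair universe.

    ``profiles``, if given, is ``{"source": (nodes, pairs), "target":
    (nodes, pairs)}`` of *raw* profiles from :func:`compute_profiles`,
    skipping their recomputation when several schemes are compared on the
    same networks.

    Returns ``(score_table, model)``.
    """
    if not source_sl:
        raise ValueError("source species has no SL labels to train on")
    if isinstance(scheme, str):
        scheme = translate.TranslationScheme(scheme)
    ss = np.random.SeedSequence(int(seed)).generate_state(4) % (2**31)
    logger.info("pipeline: computing profiles (scheme=%s)", scheme.name)
    profiles = profiles or {}
    src_profiles = _translated_profiles(source_net, scheme, profiles.get("source"))
    tgt_profiles = _translated_profiles(target_net, scheme, profiles.get("target"))
    if scheme.name == "quantile":
        src_profiles, tgt_profiles = _quantile_join(src_profiles, tgt_profiles)
    src_nodes, src_pairs = src_profiles
    tgt_nodes, tgt_pairs = tgt_profiles

    negatives = dataset.sample_negatives(
        source_net, source_sl, negative_ratio, int(ss[0])
    )
    labels = {p: "SL" for p in source_sl}
    labels.update({p: "NSL" for p in negatives})
    train_table = dataset.assemble_features(
        src_nodes, src_pairs, list(labels), labels=labels, shuffle_seed=int(ss[1])
    )
    logger.info("pipeline: training %s on %d pairs", algorithm, len(train_table))
    mdl = train(
        train_table,
        algorithm=algorithm,
        seed=int(ss[2]),
        metadata={
            "source_species": source_net.graph.get("species"),
            "target_species": target_net.graph.get("species"),
            "scheme": scheme.name,
            "scheme_seed": scheme.seed,
            "pipeline_seed": int(seed),
            "negative_ratio": negative_ratio,
        },
    )

    in_net_pairs = None
    out_pairs = []
    if target_pairs is not None:
        target_pairs = [frozenset(p) for p in target_pairs]
        in_net_pairs = [p for p in target_pairs if all(g in target_net for g in p)]
        out_pairs = [p for p in target_pairs if p not in set(in_net_pairs)]
        if out_pairs and not whole_genome:
            raise KeyError(
                f"{len(out_pairs)} requested pairs involve genes outside the "
                "target network; pass whole_genome=True to score them as 0"
            )
        if out_pairs:
            logger.info(
                "whole-genome mode: %d pairs with off-network genes scored 0",
                len(out_pairs),
            )
    score_table_input = dataset.assemble_features(
        tgt_nodes,
        tgt_pairs,
        in_net_pairs
        if in_net_pairs is not None
        else [frozenset((a, b)) for a, b in zip(tgt_pairs["gene1"], tgt_pairs["gene2"])],
        shuffle_seed=int(ss[3]),
    )
    scores = score(mdl, score_table_input)
    if out_pairs:
        zero_rows = pd.DataFrame(
            [(min(p), max(p), 0.0) for p in out_pairs],
            columns=["gene1", "gene2", "score"],
        )
        prov = scores.attrs.get("provenance", {})
        scores = pd.concat([scores, zero_rows], ignore_index=True)
        scores.attrs["provenance"] = prov
    return scores, mdl
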
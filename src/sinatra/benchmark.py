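"""End-to-end evaluation of the pipeline on the synthetic benchmark.

Shared by the test suite and the acceptance script: generates the
two-species benchmark, computes connectivity profiles once, runs the
translated and untranslated pipelines, the ablation experiment, the
comparison baselines and the permuted-label control, and collects the
resulting AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import baselines as bl
from . import dataset, evalx, model, netio, synthgen, translate

__all__ = ["BenchmarkRun", "run_benchmark", "baseline_aucs", "permuted_label_cv_auc"]

EVAL_NEGATIVE_RATIO = 5.0


@dataclass
class BenchmarkRun:
    """Benchmark bundle plus cached profiles, eval pairs and AUCs."""

    bench: synthgen.Benchmark
    seed: int
    profiles: dict
    eval_pairs: list
    labels: np.ndarray
    scores: dict = field(default_factory=dict)  # scheme -> np.ndarray
    aucs: dict = field(default_factory=dict)  # scheme -> float

    @property
    def source_net(self):
        return self.bench.source_net

    @property
    def target_net(self):
        return self.bench.target_net


def run_benchmark(spec=None, seed=0, schemes=("rank", "raw")):
    """Generate the benchmark and score target evaluation pairs per scheme.

    Evaluation pairs are every planted target SL pair plus
    ``EVAL_NEGATIVE_RATIO`` times as many uniformly sampled non-SL pairs.
    """
    spec = spec or synthgen.BenchmarkSpec()
    bench = synthgen.generate_benchmark(spec)
    src, tgt = bench.source_net, bench.target_net
    profiles = {
        "source": model.compute_profiles(src),
        "target": model.compute_profiles(tgt),
    }
    negs = dataset.sample_negatives(
        tgt, bench.target_sl, EVAL_NEGATIVE_RATIO, seed + 101
    )
    eval_pairs = sorted(bench.target_sl | negs, key=lambda p: tuple(sorted(p)))
    y = np.array([p in bench.target_sl for p in eval_pairs], dtype=int)
    run = BenchmarkRun(bench, seed, profiles, eval_pairs, y)
    for scheme in schemes:
        table, _ = model.sinatra_pipeline(
            src,
            bench.source_sl,
            tgt,
            scheme=scheme,
            seed=seed,
            target_pairs=eval_pairs,
            profiles=profiles,
        )
        s = table["score"].to_numpy()
        run.scores[scheme] = s
        run.aucs[scheme] = evalx.roc_auc(s, y)
    return run


def ablation_auc(run, keep_fraction=0.5, scheme="rank"):
    """Cross-species AUC after ablating the target network's edges.

    The target is re-pruned after ablation; evaluation keeps the pairs
    whose genes survive.
    """
    bench = run.bench
    ablated = netio.ablate_edges(bench.target_net, keep_fraction, run.seed + 301)
    surviving = set(ablated.nodes())
    pairs = [p for p in run.eval_pairs if all(g in surviving for g in p)]
    y = np.array([p in bench.target_sl for p in pairs], dtype=int)
    table, _ = model.sinatra_pipeline(
        bench.source_net,
        bench.source_sl,
        ablated,
        scheme=scheme,
        seed=run.seed,
        target_pairs=pairs,
        profiles={"source": run.profiles["source"]},
    )
    return evalx.roc_auc(table["score"].to_numpy(), y), len(pairs)


def baseline_aucs(run):
    """AUC of every comparison predictor on the benchmark eval pairs.

    Homology transfer and bi-nodal information centrality are evaluated
    directly in the target species; GO, PFam and SCOP similarities are
    logistic models fitted on the source species' labeled pairs and applied
    to the target. SCOP is evaluated on the subset of pairs with structure
    data for both genes.
    """
    bench = run.bench
    y = run.labels
    out = {}

    # homology transfer (whole-genome convention: no ortholog -> 0)
    hs = np.array(
        [
            bl.homology_transfer_score(
                tuple(p), bench.source_sl, bench.orthology, whole_genome=True
            )
            for p in run.eval_pairs
        ],
        dtype=float,
    )
    out["homology_transfer"] = evalx.roc_auc(hs, y)

    # source-trained univariate logistic baselines
    src_negs = dataset.sample_negatives(
        bench.source_net, bench.source_sl, 1.0, run.seed + 401
    )
    src_pairs = sorted(bench.source_sl | src_negs, key=lambda p: tuple(sorted(p)))
    ys = np.array([p in bench.source_sl for p in src_pairs], dtype=int)

    def univariate(value_fn, name, skip_missing=False):
        xs = np.array([value_fn(tuple(p)) for p in src_pairs], dtype=float)
        xt = np.array([value_fn(tuple(p)) for p in run.eval_pairs], dtype=float)
        if skip_missing:
            keep_s = ~np.isnan(xs)
            keep_t = ~np.isnan(xt)
            if ys[keep_s].min() == ys[keep_s].max() or y[keep_t].min() == y[keep_t].max():
                out[name] = 0.5
                return
            res = bl.fit_baseline_model(xs[keep_s], ys[keep_s], xt[keep_t], y[keep_t])
        else:
            res = bl.fit_baseline_model(xs, ys, xt, y)
        out[name] = res["auc"]

    univariate(
        lambda p: bl.functional_similarity(p, bench.go_source)
        if p[0].startswith("s")
        else bl.functional_similarity(p, bench.go_target),
        "go_overlap",
    )
    univariate(
        lambda p: bl.domain_overlap(p, bench.pfam_source)
        if p[0].startswith("s")
        else bl.domain_overlap(p, bench.pfam_target),
        "pfam_overlap",
    )

    def scop_value(p):
        scop = bench.scop_source if p[0].startswith("s") else bench.scop_target
        v = bl.structural_similarity(p, scop)
        return np.nan if v is None else float(v)

    univariate(scop_value, "scop_similarity", skip_missing=True)

    # bi-nodal information centrality: within-target univariate model
    nodes, info = bl.information_centrality_matrix(bench.target_net)
    idx = {g: i for i, g in enumerate(nodes)}
    iv = np.array(
        [info[idx[min(p)], idx[max(p)]] for p in run.eval_pairs], dtype=float
    )
    out["information_centrality"] = bl.fit_baseline_model(iv, y)["auc"]
    return out


def permuted_label_cv_auc(run, n_permutations=10, algorithm="random_forest"):
    """Mean within-source CV AUC after permuting SL/NSL labels.

    Averaging over several independent permutations keeps the control's
    sampling noise well inside the expected chance band.
    """
    bench = run.bench
    scheme = translate.TranslationScheme("rank", run.seed)
    nodes_t, pairs_t = translate.translate_table(*run.profiles["source"], scheme)
    negs = dataset.sample_negatives(
        bench.source_net, bench.source_sl, 1.0, run.seed + 501
    )
    labels = {p: "SL" for p in bench.source_sl}
    labels.update({p: "NSL" for p in negs})
    table = dataset.assemble_features(
        nodes_t, pairs_t, list(labels), labels=labels, shuffle_seed=run.seed + 502
    )
    rng = np.random.default_rng(run.seed + 503)
    aucs = []
    for k in range(n_permutations):
        permuted = table.copy()
        permuted["label"] = rng.permutation(permuted["label"].to_numpy())
        cv = model.cross_validate(
            permuted, algorithm=algorithm, k=5, seed=run.seed + 504 + k
        )
        aucs.append(cv["mean_auc"])
    return float(np.mean(aucs)), len(table)


def within_species_cv_aucs(run, scheme="raw"):
    """Within-source 5-fold CV AUC for random forest and logistic models."""
    bench = run.bench
    nodes, pairs = run.profiles["source"]
    if scheme != "raw":
        nodes, pairs = translate.translate_table(
            nodes, pairs, translate.TranslationScheme(scheme, run.seed)
        )
    negs = dataset.sample_negatives(
        bench.source_net, bench.source_sl, 1.0, run.seed + 601
    )
    labels = {p: "SL" for p in bench.source_sl}
    labels.update({p: "NSL" for p in negs})
    table = dataset.assemble_features(
        nodes, pairs, list(labels), labels=labels, shuffle_seed=run.seed + 602
    )
    return {
        alg: model.cross_validate(table, algorithm=alg, k=5, seed=run.seed + 603)[
            "mean_auc"
        ]
        for alg in ("random_forest", "logistic_regression")
    }, len(table)
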
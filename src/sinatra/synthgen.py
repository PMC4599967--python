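"""Synthetic two-species benchmark with planted, connectivity-linked SL.

The generator emulates the statistical structure the translation method
exploits, without attempting to match any real interactome exactly:

- a *source* PPI network grown by duplication-divergence (PPI-like
  heavy-tailed degrees), with protein complexes overlaid as dense subgraphs
  so that complex co-membership is visible in connectivity (shared
  neighbors, communicability);
- a *target* network derived from the source by node deletion, node
  duplication, edge rewiring and edge subsampling, so the two species share
  ancestry (a many-to-many orthology map) but differ in size and density —
  the regime in which raw parameter values stop being comparable and
  translation matters;
- SL labels planted per species by mechanism: within-complex pairs,
  "parallel" same-pathway non-adjacent pairs with shared neighbors, and
  unstructured "other" pairs, plus a label-noise fraction;
- annotation fixtures (GO, PFam, SCOP, pathways, complexes), expression
  presence tables and a co-mutation table planted preferentially on non-SL
  pairs, so every baseline and filter has signal to find.

Everything is deterministic under ``BenchmarkSpec.seed``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import netio
from .baselines import OrthologyMap

__all__ = [
    "BenchmarkSpec",
    "Benchmark",
    "generate_species_pair",
    "plant_sl_labels",
    "generate_annotations",
    "generate_benchmark",
    "write_fixture_dir",
]


@dataclass(frozen=True)
class BenchmarkSpec:
    """Study conditions for the synthetic benchmark (defaults = benchmark)."""

    n_nodes_source: int = 800
    n_nodes_target: int = 500
    generator: str = "duplication_divergence"
    dd_retention: float = 0.65  # per-edge inheritance prob at duplication
    dd_anchor_p: float = 0.9  # prob of an edge to the duplicated parent
    # source -> target divergence
    rewire_fraction: float = 0.10
    duplication_rate: float = 0.05
    target_edge_keep: float = 0.6
    observation_bias: float = 1.0  # degree-rank exponent of edge detectability
    # complexes and pathways
    n_complexes: int = 40
    complex_size_range: tuple = (8, 12)
    complex_edge_p: float = 0.85
    n_pathways: int = 20
    pathway_coverage: float = 0.6  # fraction of non-complex genes in pathways
    pathway_edge_p: float = 0.02  # extra within-pathway ancestor edges
    # SL planting
    n_sl: int = 300
    mechanism_mix: tuple = (0.5, 0.3, 0.2)  # within_complex, parallel, other
    parallel_min_shared: int = 1
    # centrality-lethality: the top degree-rank fraction of genes is
    # essential; essential genes cannot appear in SL pairs (SL requires
    # both genes to be individually nonessential)
    essential_fraction: float = 0.25
    sl_degree_bias: float = 2.5  # exponent of the degree-rank study bias
    label_noise: float = 0.02
    # annotations
    go_vocab: int = 200
    go_terms_per_gene: float = 3.0
    annotation_coverage: float = 0.8
    ortholog_share: float = 0.7
    pfam_vocab: int = 150
    pfam_per_gene: float = 1.5
    scop_coverage: float = 0.5
    complex_domain_p: float = 0.3
    # expression / co-mutation
    n_contexts: int = 5
    expression_p: float = 0.7
    comut_n_pairs: int = 2000
    # fraction of co-mutation rows on non-SL pairs; the residue models
    # annotation/sequencing noise (a true SL pair cannot be tolerated
    # homozygously co-mutated)
    comut_nonsl_enrichment: float = 0.98
    comut_n_patients: int = 200
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.mechanism_mix) - 1.0) > 1e-9:
            raise ValueError("mechanism_mix must sum to 1")
        for r in (
            self.dd_retention,
            self.rewire_fraction,
            self.duplication_rate,
            self.target_edge_keep,
            self.label_noise,
            self.annotation_coverage,
            self.ortholog_share,
        ):
            if not 0 <= r <= 1:
                raise ValueError(f"rate {r} outside [0, 1]")


@dataclass
class Benchmark:
    """Everything the pipeline, baselines and filters consume."""

    spec: BenchmarkSpec
    source_net: nx.Graph
    target_net: nx.Graph
    orthology: OrthologyMap
    orthology_pairs: list
    source_sl: set
    target_sl: set
    source_mechanisms: dict
    target_mechanisms: dict
    complexes_source: dict
    complexes_target: dict
    pathways_source: dict
    pathways_target: dict
    go_source: dict
    go_target: dict
    pfam_source: dict
    pfam_target: dict
    scop_source: dict
    scop_target: dict
    expression_target: pd.DataFrame
    comutation: pd.DataFrame
    records_source: pd.DataFrame = field(default=None)
    records_target: pd.DataFrame = field(default=None)


def _rngs(seed, n):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _dd_graph(n, retention, anchor_p, rng):
    """Duplication-divergence growth from a seed clique."""
    g = nx.complete_graph(5)
    next_id = 5
    while g.number_of_nodes() < n:
        u = int(rng.choice(list(g.nodes())))
        v = next_id
        next_id += 1
        g.add_node(v)
        for w in list(g[u]):
            if rng.random() < retention:
                g.add_edge(v, w)
        if rng.random() < anchor_p or g.degree(v) == 0:
            g.add_edge(v, u)
    return g


def _ba_graph(n, rng):
    return nx.barabasi_albert_graph(n, 3, seed=int(rng.integers(2**31)))


def _assign_complexes(genes, spec, rng):
    """Disjoint complexes over a sample of genes: {complex_id: set(genes)}."""
    lo, hi = spec.complex_size_range
    pool = list(genes)
    rng.shuffle(pool)
    complexes = {}
    cursor = 0
    for cid in range(spec.n_complexes):
        size = int(rng.integers(lo, hi + 1))
        members = pool[cursor : cursor + size]
        if len(members) < lo:
            break
        complexes[f"CPLX{cid:03d}"] = set(members)
        cursor += size
    return complexes


def generate_species_pair(spec):
    """Generate the source network, a diverged target, and their orthology.

    Returns ``(source_net, target_net, orthology_pairs, complexes_source,
    complexes_target, pathways_source, pathways_target, target_net_true,
    complexes_target_true, pathways_target_true)``. Gene ids are ``s<k>`` /
    ``t<k>`` with matching ancestor index k; duplicated target genes get a
    ``d`` suffix, making the orthology many-to-many. Complexes and pathways
    are ancestral: they shape the source network's edges (dense complexes,
    mildly enriched within-pathway contacts) before the target diverges,
    and the target inherits membership through orthology.

    ``target_net`` is the *observed* interactome — an edge subsample of the
    complete diverged network ``target_net_true``. SL labels should be
    planted on the true network (biology does not depend on assay
    coverage); profiles are computed on the observed one.
    """
    rng_net, rng_cplx, rng_div = _rngs(spec.seed, 3)

    if spec.generator == "duplication_divergence":
        base = _dd_graph(spec.n_nodes_source, spec.dd_retention, spec.dd_anchor_p, rng_net)
    elif spec.generator == "barabasi_like":
        base = _ba_graph(spec.n_nodes_source, rng_net)
    else:
        raise ValueError(f"unknown generator {spec.generator!r}")
    src = nx.relabel_nodes(base, {v: f"s{v:04d}" for v in base.nodes()})

    complexes_src = _assign_complexes(sorted(src.nodes()), spec, rng_cplx)
    for members in complexes_src.values():
        for a, b in itertools.combinations(sorted(members), 2):
            if rng_cplx.random() < spec.complex_edge_p:
                src.add_edge(a, b)
    pathways_src = _assign_pathways(src, complexes_src, spec, rng_cplx)
    for genes in pathways_src.values():
        for a, b in itertools.combinations(sorted(genes), 2):
            if not src.has_edge(a, b) and rng_cplx.random() < spec.pathway_edge_p:
                src.add_edge(a, b)
    src.graph["species"] = "source"
    src = netio.largest_component(src)
    if src.number_of_nodes() < 2:
        raise ValueError("generator parameters yielded an empty component")
    src_node_set = set(src.nodes())
    complexes_src = {
        cid: members & src_node_set
        for cid, members in complexes_src.items()
        if len(members & src_node_set) >= 2
    }
    pathways_src = {
        pid: genes & src_node_set
        for pid, genes in pathways_src.items()
        if len(genes & src_node_set) >= 2
    }

    # --- derive the target species ---
    src_nodes = sorted(src.nodes())
    keep = sorted(
        rng_div.choice(src_nodes, size=min(spec.n_nodes_target, len(src_nodes)), replace=False)
    )
    tgt = nx.Graph(src.subgraph(keep))
    tgt = nx.relabel_nodes(tgt, {g: "t" + g[1:] for g in tgt.nodes()})
    ortho = [(g, "t" + g[1:]) for g in keep]

    # duplications: a copy inherits each edge independently
    dup_candidates = sorted(tgt.nodes())
    n_dup = int(round(spec.duplication_rate * len(dup_candidates)))
    for g in rng_div.choice(dup_candidates, size=n_dup, replace=False):
        new = g + "d"
        tgt.add_node(new)
        for w in list(tgt[g]):
            if rng_div.random() < spec.dd_retention:
                tgt.add_edge(new, w)
        if tgt.degree(new) == 0:
            tgt.add_edge(new, g)
        ortho.append(("s" + g[1:].rstrip("d"), new))

    # rewiring: replace a fraction of edges with uniform non-edges
    edges = sorted(tuple(sorted(e)) for e in tgt.edges())
    n_rewire = int(round(spec.rewire_fraction * len(edges)))
    to_remove = rng_div.choice(len(edges), size=n_rewire, replace=False)
    nodes_t = sorted(tgt.nodes())
    for k in to_remove:
        tgt.remove_edge(*edges[k])
        while True:
            a, b = rng_div.choice(nodes_t, size=2, replace=False)
            if a != b and not tgt.has_edge(a, b):
                tgt.add_edge(a, b)
                break

    # the biological target network is now complete; the *observed* target
    # interactome is an edge subsample of it (incomplete experimental
    # coverage, the regime the translation step must survive). Detection is
    # degree-biased: interactions among well-connected (well-studied) genes
    # are more likely to have been assayed, mirroring literature bias in
    # curated interaction databases.
    tgt_true = tgt
    tgt_true.graph["species"] = "target"
    edges = sorted(tuple(sorted(e)) for e in tgt_true.edges())
    n_keep = int(round(spec.target_edge_keep * len(edges)))
    deg = dict(tgt_true.degree())
    rank = {
        g: (r + 1) / tgt_true.number_of_nodes()
        for r, g in enumerate(sorted(tgt_true.nodes(), key=lambda g: (deg[g], g)))
    }
    w = np.array(
        [(rank[a] * rank[b]) ** spec.observation_bias for a, b in edges]
    )
    kept = rng_div.choice(len(edges), size=n_keep, replace=False, p=w / w.sum())
    tgt2 = nx.Graph()
    tgt2.add_nodes_from(tgt_true.nodes())
    tgt2.add_edges_from(edges[k] for k in kept)
    tgt2.graph["species"] = "target"
    tgt = netio.largest_component(tgt2)

    tgt_nodes = set(tgt.nodes())
    ortho = sorted((s, t) for s, t in ortho if s in src and t in tgt_nodes)

    def map_groups(groups, universe):
        out = {}
        for gid, members in groups.items():
            mapped = {"t" + g[1:] for g in members} & universe
            mapped |= {"t" + g[1:] + "d" for g in members} & universe
            if len(mapped) >= 2:
                out[gid] = mapped
        return out

    return (
        src,
        tgt,
        ortho,
        complexes_src,
        map_groups(complexes_src, tgt_nodes),
        pathways_src,
        map_groups(pathways_src, tgt_nodes),
        tgt_true,
        map_groups(complexes_src, set(tgt_true.nodes())),
        map_groups(pathways_src, set(tgt_true.nodes())),
    )


def _assign_pathways(net, complexes, spec, rng):
    """{pathway_id: set(genes)}: complexes nest in pathways + random genes."""
    pathways = {f"PATH{p:03d}": set() for p in range(spec.n_pathways)}
    pids = sorted(pathways)
    for i, cid in enumerate(sorted(complexes)):
        pathways[pids[i % len(pids)]] |= complexes[cid] & set(net.nodes())
    in_complex = set().union(*complexes.values()) if complexes else set()
    for g in sorted(set(net.nodes()) - in_complex):
        if rng.random() < spec.pathway_coverage:
            pathways[pids[int(rng.integers(len(pids)))]].add(g)
    return {p: genes for p, genes in pathways.items() if len(genes) >= 2}


def plant_sl_labels(net, complexes, pathways, n_sl, spec, seed):
    """Plant SL pairs by mechanism mix; returns (sl_set, {pair: mechanism}).

    SL denotes functional redundancy, not physical contact, so planted SL
    pairs are non-adjacent wherever the pool allows it, and both genes must
    be individually nonessential — the top ``essential_fraction`` of the
    degree ranking is excluded (centrality-lethality rule). Mechanisms:
    ``within_complex`` (both genes in one complex, preferring co-members
    without a direct physical edge), ``parallel`` (same pathway, not
    adjacent, >= ``parallel_min_shared`` shared neighbors, not within one
    complex) and ``other`` (random). Within every
    mechanism pool, pairs are drawn with probability proportional to the
    product of the genes' within-species degree ranks raised to
    ``sl_degree_bias`` — mimicking the study bias of curated interaction
    databases, where well-connected (well-studied) genes dominate the
    labeled SL set. Because the bias is rank-based it applies identically
    in species of different density. ``label_noise`` replaces that fraction
    of planted pairs with uniform random pairs tagged ``noise``.
    """
    rng = np.random.default_rng(seed)
    nodes = sorted(net.nodes())
    deg_rank = {
        g: (r + 1) / len(nodes)
        for r, g in enumerate(sorted(nodes, key=lambda g: (net.degree(g), g)))
    }
    # centrality-lethality rule: the most connected genes are essential and
    # by definition excluded from synthetic-lethal pairs
    essential = {g for g, r in deg_rank.items() if r > 1 - spec.essential_fraction}

    def eligible(pair):
        return not (set(pair) & essential)

    def pool_weights(pool):
        w = np.array(
            [
                (deg_rank[min(p)] * deg_rank[max(p)]) ** spec.sl_degree_bias
                for p in pool
            ]
        )
        return w / w.sum()
    n_within = int(round(spec.mechanism_mix[0] * n_sl))
    n_parallel = int(round(spec.mechanism_mix[1] * n_sl))
    n_other = n_sl - n_within - n_parallel

    all_within = {
        frozenset((a, b))
        for members in complexes.values()
        for a, b in itertools.combinations(sorted(members & set(net.nodes())), 2)
    }
    all_within = {p for p in all_within if eligible(p)}
    nonadj = {p for p in all_within if not net.has_edge(*tuple(p))}
    # prefer non-adjacent co-members; fall back to adjacent ones if scarce
    pool_set = nonadj if len(nonadj) >= n_within else all_within
    within_pool = sorted(pool_set, key=lambda p: tuple(sorted(p)))
    if len(within_pool) < n_within:
        raise ValueError(
            f"only {len(within_pool)} within-complex pairs for {n_within} SL"
        )
    chosen = set(
        within_pool[i]
        for i in rng.choice(
            len(within_pool), size=n_within, replace=False, p=pool_weights(within_pool)
        )
    )
    mechanisms = {p: "within_complex" for p in chosen}

    complex_pairs = all_within
    parallel_pool = []
    for genes in pathways.values():
        members = sorted(genes & set(net.nodes()))
        for a, b in itertools.combinations(members, 2):
            p = frozenset((a, b))
            if p in complex_pairs or p in chosen or net.has_edge(a, b):
                continue
            if not eligible(p):
                continue
            shared = len(set(net[a]) & set(net[b]))
            if shared >= spec.parallel_min_shared:
                parallel_pool.append(p)
    parallel_pool = sorted(set(parallel_pool), key=lambda p: tuple(sorted(p)))
    if len(parallel_pool) < n_parallel:
        raise ValueError(
            f"only {len(parallel_pool)} eligible parallel pairs for {n_parallel} SL"
        )
    for i in rng.choice(
        len(parallel_pool), size=n_parallel, replace=False, p=pool_weights(parallel_pool)
    ):
        chosen.add(parallel_pool[i])
        mechanisms[parallel_pool[i]] = "parallel"

    def random_pairs(k, exclude, biased=True):
        # rejection sampling keeps the degree-rank bias without enumerating
        # every pair
        out = set()
        while len(out) < k:
            a, b = rng.choice(nodes, size=2, replace=False)
            p = frozenset((a, b))
            if a == b or p in exclude or p in out or not eligible(p):
                continue
            if biased:
                accept = (deg_rank[a] * deg_rank[b]) ** spec.sl_degree_bias
                if rng.random() > accept:
                    continue
            out.add(p)
        return out

    for p in random_pairs(n_other, chosen):
        chosen.add(p)
        mechanisms[p] = "other"

    n_noise = int(round(spec.label_noise * len(chosen)))
    if n_noise:
        ordered = sorted(chosen, key=lambda p: tuple(sorted(p)))
        drop_idx = rng.choice(len(ordered), size=n_noise, replace=False)
        for i in drop_idx:
            p = ordered[i]
            chosen.discard(p)
            mechanisms.pop(p, None)
        for p in random_pairs(n_noise, chosen, biased=False):
            chosen.add(p)
            mechanisms[p] = "noise"
    return chosen, mechanisms


def _hierarchy_lineage(rng):
    """Random SCOP-like 4-level lineage (class/fold/superfamily/family)."""
    c = int(rng.integers(1, 6))
    f = int(rng.integers(1, 5))
    s = int(rng.integers(1, 4))
    fam = int(rng.integers(1, 4))
    return (f"c{c}", f"c{c}.f{f}", f"c{c}.f{f}.s{s}", f"c{c}.f{f}.s{s}.fa{fam}")


def generate_annotations(
    source_net,
    target_net,
    orthology_pairs,
    complexes_source,
    complexes_target,
    pathways_source,
    pathways_target,
    sl_source,
    sl_target,
    spec,
    seed,
):
    """GO/PFam/SCOP annotation maps, expression presence and co-mutations.

    Orthologs share ancestral annotations with probability
    ``spec.ortholog_share`` (GO random terms) / high retention (PFam, SCOP);
    complex and pathway membership contribute shared terms, giving the
    functional-similarity baseline genuine but imperfect signal.
    Co-mutations are planted preferentially on non-SL target pairs so the
    co-mutation filter removes mostly true negatives.
    """
    rng_go, rng_dom, rng_scop, rng_expr, rng_comut = _rngs(seed, 5)

    tgt2src = {}
    for s, t in orthology_pairs:
        tgt2src.setdefault(t, []).append(s)

    def complex_of(gene, complexes):
        for cid, members in complexes.items():
            if gene in members:
                return cid
        return None

    def pathway_of(gene, pathways):
        for pid, members in pathways.items():
            if gene in members:
                return pid
        return None

    # --- GO: ancestral random terms on source genes, inherited by orthologs
    go_source, go_target = {}, {}
    ancestral = {}
    for g in sorted(source_net.nodes()):
        if rng_go.random() > spec.annotation_coverage:
            continue
        k = rng_go.poisson(spec.go_terms_per_gene)
        terms = {f"GO:{int(t):04d}" for t in rng_go.integers(0, spec.go_vocab, size=k)}
        ancestral[g] = terms
        full = set(terms) | {"biological_process"}
        cid = complex_of(g, complexes_source)
        pid = pathway_of(g, pathways_source)
        if cid:
            full.add(f"GO:{cid}")
        if pid:
            full.add(f"GO:{pid}")
        go_source[g] = full
    for g in sorted(target_net.nodes()):
        if rng_go.random() > spec.annotation_coverage:
            continue
        terms = set()
        for s in tgt2src.get(g, []):
            for t in ancestral.get(s, ()):  # inherit ancestral terms
                if rng_go.random() < spec.ortholog_share:
                    terms.add(t)
        k = rng_go.poisson(1.0)  # species-specific accretion
        terms |= {f"GO:{int(t):04d}" for t in rng_go.integers(0, spec.go_vocab, size=k)}
        full = terms | {"biological_process"}
        cid = complex_of(g, complexes_target)
        pid = pathway_of(g, pathways_target)
        if cid:
            full.add(f"GO:{cid}")
        if pid:
            full.add(f"GO:{pid}")
        go_target[g] = full

    # --- PFam: domain content is strongly conserved in orthologs
    pfam_source, pfam_target = {}, {}
    dom_anc = {}
    complex_domain = {
        cid: f"PF_{cid}" for cid in complexes_source if rng_dom.random() < spec.complex_domain_p
    }
    for g in sorted(source_net.nodes()):
        k = rng_dom.poisson(spec.pfam_per_gene)
        doms = {f"PF{int(d):04d}" for d in rng_dom.integers(0, spec.pfam_vocab, size=k)}
        cid = complex_of(g, complexes_source)
        if cid in complex_domain:
            doms.add(complex_domain[cid])
        dom_anc[g] = doms
        if doms:
            pfam_source[g] = doms
    for g in sorted(target_net.nodes()):
        doms = set()
        for s in tgt2src.get(g, []):
            doms |= {d for d in dom_anc.get(s, ()) if rng_dom.random() < 0.9}
        if not doms and rng_dom.random() < 0.5:
            doms = {f"PF{int(rng_dom.integers(0, spec.pfam_vocab)):04d}"}
        if doms:
            pfam_target[g] = doms

    # --- SCOP: sparse coverage, lineages conserved in orthologs
    scop_source, scop_target = {}, {}
    for g in sorted(source_net.nodes()):
        if rng_scop.random() < spec.scop_coverage:
            scop_source[g] = _hierarchy_lineage(rng_scop)
    for g in sorted(target_net.nodes()):
        inherited = None
        for s in tgt2src.get(g, []):
            if s in scop_source and rng_scop.random() < 0.9:
                inherited = scop_source[s]
                break
        if inherited is not None:
            scop_target[g] = inherited
        elif rng_scop.random() < spec.scop_coverage / 2:
            scop_target[g] = _hierarchy_lineage(rng_scop)

    # --- expression presence per context (target species only)
    rows = []
    for ctx in range(spec.n_contexts):
        for g in sorted(target_net.nodes()):
            rows.append((g, f"context{ctx}", int(rng_expr.random() < spec.expression_p)))
    expression = pd.DataFrame(rows, columns=["gene", "context", "detected"])

    # --- co-mutations, enriched on non-SL (and functionally uncoupled)
    # pairs: a pair tolerated homozygously co-mutated in a population is
    # evidence against redundancy, so the planted set avoids complex and
    # pathway co-membership
    nodes_t = sorted(target_net.nodes())
    sl_list = sorted(sl_target, key=lambda p: tuple(sorted(p)))
    coupled = {
        frozenset((a, b))
        for groups in (complexes_target, pathways_target)
        for members in groups.values()
        for a, b in itertools.combinations(sorted(members), 2)
    }
    comut_rows = []
    seen = set()
    while len(comut_rows) < spec.comut_n_pairs:
        if sl_list and rng_comut.random() > spec.comut_nonsl_enrichment:
            p = sl_list[int(rng_comut.integers(len(sl_list)))]
        else:
            a, b = rng_comut.choice(nodes_t, size=2, replace=False)
            p = frozenset((a, b))
            if p in sl_target or p in coupled:
                continue
        if p in seen or len(p) < 2:
            continue
        seen.add(p)
        g1, g2 = sorted(p)
        n_com = int(rng_comut.integers(1, max(2, int(0.05 * spec.comut_n_patients))))
        comut_rows.append((g1, g2, n_com, spec.comut_n_patients, "study1"))
    comutation = pd.DataFrame(
        comut_rows, columns=["gene1", "gene2", "n_comutated", "n_patients", "study"]
    )

    return {
        "go_source": go_source,
        "go_target": go_target,
        "pfam_source": pfam_source,
        "pfam_target": pfam_target,
        "scop_source": scop_source,
        "scop_target": scop_target,
        "expression_target": expression,
        "comutation": comutation,
    }


def _records(net, sl_pairs, rng):
    """BioGRID-style rows: >=1 physical row per edge plus SL rows."""
    rows = []
    for a, b in sorted(tuple(sorted(e)) for e in net.edges()):
        for _ in range(1 + rng.poisson(0.5)):
            rows.append((a, b, "Affinity Capture-MS"))
    for p in sorted(sl_pairs, key=lambda p: tuple(sorted(p))):
        g1, g2 = sorted(p)
        rows.append((g1, g2, "Synthetic Lethality"))
    return pd.DataFrame(rows, columns=netio.RECORD_COLUMNS)


def generate_benchmark(spec=None):
    """Full deterministic benchmark bundle under ``spec.seed``."""
    spec = spec or BenchmarkSpec()
    (
        src, tgt, ortho_pairs, cplx_s, cplx_t, paths_s, paths_t,
        tgt_true, cplx_t_true, paths_t_true,
    ) = generate_species_pair(spec)
    rng_rec_s, rng_rec_t = _rngs(spec.seed + 1, 2)
    n_sl_target = int(
        round(spec.n_sl * tgt.number_of_nodes() / src.number_of_nodes())
    )
    # labels are planted on each species' observed network: curated SL sets
    # and curated interactomes share the same study bias, which is why
    # within-species models fit them so well
    sl_s, mech_s = plant_sl_labels(src, cplx_s, paths_s, spec.n_sl, spec, spec.seed + 2)
    sl_t, mech_t = plant_sl_labels(tgt, cplx_t, paths_t, n_sl_target, spec, spec.seed + 3)
    ann = generate_annotations(
        src, tgt, ortho_pairs, cplx_s, cplx_t, paths_s, paths_t,
        sl_s, sl_t, spec, spec.seed + 4,
    )
    return Benchmark(
        spec=spec,
        source_net=src,
        target_net=tgt,
        orthology=OrthologyMap(ortho_pairs),
        orthology_pairs=ortho_pairs,
        source_sl=sl_s,
        target_sl=sl_t,
        source_mechanisms=mech_s,
        target_mechanisms=mech_t,
        complexes_source=cplx_s,
        complexes_target=cplx_t,
        pathways_source=paths_s,
        pathways_target=paths_t,
        records_source=_records(src, sl_s, rng_rec_s),
        records_target=_records(tgt, sl_t, rng_rec_t),
        **ann,
    )


def write_fixture_dir(bench, outdir):
    """Write every fixture in the tabular formats the readers accept."""
    import os

    os.makedirs(outdir, exist_ok=True)

    def path(name):
        return os.path.join(outdir, name)

    for tag, net, records, sl in (
        ("source", bench.source_net, bench.records_source, bench.source_sl),
        ("target", bench.target_net, bench.records_target, bench.target_sl),
    ):
        netio.write_network(net, path(f"{tag}_edges.tsv"))
        records.to_csv(path(f"{tag}_biogrid.tsv"), sep="\t", index=False, header=False)
        with open(path(f"{tag}_sl.tsv"), "w") as fh:
            for p in sorted(sl, key=lambda p: tuple(sorted(p))):
                a, b = sorted(p)
                fh.write(f"{a}\t{b}\n")

    with open(path("orthology.tsv"), "w") as fh:
        for s, t in bench.orthology_pairs:
            fh.write(f"{s}\t{t}\n")

    for tag, go, pfam, cplx, paths in (
        ("source", bench.go_source, bench.pfam_source, bench.complexes_source, bench.pathways_source),
        ("target", bench.go_target, bench.pfam_target, bench.complexes_target, bench.pathways_target),
    ):
        with open(path(f"{tag}_annotations.tsv"), "w") as fh:
            for gene in sorted(go):
                for term in sorted(go[gene]):
                    fh.write(f"{gene}\tGO\t{term}\n")
            for gene in sorted(pfam):
                for term in sorted(pfam[gene]):
                    fh.write(f"{gene}\tPFam\t{term}\n")
            for cid in sorted(cplx):
                for gene in sorted(cplx[cid]):
                    fh.write(f"{gene}\tcomplex\t{cid}\n")
            for pid in sorted(paths):
                for gene in sorted(paths[pid]):
                    fh.write(f"{gene}\tpathway\t{pid}\n")

    for tag, scop in (("source", bench.scop_source), ("target", bench.scop_target)):
        with open(path(f"{tag}_scop.tsv"), "w") as fh:
            for gene in sorted(scop):
                fh.write(gene + "\t" + "\t".join(scop[gene]) + "\n")

    bench.expression_target.to_csv(
        path("target_expression.tsv"), sep="\t", index=False, header=False
    )
    bench.comutation.to_csv(
        path("target_comutation.tsv"), sep="\t", index=False, header=False
    )
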
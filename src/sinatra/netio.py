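"""Reading, writing and basic manipulation of PPI networks.

Networks are simple undirected :class:`networkx.Graph` objects whose nodes
are opaque gene-identifier strings. Graphs built here carry a
``graph["species"]`` tag and are pruned to a single connected component
before any connectivity parameter is computed, because eccentricity and
shortest-path based parameters are undefined across components.

Interaction records (the raw rows of a BioGRID-style table) are kept
separately from the derived graph: duplicate and multi-evidence rows
collapse to one edge, but the raw row count per gene is the "popularity"
denominator used to check that predictions are not driven by how often a
gene has been studied.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

__all__ = [
    "GENETIC_SYSTEMS",
    "read_network",
    "write_network",
    "largest_component",
    "ablate_edges",
    "network_density",
    "popularity_stats",
    "sl_pairs_from_records",
]

#: BioGRID experimental-system names that denote genetic (not physical)
#: interactions. Rows with these tags never become PPI edges; they are kept
#: in the interaction records and may feed SL label sets.
GENETIC_SYSTEMS = frozenset(
    {
        "Synthetic Lethality",
        "Synthetic Growth Defect",
        "Synthetic Rescue",
        "Negative Genetic",
        "Positive Genetic",
        "Phenotypic Enhancement",
        "Phenotypic Suppression",
        "Dosage Lethality",
        "Dosage Rescue",
        "Dosage Growth Defect",
    }
)

RECORD_COLUMNS = ["gene_a", "gene_b", "system"]


class MalformedRowError(ValueError):
    """A row of an input table could not be parsed."""


def _parse_rows(path, fmt):
    """Yield (gene_a, gene_b, system) tuples; raise with line numbers."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if fmt == "tsv2col":
                if len(parts) < 2 or not parts[0] or not parts[1]:
                    raise MalformedRowError(
                        f"{path}:{lineno}: expected two tab-separated gene ids, "
                        f"got {line!r}"
                    )
                rows.append((parts[0], parts[1], "physical"))
            elif fmt == "biogrid_tab":
                if len(parts) < 3 or not parts[0] or not parts[1] or not parts[2]:
                    raise MalformedRowError(
                        f"{path}:{lineno}: expected gene_a<TAB>gene_b<TAB>"
                        f"experimental_system, got {line!r}"
                    )
                rows.append((parts[0], parts[1], parts[2]))
            else:
                raise ValueError(f"unknown format {fmt!r}")
    # A header line, if present, is detected by the literal column names.
    if rows and rows[0][0].lower() in {"gene_a", "gene1", "interactor_a"}:
        rows = rows[1:]
    return rows


def read_network(path, fmt="tsv2col", species=None):
    """Read an edge list into a simple undirected graph plus raw records.

    Parameters
    ----------
    path : str or Path
        TSV file. ``tsv2col`` expects two gene-id columns; ``biogrid_tab``
        expects a third column naming the experimental system.
    fmt : {"tsv2col", "biogrid_tab"}
    species : str, optional
        Tag stored in ``graph["species"]``; defaults to the file stem.

    Returns
    -------
    (networkx.Graph, pandas.DataFrame)
        The graph contains only physical-interaction edges, with self-loops
        and duplicates dropped. The DataFrame retains every parsed row
        (columns ``gene_a, gene_b, system``), including genetic rows.
    """
    rows = _parse_rows(path, fmt)
    if not rows:
        raise ValueError(f"{path}: no interaction rows found")
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    net = nx.Graph()
    for a, b, system in rows:
        if system in GENETIC_SYSTEMS:
            continue
        if a == b:
            continue  # self-interactions carry no pairwise signal
        net.add_edge(a, b)
    if net.number_of_edges() == 0:
        raise ValueError(f"{path}: no physical-interaction edges")
    net.graph["species"] = species if species is not None else _stem(path)
    return net, records


def _stem(path):
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


def write_network(net, path):
    """Serialize the edge set as a sorted 2-column TSV (bit-stable)."""
    edges = sorted(tuple(sorted(e)) for e in net.edges())
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def largest_component(net):
    """Induced subgraph on the largest connected component.

    Ties between equally sized components are broken by the component
    containing the lexicographically smallest node, so pruning is
    deterministic.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    comps = list(nx.connected_components(net))
    comps.sort(key=lambda c: (-len(c), min(c)))
    sub = net.subgraph(comps[0]).copy()
    sub.graph.update(net.graph)
    return sub


def ablate_edges(net, keep_fraction, seed):
    """Randomly retain ``round(keep_fraction * |E|)`` edges, then re-prune.

    Emulates PPI incompleteness: the result is the largest connected
    component of the subsampled graph so that shortest-path parameters
    remain defined.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    import numpy as np

    edges = sorted(tuple(sorted(e)) for e in net.edges())
    n_keep = round(keep_fraction * len(edges))
    rng = np.random.default_rng(seed)
    kept_idx = rng.choice(len(edges), size=n_keep, replace=False)
    sub = nx.Graph()
    sub.add_edges_from(edges[i] for i in kept_idx)
    sub.graph.update(net.graph)
    return largest_component(sub)


def network_density(net):
    """|E| / C(|V|, 2) — the completeness proxy for a PPI network."""
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("density undefined for networks with < 2 nodes")
    return net.number_of_edges() / (n * (n - 1) / 2)


def popularity_stats(net, records):
    """Per-gene degree, popularity and degree/popularity.

    Popularity is the number of interaction rows (of any type) in which the
    gene appears; it proxies how intensively the gene has been studied.
    """
    counts = (
        pd.concat([records["gene_a"], records["gene_b"]])
        .value_counts()
        .to_dict()
    )
    rows = []
    for gene in sorted(net.nodes()):
        if gene not in counts:
            raise ValueError(f"gene {gene!r} absent from interaction records")
        pop = counts[gene]
        deg = net.degree(gene)
        rows.append((gene, deg, pop, deg / pop))
    return pd.DataFrame(
        rows, columns=["gene", "degree", "popularity", "normalized_popularity"]
    ).set_index("gene")


def sl_pairs_from_records(records):
    """Unordered gene pairs carrying a 'Synthetic Lethality' row."""
    mask = records["system"] == "Synthetic Lethality"
    return {
        frozenset((a, b))
        for a, b in records.loc[mask, ["gene_a", "gene_b"]].itertuples(index=False)
        if a != b
    }
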
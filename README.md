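# sinatra

Cross-species prediction of synthetic lethality from protein–protein
interaction (PPI) network connectivity.

Synthetic lethality (SL) — two individually nonessential genes whose
simultaneous loss kills the cell — underpins cancer combination therapy
and the interpretation of drug–drug interactions, but testing all gene
pairs of a mammalian genome is experimentally hopeless, and most species
have essentially no curated SL labels at all. `sinatra` scores every gene
pair of a *target* species for SL using a model trained on a *source*
species' labels, requiring nothing from the target but its PPI network.

The method rests on **connectivity homology**: genes that occupy similar
positions in their species' interactomes play similar roles, whether or
not they are sequence homologs. Each gene pair is described by a
20-parameter connectivity profile — 8 single-node graph parameters per
gene (betweenness, closeness and current-flow betweenness centrality,
degree centrality, eccentricity, eigenvector centrality, PageRank,
second-degree neighbor count) plus 4 node-pair parameters
(communicability `expm(A)_ij`, inverse shortest path, shared neighbors,
shared non-neighbors). Because raw parameter values live on
species-specific scales, each parameter is **translated** — normalized
within its species, by default by rank:

```
r_i = rank(x_i) / n        (ties broken at random, seeded)
```

over the species' genes (single-node parameters) or gene pairs
(node-pair parameters). A random forest (100 trees) trained on the
source species' SL/NSL pairs then transfers directly to the translated
target profiles, emitting a score in [0, 1] per pair.

The package also implements the classical comparison predictors
(ortholog-based homology transfer, GO term overlap, PFam domain overlap,
SCOP structural similarity, bi-nodal information centrality), the
evaluation statistics (ROC/AUC, DeLong's test, precision–recall,
ratio-adjusted PPV with bootstrap CIs, expected-undiscovered-SL counts,
Fisher enrichment tests), post-hoc biological filters (population
co-mutation, tissue/cell expression context), connectivity-homology
distance analysis, and a fully synthetic two-species benchmark generator
so that every stage is testable without downloading any database.

## Worked example

Generate a small two-species benchmark with planted, connectivity-linked
SL pairs, train on the source species, and score evaluation pairs of the
target species with and without translation:

```python
import numpy as np
from sinatra import synthgen, model, dataset, evalx

spec = synthgen.BenchmarkSpec(n_nodes_source=300, n_nodes_target=200,
                              n_complexes=20, n_pathways=10, n_sl=120, seed=7)
bench = synthgen.generate_benchmark(spec)
src, tgt = bench.source_net, bench.target_net
print(f"source: {src.number_of_nodes()} genes, {src.number_of_edges()} interactions")
print(f"target: {tgt.number_of_nodes()} genes, {tgt.number_of_edges()} interactions")
print(f"training on {len(bench.source_sl)} source SL pairs")

negatives = dataset.sample_negatives(tgt, bench.target_sl, 5.0, seed=99)
pairs = sorted(bench.target_sl | negatives, key=lambda p: tuple(sorted(p)))
labels = np.array([p in bench.target_sl for p in pairs], dtype=int)

for scheme in ("rank", "raw"):
    scores, mdl = model.sinatra_pipeline(
        src, bench.source_sl, tgt, scheme=scheme, seed=0, target_pairs=pairs)
    auc = evalx.roc_auc(scores["score"], labels)
    print(f"{scheme:>4} scheme: target AUC = {auc:.3f}")
```

Output:

```
source: 300 genes, 5005 interactions
target: 197 genes, 1406 interactions
training on 120 source SL pairs
rank scheme: target AUC = 0.903
 raw scheme: target AUC = 0.758
```

The rank-translated model recovers the planted SL signal in the target
species (AUC 0.90) while the same model applied to untranslated
parameters does much worse (AUC 0.76): the target network is roughly
half as dense as the source, so raw parameter values — degrees, walk
counts, centralities — sit on a different scale, and only their
within-species ranks are comparable across species.

The same pipeline is available from the shell:

```bash
sinatra synth --seed 7 --out fixtures/
sinatra run --config run.yaml        # source/target paths, scheme, seeds
sinatra eval --scores scores.tsv --labels sl.tsv --ratio 1000 --out eval.json
```

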
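import itertools

import networkx as nx
import numpy as np
import pytest

from sinatra import netio, synthgen

SMALL = dict(
    n_nodes_source=220,
    n_nodes_target=140,
    n_complexes=18,
    n_pathways=8,
    n_sl=60,
    comut_n_pairs=300,
)


class TestSpeciesPair:
    def test_networks_connected_and_tagged(self, small_benchmark):
        b = small_benchmark
        assert nx.is_connected(b.source_net)
        assert nx.is_connected(b.target_net)
        assert b.source_net.graph["species"] == "source"
        assert b.target_net.graph["species"] == "target"

    def test_orthology_links_real_genes(self, small_benchmark):
        b = small_benchmark
        for s, t in b.orthology_pairs:
            assert s in b.source_net
            assert t in b.target_net

    def test_duplications_make_many_to_many(self, small_benchmark):
        b = small_benchmark
        multi = [
            s for s, _ in b.orthology_pairs
            if len(b.orthology.targets(s)) > 1
        ]
        assert multi, "duplication rate > 0 must yield genes with 2 orthologs"

    def test_no_rewire_no_loss_is_isomorphic_subsample(self):
        spec = synthgen.BenchmarkSpec(
            **{**SMALL, "n_nodes_target": 10**9},  # keep all source genes
            rewire_fraction=0.0,
            duplication_rate=0.0,
            target_edge_keep=1.0,
            seed=3,
        )
        src, tgt, ortho, *_ = synthgen.generate_species_pair(spec)
        mapped = {(s, t) for s, t in ortho}
        assert len(mapped) == src.number_of_nodes()
        src_edges = {frozenset(("t" + a[1:], "t" + b[1:])) for a, b in src.edges()}
        assert src_edges == set(map(frozenset, tgt.edges()))

    def test_target_sparser_than_source(self, small_benchmark):
        b = small_benchmark
        assert netio.network_density(b.source_net) > netio.network_density(
            b.target_net
        )

    def test_density_ratio_steerable_by_edge_keep(self):
        spec_full = synthgen.BenchmarkSpec(**SMALL, target_edge_keep=1.0, seed=5)
        spec_half = synthgen.BenchmarkSpec(**SMALL, target_edge_keep=0.5, seed=5)
        *_, t_full = synthgen.generate_species_pair(spec_full)[:2], None
        tgt_full = synthgen.generate_species_pair(spec_full)[1]
        tgt_half = synthgen.generate_species_pair(spec_half)[1]
        ratio = netio.network_density(tgt_full) / netio.network_density(tgt_half)
        assert ratio == pytest.approx(2.0, rel=0.2)

    def test_unknown_generator_rejected(self):
        with pytest.raises(ValueError):
            synthgen.generate_species_pair(
                synthgen.BenchmarkSpec(generator="smallworld")
            )


class TestPlantedLabels:
    def test_mechanism_mix_counts(self, small_benchmark):
        from collections import Counter

        b = small_benchmark
        counts = Counter(b.source_mechanisms.values())
        n = b.spec.n_sl
        assert counts["within_complex"] >= 0.4 * n * (1 - b.spec.label_noise) * 0.9
        assert counts["parallel"] > 0 and counts["other"] > 0

    def test_pure_within_complex_mix(self):
        spec = synthgen.BenchmarkSpec(**SMALL, mechanism_mix=(1.0, 0.0, 0.0),
                                      label_noise=0.0, seed=2)
        b = synthgen.generate_benchmark(spec)
        cplx_pairs = {
            frozenset(p)
            for members in b.complexes_source.values()
            for p in itertools.combinations(sorted(members), 2)
        }
        assert all(p in cplx_pairs for p in b.source_sl)

    def test_within_complex_pairs_in_their_complexes(self, small_benchmark):
        b = small_benchmark
        cplx_pairs = {
            frozenset(p)
            for members in b.complexes_source.values()
            for p in itertools.combinations(sorted(members), 2)
        }
        for pair, mech in b.source_mechanisms.items():
            if mech == "within_complex":
                assert pair in cplx_pairs

    def test_parallel_pairs_nonadjacent_shared_neighbor(self, small_benchmark):
        b = small_benchmark
        # labels are planted on the true target biology; the observed
        # source network is the true source network, so check there
        net = b.source_net
        for pair, mech in b.source_mechanisms.items():
            if mech == "parallel":
                a, c = tuple(pair)
                assert not net.has_edge(a, c)
                assert len(set(net[a]) & set(net[c])) >= b.spec.parallel_min_shared

    def test_label_noise_fraction_tagged(self):
        spec = synthgen.BenchmarkSpec(**SMALL, label_noise=0.1, seed=4)
        b = synthgen.generate_benchmark(spec)
        from collections import Counter

        noise = Counter(b.source_mechanisms.values())["noise"]
        assert noise == round(0.1 * spec.n_sl)

    def test_insufficient_pool_raises(self):
        spec = synthgen.BenchmarkSpec(
            **{**SMALL, "n_complexes": 2}, mechanism_mix=(1.0, 0.0, 0.0), seed=0
        )
        with pytest.raises(ValueError, match="within-complex"):
            synthgen.generate_benchmark(spec)


class TestAnnotations:
    def test_ortholog_go_sharing_full(self):
        spec = synthgen.BenchmarkSpec(
            **SMALL, ortholog_share=1.0, annotation_coverage=1.0, seed=6
        )
        b = synthgen.generate_benchmark(spec)
        shared_frac = []
        for s, t in b.orthology_pairs:
            anc = {x for x in b.go_source.get(s, set()) if x.startswith("GO:0")}
            got = {x for x in b.go_target.get(t, set()) if x.startswith("GO:0")}
            if anc:
                shared_frac.append(len(anc & got) / len(anc))
        assert np.mean(shared_frac) > 0.95

    def test_scop_lineages_have_four_levels(self, small_benchmark):
        for lineage in small_benchmark.scop_source.values():
            assert len(lineage) == 4

    def test_comutation_counts_valid(self, small_benchmark):
        c = small_benchmark.comutation
        assert (c["n_comutated"] >= 1).all()
        assert (c["n_comutated"] <= 0.05 * c["n_patients"]).all()

    def test_comutation_enriched_on_non_sl(self, small_benchmark):
        b = small_benchmark
        pairs = {
            frozenset((g1, g2))
            for g1, g2 in zip(b.comutation["gene1"], b.comutation["gene2"])
        }
        # enrichment parameter 0.9 -> roughly 10% of co-mutation rows may
        # fall on SL pairs; the bulk must be non-SL
        frac_sl = len(pairs & b.target_sl) / len(pairs)
        assert frac_sl < 0.15

    def test_expression_covers_contexts(self, small_benchmark):
        e = small_benchmark.expression_target
        assert e["context"].nunique() == small_benchmark.spec.n_contexts
        assert set(e["detected"].unique()) <= {0, 1}


class TestDeterminismAndIO:
    def test_full_determinism(self):
        spec = synthgen.BenchmarkSpec(**SMALL, seed=9)
        a = synthgen.generate_benchmark(spec)
        b = synthgen.generate_benchmark(spec)
        assert set(a.source_net.edges()) == set(b.source_net.edges())
        assert set(a.target_net.edges()) == set(b.target_net.edges())
        assert a.source_sl == b.source_sl
        assert a.target_sl == b.target_sl
        assert a.go_target == b.go_target
        assert a.comutation.equals(b.comutation)

    def test_fixture_files_byte_stable(self, small_benchmark, tmp_path):
        import filecmp
        import os

        d1, d2 = tmp_path / "a", tmp_path / "b"
        synthgen.write_fixture_dir(small_benchmark, d1)
        synthgen.write_fixture_dir(small_benchmark, d2)
        for name in sorted(os.listdir(d1)):
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name

    def test_fixture_dir_round_trip(self, small_benchmark, tmp_path):
        from sinatra import dataset

        b = small_benchmark
        synthgen.write_fixture_dir(b, tmp_path)
        net, records = netio.read_network(
            tmp_path / "source_edges.tsv", fmt="tsv2col"
        )
        assert set(map(frozenset, net.edges())) == set(
            map(frozenset, b.source_net.edges())
        )
        sl = dataset.load_sl_labels(tmp_path / "source_sl.tsv", b.source_net)
        assert sl == b.source_sl
        # BioGRID-style records parse and separate physical from SL rows
        net2, rec2 = netio.read_network(
            tmp_path / "target_biogrid.tsv", fmt="biogrid_tab"
        )
        assert netio.sl_pairs_from_records(rec2) == b.target_sl
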
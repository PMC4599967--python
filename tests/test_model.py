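import numpy as np
import pandas as pd
import pytest

from sinatra import dataset, model
from sinatra.dataset import FEATURE_COLUMNS


def separable_table(n=60, seed=0, gap=1.0):
    """Linearly separable toy: positives near 1, negatives near 0."""
    rng = np.random.default_rng(seed)
    n_pos = n // 2
    X = np.vstack(
        [
            rng.normal(1.0, 0.05, size=(n_pos, 20)),
            rng.normal(1.0 - gap, 0.05, size=(n - n_pos, 20)),
        ]
    )
    df = pd.DataFrame(X, columns=FEATURE_COLUMNS)
    df.insert(0, "gene2", [f"b{i}" for i in range(n)])
    df.insert(0, "gene1", [f"a{i}" for i in range(n)])
    df["label"] = ["SL"] * n_pos + ["NSL"] * (n - n_pos)
    return df


class TestTrainScore:
    def test_separable_training_auc_is_one(self):
        ft = separable_table()
        mdl = model.train(ft, seed=0)
        scores = model.score(mdl, ft)
        from sinatra import evalx

        y = (ft["label"] == "SL").astype(int)
        assert evalx.roc_auc(scores["score"], y) == 1.0
        assert scores["score"].between(0, 1).all()

    def test_positives_above_negatives(self):
        ft = separable_table()
        mdl = model.train(ft, algorithm="logistic_regression", seed=0)
        s = model.score(mdl, ft)["score"]
        y = ft["label"] == "SL"
        assert s[y.to_numpy()].min() >= 0.5 > s[(~y).to_numpy()].max()

    def test_single_class_error(self):
        ft = separable_table()
        ft["label"] = "SL"
        with pytest.raises(ValueError):
            model.train(ft)

    def test_same_seed_identical_scores(self):
        ft = separable_table(gap=0.3)
        held = separable_table(seed=99, gap=0.3)
        a = model.score(model.train(ft, seed=5), held)["score"]
        b = model.score(model.train(ft, seed=5), held)["score"]
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_schema_mismatch_names_columns(self):
        ft = separable_table()
        mdl = model.train(ft)
        broken = ft.drop(columns=["communicability"])
        with pytest.raises(ValueError, match="communicability"):
            model.score(mdl, broken)

    def test_batched_scoring_consistent(self):
        ft = separable_table(gap=0.3)
        mdl = model.train(ft, seed=1)
        whole = model.score(mdl, ft)["score"].to_numpy()
        parts = np.concatenate(
            [model.score(mdl, ft.iloc[i : i + 17])["score"].to_numpy()
             for i in range(0, len(ft), 17)]
        )
        assert np.array_equal(whole, parts)

    def test_rf_probability_is_tree_vote_fraction(self):
        ft = separable_table(gap=0.4)
        mdl = model.train(ft, seed=3, n_trees=5)
        X = ft[FEATURE_COLUMNS].to_numpy()
        votes = np.mean(
            [tree.predict(X) for tree in mdl.estimator.estimators_], axis=0
        )
        assert np.allclose(model.score(mdl, ft)["score"].to_numpy(), votes)


class TestCrossValidate:
    def test_fold_sizes(self):
        ft = separable_table(n=100, gap=0.3)
        res = model.cross_validate(ft, k=5, seed=0)
        assert res["k"] == 5 and len(res["fold_aucs"]) == 5

    def test_separable_mean_auc_one(self):
        ft = separable_table(n=100)
        assert model.cross_validate(ft, k=5, seed=0)["mean_auc"] == 1.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(7)
        ft = separable_table(n=200, gap=0.5)
        aucs = []
        for rep in range(5):
            permuted = ft.copy()
            permuted["label"] = rng.permutation(permuted["label"].to_numpy())
            aucs.append(model.cross_validate(permuted, k=5, seed=rep)["mean_auc"])
        assert abs(np.mean(aucs) - 0.5) < 0.06

    def test_train20_test80_mode(self):
        ft = separable_table(n=100)
        res = model.cross_validate(ft, k=5, mode="train20_test80", seed=0)
        assert res["mean_auc"] > 0.95  # separable either way

    def test_seed_reproducible(self):
        ft = separable_table(n=80, gap=0.2)
        a = model.cross_validate(ft, seed=4)
        b = model.cross_validate(ft, seed=4)
        assert a["fold_aucs"] == b["fold_aucs"]


class TestFeatureImportance:
    def test_sums_to_one_and_nonnegative(self):
        ft = separable_table(gap=0.3)
        imp = model.feature_importance(model.train(ft, seed=0))
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)
        assert (imp >= 0).all()

    def test_planted_single_signal_ranks_first(self):
        rng = np.random.default_rng(2)
        n = 200
        X = rng.normal(size=(n, 20))
        y = (X[:, 7] > 0).astype(int)
        df = pd.DataFrame(X, columns=FEATURE_COLUMNS)
        df.insert(0, "gene2", [f"b{i}" for i in range(n)])
        df.insert(0, "gene1", [f"a{i}" for i in range(n)])
        df["label"] = np.where(y == 1, "SL", "NSL")
        imp = model.feature_importance(model.train(df, seed=0))
        assert imp.idxmax() == FEATURE_COLUMNS[7]

    def test_lr_model_rejected(self):
        ft = separable_table()
        mdl = model.train(ft, algorithm="logistic_regression")
        with pytest.raises(ValueError):
            model.feature_importance(mdl)


class TestPipelineDegenerate:
    def test_raw_identical_networks_scores_deterministic(self, small_benchmark):
        """Same source/target network with raw scheme reduces to
        within-species behavior: train pairs score high."""
        bench = small_benchmark
        net = bench.source_net
        sl = bench.source_sl
        pairs = sorted(sl, key=lambda p: tuple(sorted(p)))[:30]
        s1, _ = model.sinatra_pipeline(
            net, sl, net, scheme="raw", seed=3, target_pairs=pairs
        )
        s2, _ = model.sinatra_pipeline(
            net, sl, net, scheme="raw", seed=3, target_pairs=pairs
        )
        assert np.array_equal(s1["score"].to_numpy(), s2["score"].to_numpy())
        assert s1["score"].mean() > 0.5  # training pairs rescored as likely SL

    def test_whole_genome_zero_scores_for_off_network_genes(self, small_benchmark):
        bench = small_benchmark
        tgt = bench.target_net
        genes = sorted(tgt.nodes())
        in_pairs = [frozenset((genes[0], genes[1])), frozenset((genes[2], genes[3]))]
        out_pair = frozenset(("ghostA", genes[0]))
        scores, _ = model.sinatra_pipeline(
            bench.source_net,
            bench.source_sl,
            tgt,
            scheme="rank",
            seed=1,
            target_pairs=in_pairs + [out_pair],
            whole_genome=True,
            extra_genes={"ghostA"},
        )
        lookup = {
            frozenset((a, b)): s
            for a, b, s in zip(scores.gene1, scores.gene2, scores.score)
        }
        assert lookup[out_pair] == 0.0

    def test_whole_genome_mode_does_not_change_in_network_scores(self, small_benchmark):
        bench = small_benchmark
        tgt = bench.target_net
        genes = sorted(tgt.nodes())
        in_pairs = [frozenset((genes[0], genes[1])), frozenset((genes[4], genes[9]))]
        plain, _ = model.sinatra_pipeline(
            bench.source_net, bench.source_sl, tgt, seed=2, target_pairs=in_pairs
        )
        expanded, _ = model.sinatra_pipeline(
            bench.source_net,
            bench.source_sl,
            tgt,
            seed=2,
            target_pairs=in_pairs + [frozenset(("ghostB", genes[0]))],
            whole_genome=True,
        )
        merged = plain.merge(expanded, on=["gene1", "gene2"], suffixes=("_a", "_b"))
        assert np.allclose(merged["score_a"], merged["score_b"])

    def test_off_network_pair_without_flag_is_error(self, small_benchmark):
        bench = small_benchmark
        genes = sorted(bench.target_net.nodes())
        with pytest.raises(KeyError):
            model.sinatra_pipeline(
                bench.source_net,
                bench.source_sl,
                bench.target_net,
                seed=0,
                target_pairs=[frozenset(("ghostC", genes[0]))],
            )
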
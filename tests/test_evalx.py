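import numpy as np
import pytest

from sinatra import evalx
from tests import _oracles as oracles


class TestRocAuc:
    def test_perfect(self):
        assert evalx.roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_tied_is_half(self):
        assert evalx.roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_four_point_toy(self):
        assert evalx.roc_auc([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0]) == 0.75

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            evalx.roc_auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 50))
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert evalx.roc_auc(scores, labels) == pytest.approx(
            oracles.auc_pair_counting(scores, labels)
        )


class TestDeLong:
    def test_identical_scores_degenerate(self):
        s = [0.9, 0.8, 0.3, 0.1]
        res = evalx.delong_test(s, s, [1, 1, 0, 0])
        assert res["delta_auc"] == 0.0
        assert res["p"] == 1.0
        assert res["degenerate"]

    def test_perfect_vs_antiperfect(self):
        rng = np.random.default_rng(0)
        labels = np.array([1] * 10 + [0] * 10)
        a = np.concatenate([rng.uniform(0.8, 1.0, 10), rng.uniform(0.0, 0.2, 10)])
        b = 1.0 - a
        res = evalx.delong_test(a, b, labels)
        # perfect separation has zero DeLong variance: the difference is
        # reported, the test flagged degenerate
        assert res["delta_auc"] == pytest.approx(1.0)
        assert res["degenerate"]

    def test_consistent_with_bootstrap_oracle(self):
        """DeLong p agrees with a paired-bootstrap z test on the AUC gap."""
        rng = np.random.default_rng(42)
        n = 200
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        signal = labels + rng.normal(0, 1.2, n)
        a = signal + rng.normal(0, 0.4, n)
        b = 0.7 * signal + rng.normal(0, 0.8, n)
        res = evalx.delong_test(a, b, labels)
        deltas = []
        idx = np.arange(n)
        for _ in range(2000):
            s = rng.choice(idx, n, replace=True)
            if labels[s].min() == labels[s].max():
                continue
            deltas.append(
                evalx.roc_auc(a[s], labels[s]) - evalx.roc_auc(b[s], labels[s])
            )
        se = np.std(deltas, ddof=1)
        z_boot = res["delta_auc"] / se
        import scipy.stats

        p_boot = 2 * scipy.stats.norm.sf(abs(z_boot))
        assert res["p"] == pytest.approx(p_boot, abs=0.05)


class TestPPV:
    def test_single_configuration(self):
        # pos scores [0.9], neg pool has exactly 3 -> forced sample is all 3
        scores = [0.9, 0.9, 0.1, 0.1]
        labels = [1, 0, 0, 0]
        curve = evalx.ppv_at_thresholds(
            scores, labels, nsl_per_sl=3, cutoffs=[0.85], n_boot=50, seed=0
        )
        assert curve["ppv_median"].iloc[0] == pytest.approx(0.5)

    def test_cutoff_above_max_is_missing(self):
        scores = [0.6, 0.5, 0.4, 0.3, 0.2, 0.1]
        labels = [1, 1, 0, 0, 0, 0]
        curve = evalx.ppv_at_thresholds(
            scores, labels, nsl_per_sl=2, cutoffs=[0.5, 0.95], n_boot=20, seed=0
        )
        assert np.isnan(curve["ppv_median"].iloc[1])

    def test_insufficient_pool(self):
        with pytest.raises(ValueError):
            evalx.ppv_at_thresholds([0.9, 0.1], [1, 0], nsl_per_sl=5, n_boot=5)

    def test_reproducible_ci(self):
        rng = np.random.default_rng(1)
        scores = np.concatenate([rng.beta(4, 2, 30), rng.beta(2, 4, 600)])
        labels = np.array([1] * 30 + [0] * 600)
        kw = dict(nsl_per_sl=10, cutoffs=[0.3, 0.6], n_boot=200, seed=5)
        a = evalx.ppv_at_thresholds(scores, labels, **kw)
        b = evalx.ppv_at_thresholds(scores, labels, **kw)
        assert np.allclose(a["ppv_low"], b["ppv_low"], equal_nan=True)
        assert np.allclose(a["ppv_high"], b["ppv_high"], equal_nan=True)

    def test_within_complex_degenerate_equals_all_pairs(self):
        rng = np.random.default_rng(2)
        scores = np.concatenate([rng.beta(5, 2, 20), rng.beta(2, 5, 400)])
        labels = np.array([1] * 20 + [0] * 400)
        kw = dict(nsl_per_sl=5, cutoffs=[0.4, 0.7], n_boot=100, seed=3)
        all_curve = evalx.ppv_at_thresholds(scores, labels, **kw)
        wc = evalx.within_complex_ppv(
            scores, labels, np.ones(len(scores), dtype=bool), **kw
        )
        assert np.allclose(
            all_curve["ppv_median"], wc["ppv_median"], equal_nan=True
        )


class TestExpectedUndiscovered:
    def make_inputs(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        n = 500
        genes = [f"g{i}" for i in range(60)]
        pairs = set()
        while len(pairs) < n:
            a, b = rng.choice(genes, 2, replace=False)
            pairs.add((min(a, b), max(a, b)))
        pairs = sorted(pairs)
        scores = rng.random(n)
        table = pd.DataFrame(
            {"gene1": [p[0] for p in pairs], "gene2": [p[1] for p in pairs],
             "score": scores}
        )
        known = {frozenset(p) for p, s in zip(pairs, scores) if s > 0.8 and hash(p) % 3 == 0}
        curve = pd.DataFrame(
            {"cutoff": np.arange(0.0, 1.0, 0.05),
             "ppv_median": np.linspace(0.01, 0.4, 20)}
        )
        return table, known, curve

    def test_bins_telescope(self):
        table, known, curve = self.make_inputs()
        out = evalx.expected_undiscovered(table, known, curve)
        assert out["expected"].sum() == pytest.approx(
            out["expected_cumulative"].iloc[0]
        )

    def test_zero_ppv_zero_expectation(self):
        table, known, curve = self.make_inputs()
        curve["ppv_median"] = 0.0
        out = evalx.expected_undiscovered(table, known, curve)
        assert (out["expected"] == 0).all()

    def test_expected_formula_at_cutoff(self):
        table, known, curve = self.make_inputs()
        out = evalx.expected_undiscovered(table, known, curve)
        c = 0.85
        row = out[np.isclose(out["cutoff"], c)].iloc[0]
        n_called = (table["score"] >= c).sum()
        ppv = curve.loc[np.isclose(curve["cutoff"], c), "ppv_median"].iloc[0]
        assert row["expected_cumulative"] == pytest.approx(ppv * n_called)


class TestFisher:
    def test_closed_form_or(self):
        t = evalx.confusion_from_scores(
            [1] * 10 + [1] * 1 + [0] * 2 + [0] * 20,
            [1] * 10 + [0] * 1 + [1] * 2 + [0] * 20,
            cutoff=0.5,
        )
        assert (t.tp, t.fp, t.fn, t.tn) == (10, 1, 2, 20)
        assert t.odds_ratio == pytest.approx(100.0)

    def test_no_calls_flagged(self):
        t = evalx.confusion_from_scores([0.1, 0.2, 0.3], [1, 0, 0], cutoff=0.9)
        assert t.tp == 0 and t.fp == 0
        assert not t.odds_ratio_defined
        assert t.p_value == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_fisher_matches_hypergeometric_oracle(self, seed):
        rng = np.random.default_rng(seed)
        while True:
            tp, fp, fn, tn = rng.integers(0, 11, size=4)
            if min(tp + fp, fn + tn, tp + fn, fp + tn) > 0 and tp + fp + fn + tn <= 30:
                break
        t = evalx._fisher_table(int(tp), int(fp), int(fn), int(tn))
        ref = oracles.fisher_exact_two_sided(int(tp), int(fp), int(fn), int(tn))
        assert t.p_value == pytest.approx(ref, abs=1e-12)


class TestEnrichment:
    def test_called_equals_annotated_maximal(self):
        universe = {frozenset((f"a{i}", f"b{i}")) for i in range(40)}
        called = set(list(universe)[:10])
        t = evalx.enrichment_test(called, called, universe)
        assert not t.odds_ratio_defined or t.odds_ratio == np.inf
        assert t.p_value < 1e-6

    def test_empty_universe_error(self):
        with pytest.raises(ValueError):
            evalx.enrichment_test(set(), set(), set())


class TestPrecisionRecall:
    def test_perfect_scores(self):
        pr = evalx.precision_recall([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        # every recall level is attainable at precision 1 for a perfect ranker
        for r in (0.5, 1.0):
            assert pr["precision"][pr["recall"] == r].max() == 1.0

    def test_toy_matches_hand_enumeration(self):
        scores = [0.9, 0.8, 0.7, 0.1]
        labels = [1, 0, 1, 0]
        pr = evalx.precision_recall(scores, labels)
        # thresholds descending recall: at t=0.9 -> P=1, R=.5; t=0.8 -> P=.5, R=.5;
        # t=0.7 -> P=2/3, R=1; t=0.1 -> P=.5, R=1
        rows = {
            round(t, 2): (round(p, 4), round(r, 4))
            for t, p, r in zip(pr["threshold"], pr["precision"], pr["recall"])
            if not np.isnan(t)
        }
        assert rows[0.9] == (1.0, 0.5)
        assert rows[0.8] == (0.5, 0.5)
        assert rows[0.7] == (round(2 / 3, 4), 1.0)
        assert rows[0.1] == (0.5, 1.0)
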
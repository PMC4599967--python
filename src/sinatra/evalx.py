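"""Evaluation statistics for SL score tables.

Includes ROC/AUC (Mann-Whitney with midranks), DeLong's paired test for
comparing correlated ROC curves, precision-recall, positive-predictive-value
estimation under a forced SL:NSL prevalence with percentile-bootstrap 99%
confidence intervals, the expected-undiscovered-SL calculation, and Fisher
exact contingency/enrichment tests.

The PPV machinery exists because SL is rare (~1 in 1000 gene pairs):
evaluating precision at the natural prevalence of a curated label set would
be wildly optimistic, so NSL pairs are resampled at the assumed prevalence
before each PPV computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import precision_recall_curve, roc_auc_score

__all__ = [
    "ContingencyTable",
    "roc_auc",
    "delong_test",
    "ppv_at_thresholds",
    "within_complex_ppv",
    "expected_undiscovered",
    "confusion_from_scores",
    "enrichment_test",
    "precision_recall",
]

DEFAULT_CUTOFFS = tuple(np.round(np.arange(0.0, 1.0, 0.05), 2))


@dataclass
class ContingencyTable:
    """2x2 confusion counts with odds ratio and Fisher exact p."""

    tp: int
    fp: int
    fn: int
    tn: int
    odds_ratio: float
    p_value: float
    odds_ratio_defined: bool


def _check_two_classes(labels):
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("need both classes present")
    return labels


def roc_auc(scores, labels):
    """AUC via the Mann-Whitney formulation (ties get midranks)."""
    labels = _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _midrank(x):
    """Midranks as used by the fast DeLong algorithm."""
    sorted_idx = np.argsort(x)
    xs = x[sorted_idx]
    n = len(x)
    t = np.zeros(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n, dtype=float)
    out[sorted_idx] = t
    return out


def _delong_auc_variance(scores_list, labels):
    """AUCs and their covariance matrix from DeLong structural components."""
    labels = np.asarray(labels, dtype=int)
    pos = [np.asarray(s, dtype=float)[labels == 1] for s in scores_list]
    neg = [np.asarray(s, dtype=float)[labels == 0] for s in scores_list]
    m, n = len(pos[0]), len(neg[0])
    k = len(scores_list)
    aucs = np.zeros(k)
    v01 = np.zeros((k, m))
    v10 = np.zeros((k, n))
    for r in range(k):
        all_scores = np.concatenate([pos[r], neg[r]])
        tx = _midrank(pos[r])
        ty = _midrank(neg[r])
        tz = _midrank(all_scores)
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
        v01[r] = (tz[:m] - tx) / n
        v10[r] = 1.0 - (tz[m:] - ty) / m
    s01 = np.cov(v01) if k > 1 else np.atleast_2d(np.var(v01, ddof=1))
    s10 = np.cov(v10) if k > 1 else np.atleast_2d(np.var(v10, ddof=1))
    cov = s01 / m + s10 / n
    return aucs, np.atleast_2d(cov)


def delong_test(scores_a, scores_b, labels):
    """Paired DeLong test for the AUC difference of two score vectors.

    Returns ``(delta_auc, z, p)``; if the variance of the difference is
    zero (e.g. identical score vectors) the comparison is degenerate and
    ``(0-or-delta, 0.0, 1.0)`` is returned with the difference as computed.
    """
    labels = _check_two_classes(labels)
    aucs, cov = _delong_auc_variance([scores_a, scores_b], labels)
    delta = float(aucs[0] - aucs[1])
    var = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    if var <= 0 or not math.isfinite(var):
        return {"delta_auc": delta, "z": 0.0, "p": 1.0, "degenerate": True}
    z = delta / math.sqrt(var)
    p = 2 * scipy.stats.norm.sf(abs(z))
    return {"delta_auc": delta, "z": float(z), "p": float(p), "degenerate": False}


def _ppv_resample(pos_scores, neg_scores, n_neg, cutoffs, rng):
    sample = rng.choice(neg_scores, size=n_neg, replace=False)
    ppvs = []
    called = []
    for c in cutoffs:
        tp = int((pos_scores >= c).sum())
        fp = int((sample >= c).sum())
        called.append(tp + fp)
        ppvs.append(tp / (tp + fp) if tp + fp > 0 else np.nan)
    return ppvs, called


def ppv_at_thresholds(
    scores, labels, nsl_per_sl=1000, cutoffs=DEFAULT_CUTOFFS, n_boot=1000, seed=0
):
    """PPV curve under a forced SL:NSL ratio, with 99% bootstrap CIs.

    Each of ``n_boot`` resamples draws ``nsl_per_sl * n_SL`` negative scores
    without replacement, calls every pair with score >= cutoff SL, and
    computes PPV = TP / (TP + FP). The reported curve is the per-cutoff
    median with 0.5%/99.5% percentile bounds. Cutoffs where no pair is
    called are reported as missing (NaN), not as PPV 0.

    Returns a DataFrame ``cutoff, ppv_median, ppv_low, ppv_high, n_called,
    expected_hits`` where ``n_called``/``expected_hits`` are medians over
    resamples.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_classes(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    n_neg = int(round(nsl_per_sl * len(pos)))
    if n_neg > len(neg):
        raise ValueError(
            f"need {n_neg} NSL scores per resample but only {len(neg)} available"
        )
    cutoffs = np.asarray(sorted(cutoffs), dtype=float)
    rng = np.random.default_rng(seed)
    boot_ppv = np.empty((n_boot, len(cutoffs)))
    boot_called = np.empty((n_boot, len(cutoffs)))
    for r in range(n_boot):
        ppvs, called = _ppv_resample(pos, neg, n_neg, cutoffs, rng)
        boot_ppv[r] = ppvs
        boot_called[r] = called
    import warnings

    with warnings.catch_warnings():
        # columns where no resample calls a pair are legitimately all-NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(boot_ppv, axis=0)
        lo = np.nanpercentile(boot_ppv, 0.5, axis=0)
        hi = np.nanpercentile(boot_ppv, 99.5, axis=0)
    n_called = np.median(boot_called, axis=0)
    return pd.DataFrame(
        {
            "cutoff": cutoffs,
            "ppv_median": med,
            "ppv_low": lo,
            "ppv_high": hi,
            "n_called": n_called,
            "expected_hits": med * n_called,
        }
    )


def within_complex_ppv(
    scores,
    labels,
    complex_flags,
    nsl_per_sl=50,
    cutoffs=DEFAULT_CUTOFFS,
    n_boot=1000,
    seed=0,
):
    """PPV restricted to within-complex pairs, at the within-complex ratio.

    Within protein complexes SL is far less rare than genome-wide, so the
    forced ratio defaults to 1:50 instead of 1:1000.
    """
    flags = np.asarray(complex_flags, dtype=bool)
    scores = np.asarray(scores, dtype=float)[flags]
    labels = np.asarray(labels, dtype=int)[flags]
    return ppv_at_thresholds(
        scores, labels, nsl_per_sl=nsl_per_sl, cutoffs=cutoffs, n_boot=n_boot, seed=seed
    )


def expected_undiscovered(score_table, known_sl, ppv_curve, bin_width=0.05):
    """Expected vs observed SL counts per score bin.

    ``expected(>=C) = PPV(C) * n_called(C)`` where ``n_called(C)`` counts all
    scored pairs at or above C; the per-bin expectation is the telescoping
    difference between consecutive cutoffs so bins sum back to the
    expectation at the lowest cutoff. ``observed`` counts experimentally
    known SL pairs falling in each bin.
    """
    scores = score_table["score"].to_numpy(dtype=float)
    known = np.array(
        [
            frozenset((a, b)) in known_sl
            for a, b in zip(score_table["gene1"], score_table["gene2"])
        ]
    )
    cutoffs = ppv_curve["cutoff"].to_numpy(dtype=float)
    ppv = np.nan_to_num(ppv_curve["ppv_median"].to_numpy(dtype=float), nan=0.0)
    n_called = np.array([(scores >= c).sum() for c in cutoffs])
    expected_cum = ppv * n_called
    rows = []
    for i, c in enumerate(cutoffs):
        upper = c + bin_width
        exp_next = expected_cum[i + 1] if i + 1 < len(cutoffs) else 0.0
        expected_bin = expected_cum[i] - exp_next
        observed_bin = int(((scores >= c) & (scores < upper) & known).sum())
        if i + 1 == len(cutoffs):
            observed_bin = int(((scores >= c) & known).sum())
        rows.append((c, expected_bin, observed_bin, expected_cum[i], n_called[i]))
    return pd.DataFrame(
        rows,
        columns=["cutoff", "expected", "observed", "expected_cumulative", "n_called"],
    )


def confusion_from_scores(scores, labels, cutoff):
    """Confusion table calling score >= cutoff SL, with OR and Fisher p."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    called = scores >= cutoff
    tp = int((called & (labels == 1)).sum())
    fp = int((called & (labels == 0)).sum())
    fn = int((~called & (labels == 1)).sum())
    tn = int((~called & (labels == 0)).sum())
    return _fisher_table(tp, fp, fn, tn)


def _fisher_table(tp, fp, fn, tn):
    if min(tp + fp, fn + tn, tp + fn, fp + tn) == 0:
        # zero margin: the test is uninformative
        return ContingencyTable(tp, fp, fn, tn, float("nan"), 1.0, False)
    _, p = scipy.stats.fisher_exact([[tp, fp], [fn, tn]], alternative="two-sided")
    if fp * fn == 0:
        return ContingencyTable(tp, fp, fn, tn, float("inf"), float(p), False)
    return ContingencyTable(tp, fp, fn, tn, (tp * tn) / (fp * fn), float(p), True)


def enrichment_test(called_pairs, annotation_pairs, universe_pairs):
    """Fisher enrichment of an annotation among called pairs.

    2x2 of called/uncalled x annotated/unannotated over the pair universe;
    used e.g. to ask whether high-scoring pairs are enriched for
    within-pathway or within-complex membership.
    """
    universe = set(universe_pairs)
    if not universe:
        raise ValueError("empty pair universe")
    called = set(called_pairs) & universe
    annotated = set(annotation_pairs) & universe
    tp = len(called & annotated)
    fp = len(called - annotated)
    fn = len(annotated - called)
    tn = len(universe) - tp - fp - fn
    return _fisher_table(tp, fp, fn, tn)


def precision_recall(scores, labels):
    """Precision/recall at every distinct score threshold (DataFrame)."""
    labels = _check_two_classes(labels)
    precision, recall, thresholds = precision_recall_curve(
        labels, np.asarray(scores, dtype=float)
    )
    return pd.DataFrame(
        {
            "threshold": np.append(thresholds, np.nan),
            "precision": precision,
            "recall": recall,
        }
    )
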
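"""Post-hoc biological filters for human-scale SL predictions.

A high connectivity score marks synthetic-lethal *potential*; population
genetics and expression context can veto it:

- **co-mutation filter** — a pair observed homozygously co-mutated with
  deleterious variants in living individuals (at least 1 patient but no
  more than 5% of a study cohort) is demonstrably tolerated, hence a
  confirmed non-SL pair;
- **tissue/cell filter** — a pair whose products are both undetected in a
  tissue cannot be SL *in that context* (the default ``both_absent`` rule;
  ``either_absent`` is the stricter alternative);
- **expected retained** — the chance expectation
  ``(1 - removed/total) * N`` for how many of N unfiltered SL calls a
  context filter should retain if removal were independent of the score.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .evalx import _fisher_table

__all__ = [
    "load_comutation_table",
    "load_expression_table",
    "comutation_filter",
    "tissue_filter",
    "expected_retained",
    "context_filter_report",
]

COMUT_COLUMNS = ["gene1", "gene2", "n_comutated", "n_patients", "study"]


def load_comutation_table(path):
    """Co-mutation TSV ``gene1 gene2 n_comut n_patients study``."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=COMUT_COLUMNS, comment="#",
        dtype={"gene1": str, "gene2": str, "study": str},
    )
    if (df["n_comutated"] > df["n_patients"]).any():
        bad = df[df["n_comutated"] > df["n_patients"]].iloc[0]
        raise ValueError(
            f"pair ({bad.gene1}, {bad.gene2}): n_comutated > n_patients"
        )
    return df


def load_expression_table(path):
    """Expression TSV ``gene context detected{0,1}`` -> DataFrame."""
    return pd.read_csv(
        path, sep="\t", header=None, names=["gene", "context", "detected"],
        comment="#", dtype={"gene": str, "context": str},
    )


def comutation_filter(pairs, comut, min_patients=1, max_fraction=0.05):
    """Split pairs into (retained, removed) by the co-mutation rule.

    A pair is removed iff, in at least one study, it was co-mutated in at
    least ``min_patients`` patients and in no more than ``max_fraction`` of
    the study's cohort. The upper bound guards against sequencing artifacts
    and common benign variants.
    """
    if (comut["n_comutated"] > comut["n_patients"]).any():
        raise ValueError("co-mutation table has n_comutated > n_patients")
    flagged = set()
    for row in comut.itertuples(index=False):
        frac = row.n_comutated / row.n_patients
        if row.n_comutated >= min_patients and frac <= max_fraction:
            flagged.add(frozenset((row.gene1, row.gene2)))
    pairs = [frozenset(p) for p in pairs]
    retained = [p for p in pairs if p not in flagged]
    removed = [p for p in pairs if p in flagged]
    return retained, removed


def tissue_filter(pairs, expression, ctx, mode="both_absent"):
    """Pairs retained in an expression context.

    ``both_absent`` (default) removes a pair only when *neither* product is
    detected; ``either_absent`` removes it when at least one is missing.
    """
    sub = expression[expression["context"] == ctx]
    if sub.empty:
        raise KeyError(f"unknown expression context {ctx!r}")
    detected = {g for g, d in zip(sub["gene"], sub["detected"]) if d}
    retained = []
    for p in pairs:
        g1, g2 = tuple(p)
        present = (g1 in detected, g2 in detected)
        if mode == "both_absent":
            keep = any(present)
        elif mode == "either_absent":
            keep = all(present)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if keep:
            retained.append(frozenset(p))
    return retained


def expected_retained(removed_pairs_total, total_pairs, n_unfiltered):
    """Chance expectation ``(1 - removed/total) * N`` of retained SL calls."""
    if total_pairs == 0:
        raise ValueError("total_pairs must be positive")
    if removed_pairs_total > total_pairs:
        raise ValueError("removed_pairs_total exceeds total_pairs")
    if n_unfiltered < 0:
        raise ValueError("N must be non-negative")
    return (1 - removed_pairs_total / total_pairs) * n_unfiltered


@dataclass
class ContextFilterReport:
    context: str
    n_unfiltered: int
    n_removed: int
    n_retained: int
    expected: float
    odds_ratio: float
    p_value: float


def context_filter_report(
    ctx, sl_pairs, retained, removed_pairs_network_wide, total_pairs
):
    """Observed vs expected retention for one context filter.

    Fisher 2x2: SL-call membership x removal, comparing the filter's bite on
    the SL calls against its network-wide bite.
    """
    n = len(sl_pairs)
    n_removed = n - len(retained)
    expected = expected_retained(removed_pairs_network_wide, total_pairs, n)
    tp = n_removed
    fp = len(retained)
    fn = removed_pairs_network_wide - n_removed
    tn = (total_pairs - removed_pairs_network_wide) - len(retained)
    table = _fisher_table(tp, fp, fn, tn)
    return ContextFilterReport(
        context=ctx,
        n_unfiltered=n,
        n_removed=n_removed,
        n_retained=len(retained),
        expected=expected,
        odds_ratio=table.odds_ratio,
        p_value=table.p_value,
    )
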
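"""Enrichment statistics: GO terms, expression profiles, pCRE presence.

All tests share the exact hypergeometric Fisher core from the k-mer module
(one-sided, enrichment in the study group; two-sided available by flag) and
Benjamini-Hochberg step-up correction.  Odds ratios use a 0.5 Haldane
correction when any contingency cell is zero so the log odds ratio stays
finite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .kmers import fisher_pvalues, odds_ratios


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped
    at 1, returned in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _fisher_table(a, b, c, d, two_sided: bool = False):
    if two_sided:
        p = np.array([
            fisher_exact([[ai, bi], [ci, di]], alternative="two-sided")[1]
            for ai, bi, ci, di in zip(
                np.atleast_1d(a), np.atleast_1d(b),
                np.atleast_1d(c), np.atleast_1d(d))
        ])
    else:
        p = fisher_pvalues(a, b, c, d)
    return p, odds_ratios(a, b, c, d)


def go_enrichment(
    study: set[str],
    background: set[str],
    annotations: dict[str, set[str]],
    alpha: float = 0.05,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Per-term Fisher enrichment of the study set vs the rest of the
    background; BH across terms; enriched iff q <= alpha.

    Columns: item a b c d odds_ratio log10_or p q enriched.
    """
    if not study:
        return _empty_rows()
    if not study <= background:
        raise ValueError("study set must be a subset of the background")
    rest = background - study
    if not rest:
        raise ValueError("degenerate-background: study equals background")
    terms = sorted({t for g in background for t in annotations.get(g, ())})
    if not terms:
        raise ValueError("annotations are empty")
    rows = []
    for term in terms:
        with_term = {g for g in background if term in annotations.get(g, ())}
        a = len(study & with_term)
        b = len(study) - a
        c = len(rest & with_term)
        d = len(rest) - c
        rows.append((term, a, b, c, d))
    df = pd.DataFrame(rows, columns=["item", "a", "b", "c", "d"])
    p, orat = _fisher_table(df["a"], df["b"], df["c"], df["d"], two_sided)
    df["odds_ratio"] = orat
    df["log10_or"] = np.log10(orat)
    df["p"] = p
    df["q"] = bh_adjust(p)
    df["enriched"] = df["q"] <= alpha
    return df.sort_values("q", kind="stable").reset_index(drop=True)


def profile_enrichment(
    cluster_genes: set[str],
    comparison_genes: set[str],
    profiles: dict[str, str],
    alpha: float = 0.05,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Per-profile Fisher enrichment of cluster-bearing genes vs genes
    bearing pCREs of other clusters.  Profiles absent from both groups are
    omitted."""
    if not cluster_genes or not comparison_genes:
        raise ValueError("insufficient-background: both gene groups must be non-empty")
    seen = sorted({
        profiles[g] for g in (cluster_genes | comparison_genes) if g in profiles
    })
    rows = []
    for prof in seen:
        a = sum(1 for g in cluster_genes if profiles.get(g) == prof)
        b = len(cluster_genes) - a
        c = sum(1 for g in comparison_genes if profiles.get(g) == prof)
        d = len(comparison_genes) - c
        rows.append((prof, a, b, c, d))
    df = pd.DataFrame(rows, columns=["item", "a", "b", "c", "d"])
    p, orat = _fisher_table(df["a"], df["b"], df["c"], df["d"], two_sided)
    df["odds_ratio"] = orat
    df["log10_or"] = np.log10(orat)
    df["p"] = p
    df["q"] = bh_adjust(p)
    df["enriched"] = df["q"] <= alpha
    return df.sort_values("q", kind="stable").reset_index(drop=True)


def pcre_upregulated_enrichment(
    presence: pd.DataFrame,
    up_genes: set[str],
    negatives: set[str],
    log_base: str = "natural",
    two_sided: bool = False,
) -> pd.DataFrame:
    """Enrichment of each pCRE's presence in up-regulated vs negative genes.

    ``presence`` is a binary genes x pCREs frame.  The log odds ratio column
    is natural-log by default (log10 by flag); BH across the tested pCREs.
    """
    up = sorted(up_genes & set(presence.index))
    neg = sorted(negatives & set(presence.index))
    if not up or not neg:
        raise ValueError("insufficient-background: empty gene group")
    sub_up = presence.loc[up]
    sub_neg = presence.loc[neg]
    a = sub_up.sum(axis=0).to_numpy()
    b = len(up) - a
    c = sub_neg.sum(axis=0).to_numpy()
    d = len(neg) - c
    p, orat = _fisher_table(a, b, c, d, two_sided)
    log_or = np.log(orat) if log_base == "natural" else np.log10(orat)
    df = pd.DataFrame(
        {"item": presence.columns, "a": a, "b": b, "c": c, "d": d,
         "odds_ratio": orat, "log_or": log_or, "p": p, "q": bh_adjust(p)}
    )
    return df.sort_values("q", kind="stable").reset_index(drop=True)


def _empty_rows() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["item", "a", "b", "c", "d", "odds_ratio", "log10_or", "p",
                 "q", "enriched"]
    )
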
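"""GO enrichment of DE genes against an expression-matched background.

Enrichment of a term among differentially expressed genes is judged
against a background matched on expression level: for each DE gene the
k pool genes closest in expression are collected, so the background
mirrors the DE set's expression distribution and expression-correlated
annotation biases cancel.  The background is kept as a multiset (a
pool gene picked for several DE genes is counted each time), which
preserves the k-per-gene matching ratio; a deduplicated variant is
available.  Each term is then tested with Fisher's exact test on the
(in term / not) x (DE / background) table, in both directions.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["matched_background", "go_fisher"]


def matched_background(
    de_genes: Iterable[str],
    expression: Mapping[str, float],
    pool: Iterable[str],
    k: int = 10,
) -> list[str]:
    """k nearest-in-expression pool genes for each DE gene, as a multiset.

    DE genes are removed from the pool first.  Distance is the absolute
    difference in the supplied expression value; ties are broken by
    gene-id order.  The returned list has length k * |DE| and may
    contain repeats.
    """
    de = sorted(set(de_genes))
    pool_ids = sorted(set(pool) - set(de))
    if len(pool_ids) < k:
        raise ValueError(f"pool has {len(pool_ids)} genes but k={k}")
    pool_expr = np.array([expression[g] for g in pool_ids], dtype=float)
    background: list[str] = []
    for g in de:
        d = np.abs(pool_expr - expression[g])
        # pool_ids is id-sorted, so a stable sort on distance breaks
        # ties by gene id
        nearest = np.argsort(d, kind="stable")[:k]
        background.extend(pool_ids[i] for i in nearest)
    return background


def _tail_pair(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """(odds ratio, p_over, p_under) for table [[a, b], [c, d]]."""
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    p_over = stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
    p_under = stats.fisher_exact([[a, b], [c, d]], alternative="less")[1]
    return float(odds), float(p_over), float(p_under)


def go_fisher(
    de_genes: Iterable[str],
    background: Iterable[str],
    term_sets: Mapping[str, set],
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-term Fisher's exact test of DE vs. matched background.

    ``background`` may contain repeats (multiset semantics); each
    occurrence contributes to the table.  Terms absent from both sets
    are skipped.  Columns: term_id, n_de_in_term, n_bg_in_term,
    odds_ratio, p_over, p_under (+ p_over_adj/p_under_adj with
    ``adjust=True``, BH across terms per direction).
    """
    de = list(de_genes)
    bg = list(background)
    if not de or not bg:
        raise ValueError("DE set and background must be non-empty")
    n_de, n_bg = len(de), len(bg)
    rows = []
    for term, members in sorted(term_sets.items()):
        a = sum(g in members for g in de)
        c = sum(g in members for g in bg)
        if a == 0 and c == 0:
            continue
        odds, p_over, p_under = _tail_pair(a, n_de - a, c, n_bg - c)
        rows.append((term, a, c, odds, p_over, p_under))
    df = pd.DataFrame(
        rows,
        columns=["term_id", "n_de_in_term", "n_bg_in_term", "odds_ratio", "p_over", "p_under"],
    )
    if adjust and len(df):
        from xsc.diffexpr import bh_adjust

        df["p_over_adj"] = bh_adjust(df["p_over"].to_numpy())
        df["p_under_adj"] = bh_adjust(df["p_under"].to_numpy())
    return df
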
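"""Pairwise cross-species differential expression on raw counts.

The test is a negative-binomial Wald test with a shared, externally
supplied dispersion alpha (the genome-wide average estimated by
:func:`xsc.expression.estimate_alpha`): group means are fitted on
size-factor-normalized counts, the variance of each log group mean
follows from Var = mu + alpha*mu^2 by the delta method, and the
two-sided p-value comes from the normal reference.  Significance is
called on the Benjamini-Hochberg adjusted p-value, at 0.1 by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DESummary",
    "nb_test",
    "nb_test_matrix",
    "bh_adjust",
    "de_table",
    "summarize_de",
    "lfc_concordance",
]

#: floor (in normalized counts) applied to small group means when
#: forming the log fold change and the delta-method variance
MEAN_FLOOR = 0.5


@dataclass(frozen=True)
class DESummary:
    """Per-cell-type DE summary: percentages of expressed orthologs up/down."""

    cell_type: str
    species_pair: tuple[str, str]
    n_expressed: int
    pct_up: float
    pct_down: float


def nb_test_matrix(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    sf_a: np.ndarray,
    sf_b: np.ndarray,
    alpha: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized NB Wald test over genes.

    Parameters
    ----------
    counts_a, counts_b : int arrays, genes x replicates
        Raw counts per side.
    sf_a, sf_b : float arrays, per replicate
        Positive size factors.
    alpha : float
        Shared NB dispersion (Var = mu + alpha*mu^2), >= 0.

    Returns
    -------
    (mu_a, mu_b, lfc, p, expressed_flag)
        Group means of normalized counts, log2 fold change (a over b,
        floored means), two-sided p-values, and a boolean flag that is
        False for genes with zero counts on both sides (p set to 1,
        lfc to 0).
    """
    counts_a = np.atleast_2d(np.asarray(counts_a, dtype=float))
    counts_b = np.atleast_2d(np.asarray(counts_b, dtype=float))
    sf_a = np.asarray(sf_a, dtype=float)
    sf_b = np.asarray(sf_b, dtype=float)
    if (sf_a <= 0).any() or (sf_b <= 0).any():
        raise ValueError("size factors must be positive")
    if counts_a.shape[1] < 1 or counts_b.shape[1] < 1:
        raise ValueError("each side needs at least one replicate")
    na, nb = counts_a.shape[1], counts_b.shape[1]

    norm_a = counts_a / sf_a
    norm_b = counts_b / sf_b
    mu_a = norm_a.mean(axis=1)
    mu_b = norm_b.mean(axis=1)

    fa = np.maximum(mu_a, MEAN_FLOOR)
    fb = np.maximum(mu_b, MEAN_FLOOR)
    lfc = np.log2(fa / fb)

    # Var(mean of normalized counts) = (1/n^2) sum_i (mu/s_i + alpha*mu^2);
    # delta method gives Var(log mean) = Var(mean) / mean^2.
    var_log_a = (1.0 / fa * np.mean(1.0 / sf_a) + alpha) / na
    var_log_b = (1.0 / fb * np.mean(1.0 / sf_b) + alpha) / nb
    se = np.sqrt(var_log_a + var_log_b)
    z = (np.log(fa) - np.log(fb)) / se
    p = 2.0 * stats.norm.sf(np.abs(z))

    expressed = ~((counts_a.sum(axis=1) == 0) & (counts_b.sum(axis=1) == 0))
    p = np.where(expressed, p, 1.0)
    lfc = np.where(expressed, lfc, 0.0)
    return mu_a, mu_b, lfc, p, expressed


def nb_test(counts_a, counts_b, sf_a, sf_b, alpha: float) -> tuple[float, float]:
    """Single-gene NB Wald test; returns (log2 fold change, p-value)."""
    _, _, lfc, p, _ = nb_test_matrix(
        np.asarray(counts_a)[None, :], np.asarray(counts_b)[None, :], sf_a, sf_b, alpha
    )
    return float(lfc[0]), float(p[0])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_table(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    gene_a: Sequence[str],
    gene_b: Sequence[str],
    sf_a: np.ndarray,
    sf_b: np.ndarray,
    alpha: float,
    fdr: float = 0.1,
    min_expr: float = 5.0,
) -> pd.DataFrame:
    """Full DE table for one cell type over ortholog pairs.

    A gene pair counts as *expressed* when its mean normalized count is
    >= ``min_expr`` in at least one species; BH adjustment runs over
    expressed pairs only and non-expressed pairs get ``p_adj`` = NaN
    and ``is_de`` = False.

    Columns: gene_a, gene_b, base_mean_a, base_mean_b, lfc, p, p_adj,
    is_de, direction ('up' means higher in species a).
    """
    mu_a, mu_b, lfc, p, _ = nb_test_matrix(counts_a, counts_b, sf_a, sf_b, alpha)
    expressed = (mu_a >= min_expr) | (mu_b >= min_expr)
    p_adj = np.full_like(p, np.nan)
    if expressed.any():
        p_adj[expressed] = bh_adjust(p[expressed])
    is_de = expressed & (p_adj < fdr)
    direction = np.where(is_de & (lfc > 0), "up", np.where(is_de & (lfc < 0), "down", "none"))
    return pd.DataFrame(
        {
            "gene_a": list(gene_a),
            "gene_b": list(gene_b),
            "base_mean_a": mu_a,
            "base_mean_b": mu_b,
            "lfc": lfc,
            "p": p,
            "p_adj": p_adj,
            "is_de": is_de,
            "expressed": expressed,
            "direction": direction,
        }
    )


def summarize_de(
    table: pd.DataFrame, cell_type: str, species_pair: tuple[str, str]
) -> DESummary:
    """Percentages of expressed ortholog pairs called up/down."""
    expressed = table[table["expressed"]]
    n = len(expressed)
    if n == 0:
        raise ValueError("no expressed genes in DE table")
    pct_up = 100.0 * float((expressed["direction"] == "up").sum()) / n
    pct_down = 100.0 * float((expressed["direction"] == "down").sum()) / n
    return DESummary(cell_type, tuple(species_pair), n, pct_up, pct_down)


def lfc_concordance(
    lfc_x: Mapping[str, float],
    lfc_y: Mapping[str, float],
    de_x: Mapping[str, bool],
    de_y: Mapping[str, bool],
) -> tuple[float | None, int]:
    """Sign concordance of fold changes over genes DE in both inputs.

    Genes with a zero fold change in either input are excluded.
    Returns (fraction concordant, number of genes compared); the
    fraction is None when no gene qualifies.
    """
    shared = set(lfc_x) & set(lfc_y)
    if not shared:
        raise ValueError("no shared genes between the two fold-change maps")
    used = [
        g
        for g in shared
        if de_x.get(g, False) and de_y.get(g, False) and lfc_x[g] != 0 and lfc_y[g] != 0
    ]
    if not used:
        return None, 0
    conc = sum(1 for g in used if np.sign(lfc_x[g]) == np.sign(lfc_y[g]))
    return conc / len(used), len(used)
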
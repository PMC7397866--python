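"""Integrative correlation coefficient (correlation-of-correlations) and AFA.

For each species separately, a gene x gene correlation matrix across
cell types is computed; the integrative correlation coefficient (ICC)
of gene g is the Pearson correlation between row g of the species-A
matrix and row g of the species-B matrix, with the self-correlation
entries (identically 1) removed.  High ICC means the gene keeps the
same co-expression partners in both species.  The null distribution
comes from shuffling the cell-type columns of one species before
building its correlation matrix.  Analysis of Functional Annotation
(AFA) ranks genes by a score (here the ICC) and tests each annotation
term by a one-sided Wilcoxon rank-sum against the remaining genes.

The gene x gene correlation matrix is never materialized in full:
rows are processed in blocks, and the self-entry is removed from the
ICC moments analytically (its contribution to every sum is exactly 1).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from xsc.diffexpr import bh_adjust

__all__ = ["quantile_normalize", "integrative_correlation", "icc_null", "afa"]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column to the same distribution (mean of sorted columns).

    The target vector is the row-wise mean of the per-column sorted
    values; each column's values are replaced by the target value at
    their rank, with tied values receiving the mean of the target
    values their tie block spans.
    """
    x = matrix.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing values not supported")
    target = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        ranked = np.empty_like(target)
        ranked[order] = target
        # average target values over ties so equal inputs map to equal outputs
        vals, inv = np.unique(col, return_inverse=True)
        if len(vals) < len(col):
            sums = np.bincount(inv, weights=ranked)
            cnts = np.bincount(inv)
            ranked = (sums / cnts)[inv]
        out[:, j] = ranked
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _standardize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows scaled so that z @ z.T gives Pearson correlations; flags degenerate rows."""
    c = x - x.mean(axis=1, keepdims=True)
    norm = np.sqrt((c**2).sum(axis=1))
    degenerate = norm == 0
    norm[degenerate] = 1.0
    return c / norm[:, None], degenerate


def integrative_correlation(
    expr_a: pd.DataFrame, expr_b: pd.DataFrame, block_size: int = 2048
) -> pd.DataFrame:
    """Per-gene correlation-of-correlations between two species.

    Rows of the two frames are matched ortholog pairs; columns are the
    cell types of each species (>= 3 each, equal count so correlation-
    matrix rows align).  Genes with a constant profile in either
    species have no defined correlations and get ICC NaN; they are
    also excluded from every other gene's row comparison.

    Returns a frame indexed like ``expr_a`` with columns ``icc`` and
    ``defined``.
    """
    if expr_a.shape[0] != expr_b.shape[0]:
        raise ValueError("matrices must have matched ortholog rows")
    if expr_a.shape[1] < 3 or expr_b.shape[1] < 3:
        raise ValueError("need >= 3 cell types per species")
    if expr_a.shape[1] != expr_b.shape[1]:
        raise ValueError("cell-type counts must match between species")
    za, dega = _standardize_rows(expr_a.to_numpy(dtype=float))
    zb, degb = _standardize_rows(expr_b.to_numpy(dtype=float))
    degenerate = dega | degb
    valid = ~degenerate
    zav = za[valid]
    zbv = zb[valid]
    n_valid = int(valid.sum())
    icc = np.full(expr_a.shape[0], np.nan)

    idx_valid = np.flatnonzero(valid)
    for start in range(0, n_valid, block_size):
        stop = min(start + block_size, n_valid)
        # correlation-matrix rows restricted to valid genes
        u = zav[start:stop] @ zav.T  # block x n_valid
        v = zbv[start:stop] @ zbv.T
        # moments over all valid columns, then remove the self entry
        # (u_ii = v_ii = 1 exactly) from every sum
        m = n_valid - 1
        su = u.sum(axis=1) - 1.0
        sv = v.sum(axis=1) - 1.0
        suu = (u**2).sum(axis=1) - 1.0
        svv = (v**2).sum(axis=1) - 1.0
        suv = (u * v).sum(axis=1) - 1.0
        cov = suv - su * sv / m
        var_u = suu - su**2 / m
        var_v = svv - sv**2 / m
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov / np.sqrt(var_u * var_v)
        r[(var_u <= 0) | (var_v <= 0)] = np.nan
        icc[idx_valid[start:stop]] = np.clip(r, -1.0, 1.0)

    return pd.DataFrame({"icc": icc, "defined": ~np.isnan(icc)}, index=expr_a.index)


def icc_null(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
    block_size: int = 2048,
) -> np.ndarray:
    """Sample-permutation null for the ICC.

    Each permutation shuffles the sample (cell-type) assignment of
    species B independently per gene before building its correlation
    matrix.  A permutation common to all genes would leave the
    gene x gene correlation matrix — and hence every ICC — exactly
    unchanged, so the shuffle must be per gene to destroy the
    co-expression structure.  ICC values are pooled across genes and
    permutations.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    b = expr_b.to_numpy()
    out: list[np.ndarray] = []
    for _ in range(n_perm):
        # independent column permutation per row
        keys = rng.random(b.shape)
        perm = np.argsort(keys, axis=1)
        shuffled = pd.DataFrame(
            np.take_along_axis(b, perm, axis=1), index=expr_b.index, columns=expr_b.columns
        )
        vals = integrative_correlation(expr_a, shuffled, block_size)["icc"].to_numpy()
        out.append(vals[~np.isnan(vals)])
    return np.concatenate(out)


def afa(
    scores: Mapping[str, float],
    term_sets: Mapping[str, set],
    min_genes: int = 10,
) -> pd.DataFrame:
    """Analysis of Functional Annotation over a gene-level score.

    Each term with at least ``min_genes`` scored genes is tested by a
    one-sided Wilcoxon rank-sum in both directions (term genes ranked
    high vs. ranked low relative to the remaining genes); the smaller
    direction labels the term, and BH adjustment runs across terms
    within each direction.

    Returns a frame with columns term_id, n_genes, p_high, p_low,
    direction, p_raw, p_adj (empty, with a warning, when no term
    qualifies).
    """
    import warnings

    gene_ids = np.array(sorted(scores))
    vals = np.array([scores[g] for g in gene_ids], dtype=float)
    rows = []
    for term, members in sorted(term_sets.items()):
        mask = np.isin(gene_ids, list(members))
        n = int(mask.sum())
        if n < min_genes or n == len(gene_ids):
            continue
        inside, outside = vals[mask], vals[~mask]
        # exact rank-sum distribution when small and tie-free, else the
        # tie-corrected normal approximation
        method = "exact" if len(vals) <= 60 and len(np.unique(vals)) == len(vals) else "asymptotic"
        p_high = float(
            stats.mannwhitneyu(inside, outside, alternative="greater", method=method).pvalue
        )
        p_low = float(
            stats.mannwhitneyu(inside, outside, alternative="less", method=method).pvalue
        )
        rows.append((term, n, p_high, p_low))
    if not rows:
        warnings.warn(f"no term has >= {min_genes} scored genes")
        return pd.DataFrame(
            columns=["term_id", "n_genes", "p_high", "p_low", "direction", "p_raw", "p_adj"]
        )
    df = pd.DataFrame(rows, columns=["term_id", "n_genes", "p_high", "p_low"])
    df["direction"] = np.where(df["p_high"] <= df["p_low"], "high_ranked", "low_ranked")
    df["p_raw"] = df[["p_high", "p_low"]].min(axis=1)
    adj_high = bh_adjust(df["p_high"].to_numpy())
    adj_low = bh_adjust(df["p_low"].to_numpy())
    df["p_adj"] = np.where(df["direction"] == "high_ranked", adj_high, adj_low)
    return df
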
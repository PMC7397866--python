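"""Motif activity decomposition (MARA-style) and activity comparisons.

Expression of regulatory elements is modelled as a linear combination
of per-motif activities weighted by predicted TFBS counts:

    E_ps = c_s + sum_m N_pm * A_ms + eps,

where E is elements x samples expression (VST or log scale), N is the
elements x motifs TFBS count matrix, A the motif x samples activity
matrix, and c_s a per-sample intercept.  A is obtained per sample by
ridge regression of the column-centered expression on the
column-centered design, A_.s = (Nc'Nc + lambda I)^-1 Nc' (E_.s - mean(E_.s))
with Nc = N - colmean(N) so the intercept absorbs the design's mean
TFBS load, and activity rows
are centered across samples afterwards so that cross-species
comparisons are location-free.

Matched-motif activity correlations across species (or between
promoter- and enhancer-derived models) are judged against a background
of mismatched motif pairs with a one-sided Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from xsc.conservation import compare_to_null, rowwise_pearson

__all__ = ["MotifModel", "fit_activities", "compare_activities", "promoter_vs_enhancer"]


@dataclass
class MotifModel:
    """Fitted decomposition: TFBS design N, activities A, intercepts, penalty."""

    N: pd.DataFrame  # elements x motifs
    A: pd.DataFrame  # motifs x samples, row-centered
    intercepts: pd.Series  # per sample
    lam: float


def fit_activities(E: pd.DataFrame, N: pd.DataFrame, lam: float | None = None) -> MotifModel:
    """Ridge decomposition of element expression over a TFBS count matrix.

    Parameters
    ----------
    E : DataFrame, elements x samples
        Expression on a log-like scale (VST for promoters,
        log2(1 + normalized count) for enhancers).
    N : DataFrame, elements x motifs
        Non-negative predicted TFBS counts; rows must align with E.
    lam : float, optional
        Ridge penalty on the activities.  Defaults to
        ``n_elements * 1e-3``.  ``lam=0`` requires N of full column
        rank.
    """
    if E.shape[0] != N.shape[0]:
        raise ValueError("E and N must have the same elements (rows)")
    if lam is None:
        lam = E.shape[0] * 1e-3
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    Nv = N.to_numpy(dtype=float)
    Ev = E.to_numpy(dtype=float)
    if lam == 0 and np.linalg.matrix_rank(Nv) < Nv.shape[1]:
        raise ValueError("N is rank-deficient; use lambda > 0")
    intercepts = Ev.mean(axis=0)
    # column-center both sides so the per-sample intercept absorbs the
    # mean TFBS load; otherwise activities pick up a rank-one bias along
    # the design's column means
    Nc = Nv - Nv.mean(axis=0)
    Ec = Ev - intercepts
    if lam == 0:
        A = np.linalg.lstsq(Nc, Ec, rcond=None)[0]
    else:
        A = np.linalg.solve(Nc.T @ Nc + lam * np.eye(Nv.shape[1]), Nc.T @ Ec)
    A = A - A.mean(axis=1, keepdims=True)
    return MotifModel(
        N=N,
        A=pd.DataFrame(A, index=N.columns, columns=E.columns),
        intercepts=pd.Series(intercepts, index=E.columns),
        lam=float(lam),
    )


def _mismatched_pairs(n_motifs: int, max_exhaustive: int = 200, n_sample: int = 10000,
                      seed: int | None = None) -> np.ndarray:
    """Ordered (i, j), i != j: exhaustive when small, else seeded sample."""
    if n_motifs <= max_exhaustive:
        idx = np.array([(i, j) for i in range(n_motifs) for j in range(n_motifs) if i != j])
        return idx
    rng = np.random.default_rng(seed)
    i = rng.integers(0, n_motifs, size=n_sample)
    j = rng.integers(0, n_motifs - 1, size=n_sample)
    j = np.where(j >= i, j + 1, j)
    return np.column_stack([i, j])


def compare_activities(
    model_a: MotifModel,
    model_b: MotifModel,
    matched_samples: list[tuple[str, str]] | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, float, float]:
    """Matched-motif activity correlation vs. mismatched-pair background.

    ``matched_samples`` pairs sample (cell-type) labels of the two
    models; by default columns are matched by identical label.  The
    per-motif Pearson r across matched samples is compared to the
    correlations of mismatched motif pairs with a one-sided
    Mann-Whitney U test (matched greater).

    Returns (per-motif frame with columns motif_id and r_matched,
    U statistic, p-value).
    """
    motifs = [m for m in model_a.A.index if m in set(model_b.A.index)]
    if not motifs:
        raise ValueError("models share no motifs")
    if matched_samples is None:
        shared = [s for s in model_a.A.columns if s in set(model_b.A.columns)]
        matched_samples = [(s, s) for s in shared]
    if len(matched_samples) < 3:
        raise ValueError("need >= 3 matched samples")
    cols_a = [a for a, _ in matched_samples]
    cols_b = [b for _, b in matched_samples]
    Aa = model_a.A.loc[motifs, cols_a].to_numpy()
    Ab = model_b.A.loc[motifs, cols_b].to_numpy()
    r_matched = rowwise_pearson(Aa, Ab)
    pairs = _mismatched_pairs(len(motifs), seed=seed)
    null_rs = rowwise_pearson(Aa[pairs[:, 0]], Ab[pairs[:, 1]])
    obs = r_matched[~np.isnan(r_matched)]
    null = null_rs[~np.isnan(null_rs)]
    u, p = compare_to_null(obs, null)
    table = pd.DataFrame({"motif_id": motifs, "r_matched": r_matched})
    return table, u, p


def promoter_vs_enhancer(
    model_prom: MotifModel, model_enh: MotifModel, seed: int | None = None
) -> tuple[pd.DataFrame, float, float]:
    """Within-species comparison of promoter- and enhancer-derived activities.

    Identical machinery to :func:`compare_activities` with the sample
    matching being the shared sample set of the two models.
    """
    return compare_activities(model_prom, model_enh, seed=seed)
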
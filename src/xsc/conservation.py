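"""Conservation correlations, permutation/theoretical nulls, and stratified trend tests.

Per-gene conservation is the Pearson correlation across matched cell
types between the expression profiles of an ortholog pair; per-cell-type
conservation is the correlation across ortholog pairs within one cell
type.  Three null distributions accompany the per-gene correlations:

* ``gene_permute`` — shuffle which gene in species B is paired with
  each gene in species A;
* ``sample_permute`` — shuffle the cell-type columns of one matrix,
  destroying the cell-type matching while keeping each gene pair;
* ``theoretical_normal`` — the exact distribution of Pearson's r for n
  paired observations from an uncorrelated bivariate normal,
  f(r) = (1 - r^2)^((n-4)/2) / B(1/2, (n-2)/2), realised as a scaled
  Beta((n-2)/2, (n-2)/2) on [-1, 1].

Observed and null correlation sets are compared with a one-sided
Mann-Whitney U test.  Evolutionary-age trends in DE fractions are
tested by Poisson regression of per-class DE counts on an equidistant
class score (with a log class-size offset) using a likelihood-ratio
test, and p-values across pairwise species comparisons are combined by
Fisher's method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AGE_CLASSES",
    "AgeTrendResult",
    "rowwise_pearson",
    "pergene_correlation",
    "pergroup_correlation",
    "theoretical_r_distribution",
    "correlation_null",
    "compare_to_null",
    "stratified_fisher",
    "age_trend",
    "age_trend_counts",
    "fisher_combine",
]

#: ordered oldest -> youngest; the equidistant score k is the position here
AGE_CLASSES = ("bilateria", "vertebrate", "mammal")


@dataclass(frozen=True)
class AgeTrendResult:
    """Poisson-regression trend of DE fraction over ordered age classes.

    ``slope`` is the per-class log-rate increment (positive = more DE
    in younger classes); ``p_one_sided`` tests slope > 0.
    """

    slope: float
    intercept: float
    lrt_stat: float
    p_one_sided: float
    class_counts: dict[str, tuple[int, int]]


def rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between corresponding rows of two equal-shape matrices.

    Rows that are constant in either matrix yield NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = (ac * bc).sum(axis=1)
    den = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


def _check_matched(expr_a: pd.DataFrame, expr_b: pd.DataFrame, min_cols: int) -> None:
    if expr_a.shape != expr_b.shape:
        raise ValueError("expression matrices must have matching shapes")
    if expr_a.shape[1] < min_cols:
        raise ValueError(f"need >= {min_cols} shared cell types, got {expr_a.shape[1]}")


def pergene_correlation(expr_a: pd.DataFrame, expr_b: pd.DataFrame) -> pd.DataFrame:
    """Per-ortholog-pair Pearson r across matched cell-type columns.

    Rows of the two frames are matched ortholog pairs (same order);
    columns are matched cell types (>= 3).  Pairs with a constant
    profile in either species have undefined r and are returned with
    NaN; callers can count them via the ``defined`` column.
    """
    _check_matched(expr_a, expr_b, 3)
    r = rowwise_pearson(expr_a.to_numpy(), expr_b.to_numpy())
    return pd.DataFrame(
        {"r": r, "n": expr_a.shape[1], "defined": ~np.isnan(r)}, index=expr_a.index
    )


def pergroup_correlation(expr_a: pd.DataFrame, expr_b: pd.DataFrame) -> pd.DataFrame:
    """Per-cell-type Pearson r across ortholog pairs (matrices transposed)."""
    _check_matched(expr_a, expr_b, 1)
    if expr_a.shape[0] < 3:
        raise ValueError("need >= 3 ortholog pairs")
    r = rowwise_pearson(expr_a.to_numpy().T, expr_b.to_numpy().T)
    return pd.DataFrame(
        {"r": r, "n": expr_a.shape[0], "defined": ~np.isnan(r)},
        index=expr_a.columns,
    )


def theoretical_r_distribution(n: int):
    """Distribution of Pearson's r under an uncorrelated bivariate normal.

    For n paired observations, (r + 1)/2 ~ Beta((n-2)/2, (n-2)/2), so
    the returned frozen scipy distribution has support [-1, 1],
    density proportional to (1 - r^2)^((n-4)/2), and Var(r) = 1/(n-1).
    Requires n >= 4.
    """
    if n < 4:
        raise ValueError(f"theoretical null needs n >= 4 observations, got {n}")
    a = (n - 2) / 2.0
    return stats.beta(a, a, loc=-1.0, scale=2.0)


def correlation_null(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    kind: str = "gene_permute",
    n_draws: int = 1,
    seed: int | None = None,
):
    """Null distribution of per-gene correlations.

    ``gene_permute`` re-pairs the rows of ``expr_b`` at random;
    ``sample_permute`` shuffles the columns of ``expr_b`` independently
    per draw; both pool the resulting row-wise correlations over
    ``n_draws`` draws and return a 1-D array (NaNs from constant rows
    dropped).  ``theoretical_normal`` ignores draws and returns the
    frozen distribution from :func:`theoretical_r_distribution` for
    n = number of columns.
    """
    _check_matched(expr_a, expr_b, 3)
    if kind == "theoretical_normal":
        return theoretical_r_distribution(expr_a.shape[1])
    if kind not in ("gene_permute", "sample_permute"):
        raise ValueError(f"unknown null kind {kind!r}")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1 for permutation nulls")
    rng = np.random.default_rng(seed)
    a = expr_a.to_numpy()
    b = expr_b.to_numpy()
    out: list[np.ndarray] = []
    for _ in range(n_draws):
        if kind == "gene_permute":
            perm = rng.permutation(b.shape[0])
            r = rowwise_pearson(a, b[perm])
        else:
            perm = rng.permutation(b.shape[1])
            r = rowwise_pearson(a, b[:, perm])
        out.append(r[~np.isnan(r)])
    return np.concatenate(out)


def compare_to_null(observed, null) -> tuple[float, float]:
    """One-sided Mann-Whitney U: are observed correlations stochastically greater?

    Uses the normal approximation with tie correction.  Returns
    (U statistic, one-sided p-value).
    """
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float)
    if observed.size == 0 or null.size == 0:
        raise ValueError("both correlation sets must be non-empty")
    res = stats.mannwhitneyu(observed, null, alternative="greater", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def stratified_fisher(
    de_flags: Mapping[str, bool], stratum: Mapping[str, bool]
) -> tuple[float, float]:
    """Fisher's exact test for DE enrichment in the flagged stratum.

    ``stratum[g]`` is True for genes in the stratum expected to carry
    more DE (e.g. dominant promoter without an orthologous region).
    The 2x2 table is (DE x stratum) and the one-sided alternative is
    that the flagged stratum has a higher DE rate.  Returns the sample
    odds ratio (ad/bc, inf when bc = 0) and the exact hypergeometric
    one-sided p-value.
    """
    genes = list(de_flags)
    in_stratum = np.array([bool(stratum[g]) for g in genes])
    de = np.array([bool(de_flags[g]) for g in genes])
    if in_stratum.all() or not in_stratum.any():
        raise ValueError("both strata must be non-empty")
    a = int((de & in_stratum).sum())
    b = int((de & ~in_stratum).sum())
    c = int((~de & in_stratum).sum())
    d = int((~de & ~in_stratum).sum())
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds), float(p)


def _poisson_trend_fit(y: np.ndarray, offset: np.ndarray, k: np.ndarray) -> tuple[float, float, float]:
    """Newton fit of y_k ~ Poisson(exp(a + b*k + offset_k)); returns (a, b, loglik)."""
    X = np.column_stack([np.ones_like(k, dtype=float), k.astype(float)])
    beta = np.array([np.log(max(y.sum(), 0.5)) - np.log(np.exp(offset).sum()), 0.0])
    for _ in range(100):
        eta = X @ beta + offset
        mu = np.exp(eta)
        grad = X.T @ (y - mu)
        hess = X.T @ (mu[:, None] * X)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        # dampen large Newton steps for stability far from the optimum
        norm = np.abs(step).max()
        if norm > 5.0:
            step *= 5.0 / norm
        beta = beta + step
        if np.abs(step).max() < 1e-12:
            break
    eta = X @ beta + offset
    ll = float((y * eta - np.exp(eta)).sum())
    return float(beta[0]), float(beta[1]), ll


def age_trend_counts(
    n_de: Sequence[int],
    n_total: Sequence[int],
    scores: Sequence[float] | None = None,
    use_offset: bool = True,
    class_names: Sequence[str] = AGE_CLASSES,
) -> AgeTrendResult:
    """Poisson trend test on per-class (DE count, class size) pairs.

    The per-class DE count is modelled as Poisson with log rate
    a + b*k plus, by default, a log(class size) offset so that unequal
    class sizes do not confound the trend; k is the equidistant class
    score (0, 1, 2, ... oldest first by default).  The likelihood-ratio
    statistic against b = 0 is referred to chi-square(1); the one-sided
    p-value takes p_two/2 when the fitted slope is positive (more DE
    among younger classes) and 1 - p_two/2 otherwise.
    """
    y = np.asarray(n_de, dtype=float)
    n = np.asarray(n_total, dtype=float)
    if len(y) != len(n) or len(y) < 2:
        raise ValueError("need >= 2 classes of (n_de, n_total)")
    k = np.arange(len(y), dtype=float) if scores is None else np.asarray(scores, dtype=float)
    offset = np.log(n) if use_offset else np.zeros_like(n)
    counts = {
        str(class_names[i]) if i < len(class_names) else str(i): (int(y[i]), int(n[i]))
        for i in range(len(y))
    }
    if y.sum() == 0:
        return AgeTrendResult(0.0, -np.inf, 0.0, 1.0, counts)

    a1, b1, ll1 = _poisson_trend_fit(y, offset, k)
    # null: slope fixed at 0 -> closed-form MLE a = log(sum y / sum exp(offset))
    a0 = np.log(y.sum()) - np.log(np.exp(offset).sum())
    eta0 = a0 + offset
    ll0 = float((y * eta0 - np.exp(eta0)).sum())
    lrt = max(2.0 * (ll1 - ll0), 0.0)
    p_two = float(stats.chi2.sf(lrt, df=1))
    p_one = p_two / 2.0 if b1 > 0 else 1.0 - p_two / 2.0
    return AgeTrendResult(b1, a1, lrt, p_one, counts)


def age_trend(
    de_flags: Mapping[str, bool],
    age_class: Mapping[str, str],
    classes: Sequence[str] = AGE_CLASSES,
    use_offset: bool = True,
) -> AgeTrendResult:
    """Trend of DE fraction over ordered evolutionary-age classes.

    Tabulates per-class (DE, total) counts from per-gene flags and
    class labels, then applies :func:`age_trend_counts` with classes
    scored equidistantly, oldest first (bilateria=0, vertebrate=1,
    mammal=2 by default).  Classes with no genes are dropped with a
    warning; at least two populated classes are required.
    """
    counts: dict[str, tuple[int, int]] = {}
    for cls in classes:
        genes = [g for g in de_flags if age_class.get(g) == cls]
        counts[cls] = (sum(bool(de_flags[g]) for g in genes), len(genes))
    kept = [cls for cls in classes if counts[cls][1] > 0]
    dropped = [cls for cls in classes if counts[cls][1] == 0]
    if dropped:
        warnings.warn(f"age classes with no genes dropped: {dropped}")
    if len(kept) < 2:
        raise ValueError("need >= 2 age classes with genes")
    res = age_trend_counts(
        [counts[c][0] for c in kept],
        [counts[c][1] for c in kept],
        scores=[float(classes.index(c)) for c in kept],
        use_offset=use_offset,
        class_names=kept,
    )
    return AgeTrendResult(res.slope, res.intercept, res.lrt_stat, res.p_one_sided, counts)


def fisher_combine(p_values) -> float:
    """Fisher's method: X^2 = -2 sum(ln p) against chi-square(2m)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if (p > 1).any() or (p < 0).any():
        raise ValueError("p-values must lie in [0, 1]")
    if (p == 0).any():
        warnings.warn("zero p-values clipped to smallest positive normal")
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    x2 = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x2, df=2 * p.size))
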
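"""Count-matrix data model, normalization, and the variance-stabilizing transform.

The count matrix is genes x samples, with each sample annotated by
species, cell type, and replicate.  Normalization follows the
total-count / median convention: each sample's total tag count is
divided by the median of the totals across samples, and counts are
divided by the resulting factor.  Dispersion is estimated per
(species, cell type) replicate group by method of moments under the
NB parameterization Var = mu + alpha * mu^2 and averaged across groups
to a single alpha consumed by the VST and the differential-expression
test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleInfo",
    "VSTParams",
    "PromoterRegion",
    "size_factors",
    "normalize_counts",
    "estimate_alpha",
    "vst",
    "average_replicates",
    "dominant_promoter",
    "merge_intervals",
    "filter_by_n_fraction",
]

LN2 = np.log(2.0)


@dataclass(frozen=True)
class SampleInfo:
    """Annotation of a single library: species, cell type, replicate index."""

    sample_id: str
    species: str
    cell_type: str
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")


class CountMatrix:
    """Non-negative integer expression counts (genes x samples) with sample annotations.

    Parameters
    ----------
    counts : DataFrame
        Genes x samples, non-negative integers; index = gene ids,
        columns = sample ids.
    samples : sequence of SampleInfo or DataFrame
        One record per column of ``counts``, in column order.  A
        DataFrame must have columns sample_id, species, cell_type,
        replicate.
    """

    def __init__(self, counts: pd.DataFrame, samples) -> None:
        if isinstance(samples, pd.DataFrame):
            samples = [
                SampleInfo(str(r.sample_id), str(r.species), str(r.cell_type), int(r.replicate))
                for r in samples.itertuples(index=False)
            ]
        samples = list(samples)
        if len(samples) != counts.shape[1]:
            raise ValueError(
                f"{len(samples)} sample records for {counts.shape[1]} count columns"
            )
        if not counts.index.is_unique:
            raise ValueError("gene ids are not unique")
        keys = [(s.species, s.cell_type, s.replicate) for s in samples]
        if len(set(keys)) != len(keys):
            raise ValueError("(species, cell_type, replicate) not unique across samples")
        vals = counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("negative counts")
        self.counts = counts
        self.samples = samples

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "species": [s.species for s in self.samples],
                "cell_type": [s.cell_type for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )

    def __repr__(self) -> str:  # pragma: no cover
        g, s = self.counts.shape
        return f"CountMatrix({g} genes x {s} samples)"

    # --- TSV round-trip -------------------------------------------------
    def to_tsv(self, counts_path, samples_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
        self.sample_frame.to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        counts.index.name = None
        samples = pd.read_csv(samples_path, sep="\t")
        return cls(counts, samples)


@dataclass(frozen=True)
class VSTParams:
    """Average asymptotic dispersion alpha and per-sample size factors."""

    alpha: float
    size_factors: pd.Series

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        med = float(np.median(self.size_factors.to_numpy()))
        if abs(med - 1.0) > 1e-9:
            raise ValueError(f"median of size factors must be 1, got {med}")


@dataclass(frozen=True)
class PromoterRegion:
    """Merged, disjoint promoter spans of one gene (0-based half-open)."""

    gene_id: str
    chrom: str
    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for start, end in self.intervals:
            if end <= start:
                raise ValueError(f"empty span ({start}, {end}) for {self.gene_id}")
            if start < prev_end:
                raise ValueError(f"intervals of {self.gene_id} overlap or are unsorted")
            prev_end = end


def size_factors(matrix: CountMatrix) -> pd.Series:
    """Total-count size factors: per-sample totals divided by their median.

    Normalized counts are ``counts / factor`` per sample.  The median
    of the returned factors is 1 by construction.

    Raises
    ------
    ValueError
        If any sample has a zero total, naming the sample.
    """
    totals = matrix.counts.sum(axis=0).astype(float)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total count: {', '.join(map(str, zero.index))}")
    return totals / float(np.median(totals.to_numpy()))


def normalize_counts(matrix: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts divided by per-sample size factors."""
    if factors is None:
        factors = size_factors(matrix)
    return matrix.counts / factors


def _group_alpha(norm: np.ndarray, trim: float = 0.1) -> float:
    """Method-of-moments dispersion for one replicate group (genes x reps).

    Per gene, alpha_g = (s^2 - m) / m^2 from the sample mean and
    variance of normalized counts; a trimmed mean (``trim`` of each
    tail) across genes with positive mean gives the group estimate,
    floored at 0.
    """
    m = norm.mean(axis=1)
    v = norm.var(axis=1, ddof=1)
    keep = m > 0
    if not keep.any():
        return 0.0
    a = (v[keep] - m[keep]) / m[keep] ** 2
    a = np.sort(a)
    k = int(len(a) * trim)
    if len(a) - 2 * k <= 0:
        k = 0
    return float(max(a[k : len(a) - k].mean(), 0.0))


def estimate_alpha(matrix: CountMatrix, factors: pd.Series | None = None) -> float:
    """Average asymptotic NB dispersion across (species, cell type) groups.

    Dispersion is estimated within each replicate group that has at
    least two replicates, on size-factor-normalized counts, and the
    unweighted arithmetic mean across groups is returned.

    Raises
    ------
    ValueError
        If no group has >= 2 replicates; supply alpha explicitly then.
    """
    norm = normalize_counts(matrix, factors).to_numpy()
    cols_by_group: dict[tuple[str, str], list[int]] = {}
    for j, s in enumerate(matrix.samples):
        cols_by_group.setdefault((s.species, s.cell_type), []).append(j)
    estimates = [
        _group_alpha(norm[:, cols]) for cols in cols_by_group.values() if len(cols) >= 2
    ]
    if not estimates:
        raise ValueError(
            "no (species, cell type) group has >= 2 replicates; "
            "dispersion cannot be estimated — supply alpha explicitly"
        )
    return float(np.mean(estimates))


def vst(x, alpha: float):
    """Variance-stabilizing transform of normalized NB counts.

    ``(2*asinh(sqrt(alpha*x)) - ln(alpha) - ln(4)) / ln(2)``, applied
    elementwise.  Strictly increasing in x, and for large x converges
    to log2(x), so downstream log-scale analyses read it as a log2-like
    expression value.  Under Var = mu + alpha*mu^2 the transform
    renders the variance approximately independent of the mean.

    Parameters
    ----------
    x : array-like or scalar
        Normalized counts, >= 0.
    alpha : float
        NB dispersion, > 0.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    arr = np.asarray(x, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative values passed to vst")
    out = (2.0 * np.arcsinh(np.sqrt(alpha * arr)) - np.log(alpha) - np.log(4.0)) / LN2
    if isinstance(x, pd.DataFrame):
        return pd.DataFrame(out, index=x.index, columns=x.columns)
    if isinstance(x, pd.Series):
        return pd.Series(out, index=x.index)
    if np.isscalar(x):
        return float(out)
    return out


def average_replicates(values: pd.DataFrame, samples: Sequence[SampleInfo]) -> pd.DataFrame:
    """Mean across replicates within each (species, cell type) group.

    Returns a genes x groups frame whose columns are a MultiIndex
    (species, cell_type) sorted lexicographically, making column order
    deterministic.
    """
    if len(samples) != values.shape[1]:
        raise ValueError("sample records do not match value columns")
    groups: dict[tuple[str, str], list[str]] = {}
    for s, col in zip(samples, values.columns):
        groups.setdefault((s.species, s.cell_type), []).append(col)
    keys = sorted(groups)
    data = {k: values[groups[k]].mean(axis=1) for k in keys}
    out = pd.DataFrame(data)
    out.columns = pd.MultiIndex.from_tuples(keys, names=["species", "cell_type"])
    return out


def dominant_promoter(totals: Mapping[str, float], starts: Mapping[str, int] | None = None) -> str:
    """The most highly expressed promoter of a gene.

    ``totals`` maps promoter id to summed expression across all
    samples.  Ties are broken by the lowest genomic start coordinate
    when ``starts`` is given, else by promoter-id order.
    """
    if not totals:
        raise ValueError("gene has no promoters")
    best = max(totals.values())
    tied = [p for p, t in totals.items() if t == best]
    if len(tied) == 1:
        return tied[0]
    if starts is not None:
        return min(tied, key=lambda p: (starts[p], p))
    return min(tied)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Merge overlapping/adjacent 0-based half-open spans into disjoint sorted spans."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for start, end in ivs:
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return tuple((a, b) for a, b in merged)


def filter_by_n_fraction(
    regions: Sequence[PromoterRegion], fasta_path, max_n_frac: float = 0.10
) -> list[str]:
    """Gene ids whose promoter regions all pass the N-content filter.

    A gene is removed iff *any* of its merged regions has a fraction of
    unidentified nucleotides (N/n) strictly greater than ``max_n_frac``.
    Regions are clipped to chromosome bounds before counting, and the
    fraction is computed over the clipped length.
    """
    from pyfaidx import Fasta

    fasta = Fasta(str(fasta_path))
    retained: list[str] = []
    for region in regions:
        if region.chrom not in fasta:
            raise ValueError(f"chromosome {region.chrom!r} missing from FASTA")
        chrom_len = len(fasta[region.chrom])
        bad = False
        for start, end in region.intervals:
            s, e = max(start, 0), min(end, chrom_len)
            if e <= s:
                continue
            seq = str(fasta[region.chrom][s:e]).upper()
            if seq.count("N") / len(seq) > max_n_frac:
                bad = True
                break
        if not bad:
            retained.append(region.gene_id)
    return retained
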
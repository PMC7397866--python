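"""Synthetic cross-species expression data with planted ground truth.

Emulates the statistical structure of a two-species primary-cell
expression compendium at the gene/promoter level: negative-binomial
counts per ortholog pair over a handful of cell types with a few
replicates each, a tunable fraction of orthologs whose expression has
diverged (a log2 fold-change shift in the second species), an
evolutionary-age classification with a planted monotone divergence
trend, a promoter-orthology flag with planted DE enrichment, GO-like
term assignments with one term enriched among divergent genes, and a
planted motif-activity model E = N.A + noise whose activities are
correlated across the two species.  Read-level phenomena (sequencing
error, mapping, peak calling) are out of scope.

The negative binomial is parameterized by Var = mu + alpha * mu^2,
the same dispersion sense the variance-stabilizing transform assumes.
Divergence probability follows a logistic model
logit p = logit(f) + age_effect * (k - E[k]) + promoter_effect * (z - E[z]),
with k the equidistant age score (bilateria=0 .. mammal=2), z the
indicator of a non-orthologous promoter, and f the configured marginal
divergent fraction; the centering keeps the marginal rate at f.
Divergence direction is drawn symmetrically (+/- divergent_lfc).

Each output artifact draws from its own RNG stream split from the
master seed, so regenerating one artifact never perturbs the others.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from xsc.expression import CountMatrix, SampleInfo
from xsc.conservation import AGE_CLASSES

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_counts",
    "generate_motif_data",
    "generate_promoter_fasta",
    "simulate_to_dir",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the generator; ``seed`` fully determines every output."""

    n_genes: int = 2000
    n_cell_types: int = 8
    n_replicates: int = 3
    species_pair: tuple[str, str] = ("human", "mouse")
    dispersion_alpha: float = 0.05
    divergent_fraction: float = 0.3
    divergent_lfc: float = 2.0
    age_class_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)
    age_effect: float = 1.0
    promoter_nonortho_fraction: float = 0.15
    promoter_effect: float = 1.0
    n_go_terms: int = 20
    go_effect: float = 2.0
    n_motifs: int = 50
    n_promoters: int = 500
    activity_cross_species_corr: float = 0.8
    seed: int = 0
    # shape of the expression landscape
    base_mean: float = 200.0
    log_mean_sd: float = 1.5
    profile_sd: float = 1.0
    go_base_prob: float = 0.05
    # motif model noise
    motif_noise_sd: float = 0.5
    motif_intercept_sd: float = 1.0
    # promoter FASTA
    high_n_fraction: float = 0.0
    promoter_halfwidth: int = 500

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_cell_types", "n_replicates", "n_go_terms",
                     "n_motifs", "n_promoters"):
            if getattr(self, name) < 1:
                raise ValueError(f"configuration error: {name} must be a positive integer")
        if self.dispersion_alpha < 0:
            raise ValueError("configuration error: dispersion_alpha must be >= 0")
        for name in ("divergent_fraction", "promoter_nonortho_fraction", "high_n_fraction",
                     "go_base_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"configuration error: {name} must lie in [0, 1]")
        probs = np.asarray(self.age_class_probs, dtype=float)
        if probs.shape != (3,) or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(
                "configuration error: age_class_probs must be a 3-vector of "
                "probabilities summing to 1"
            )
        if not -1.0 <= self.activity_cross_species_corr <= 1.0:
            raise ValueError(
                "configuration error: activity_cross_species_corr must lie in [-1, 1]"
            )
        if self.n_motifs >= self.n_promoters:
            raise ValueError(
                "configuration error: n_motifs must be < n_promoters (unidentifiable)"
            )


@dataclass
class SyntheticTruth:
    """Ground-truth record of everything the generator planted."""

    divergent_genes: set
    age_class: dict
    promoter_ortho: dict
    go_assignments: dict
    true_lfc: dict
    enriched_go_term: str
    true_activities: dict = field(default_factory=dict)  # species -> DataFrame

    def to_json(self, path) -> None:
        payload = {
            "divergent_genes": sorted(self.divergent_genes),
            "age_class": self.age_class,
            "promoter_ortho": self.promoter_ortho,
            "go_assignments": {g: sorted(t) for g, t in self.go_assignments.items()},
            "true_lfc": self.true_lfc,
            "enriched_go_term": self.enriched_go_term,
            "true_activities": {
                sp: {"index": list(df.index), "columns": list(df.columns),
                     "values": df.to_numpy().tolist()}
                for sp, df in self.true_activities.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            divergent_genes=set(d["divergent_genes"]),
            age_class=d["age_class"],
            promoter_ortho=d["promoter_ortho"],
            go_assignments={g: set(t) for g, t in d["go_assignments"].items()},
            true_lfc=d["true_lfc"],
            enriched_go_term=d["enriched_go_term"],
            true_activities={
                sp: pd.DataFrame(v["values"], index=v["index"], columns=v["columns"])
                for sp, v in d["true_activities"].items()
            },
        )


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ["means", "labels", "divergence", "counts_a", "counts_b", "go",
             "motifs", "fasta"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu, Var = mu + alpha mu^2) via the gamma-Poisson mixture."""
    if alpha == 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    return rng.poisson(lam)


def divergence_probability(config: SyntheticConfig, k: np.ndarray, nonortho: np.ndarray) -> np.ndarray:
    """Planted logistic divergence model, centered to the marginal fraction."""
    f = config.divergent_fraction
    if f <= 0.0:
        return np.zeros(len(k))
    if f >= 1.0:
        return np.ones(len(k))
    probs = np.asarray(config.age_class_probs)
    mean_k = float((probs * np.arange(3)).sum())
    eta = (
        np.log(f / (1.0 - f))
        + config.age_effect * (k - mean_k)
        + config.promoter_effect * (nonortho.astype(float) - config.promoter_nonortho_fraction)
    )
    return 1.0 / (1.0 + np.exp(-eta))


def generate_counts(
    config: SyntheticConfig,
) -> tuple[CountMatrix, CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate paired count matrices, the ortholog table, and the truth record.

    Both species share each gene's cell-type mean profile mu_gc except
    for divergent genes, whose second-species means are divided by
    2**true_lfc across all cell types (true_lfc = log2 of the
    reference-over-other mean ratio).  Counts are NB with the
    configured dispersion, independently per replicate.

    Returns (counts species A, counts species B, ortholog table, truth).
    The ortholog table has columns gene_a, gene_b, age_class,
    promoter_ortho.
    """
    rng = _streams(config.seed)
    g, c, r = config.n_genes, config.n_cell_types, config.n_replicates
    gene_a = [f"g{i:05d}_{config.species_pair[0]}" for i in range(g)]
    gene_b = [f"g{i:05d}_{config.species_pair[1]}" for i in range(g)]
    cell_types = [f"ct{j:02d}" for j in range(c)]

    # shared expression landscape
    base = np.exp(rng["means"].normal(np.log(config.base_mean), config.log_mean_sd, size=g))
    profile = np.exp(rng["means"].normal(0.0, config.profile_sd, size=(g, c)))
    mu = base[:, None] * profile  # genes x cell types

    # gene labels and the planted divergence model
    k = rng["labels"].choice(3, size=g, p=np.asarray(config.age_class_probs))
    nonortho = rng["labels"].random(g) < config.promoter_nonortho_fraction
    p_div = divergence_probability(config, k, nonortho)
    divergent = rng["divergence"].random(g) < p_div
    sign = np.where(rng["divergence"].random(g) < 0.5, 1.0, -1.0)
    lfc = np.where(divergent, sign * config.divergent_lfc, 0.0)

    mu_b = mu / np.power(2.0, lfc[:, None])

    def sample_counts(stream: np.random.Generator, means: np.ndarray, species: str) -> CountMatrix:
        cols = {}
        samples = []
        for j, ct in enumerate(cell_types):
            for rep in range(1, r + 1):
                sid = f"{species}.{ct}.r{rep}"
                cols[sid] = _nb_draw(stream, means[:, j], config.dispersion_alpha)
                samples.append(SampleInfo(sid, species, ct, rep))
        ids = gene_a if species == config.species_pair[0] else gene_b
        return CountMatrix(pd.DataFrame(cols, index=ids), samples)

    cm_a = sample_counts(rng["counts_a"], mu, config.species_pair[0])
    cm_b = sample_counts(rng["counts_b"], mu_b, config.species_pair[1])

    # GO assignments: independent per gene and term; one designated term
    # has its assignment probability raised (log-odds +go_effect) among
    # divergent genes
    terms = [f"T{t:03d}" for t in range(config.n_go_terms)]
    enriched_term = terms[0]
    p0 = config.go_base_prob
    p_enriched = 1.0 / (1.0 + np.exp(-(np.log(p0 / (1 - p0)) + config.go_effect)))
    assign = rng["go"].random((g, config.n_go_terms)) < p0
    boost = rng["go"].random(g) < p_enriched
    assign[:, 0] = np.where(divergent, boost, assign[:, 0])
    go_assignments = {
        gene_a[i]: {terms[t] for t in range(config.n_go_terms) if assign[i, t]}
        for i in range(g)
    }

    ortho = pd.DataFrame(
        {
            "gene_a": gene_a,
            "gene_b": gene_b,
            "age_class": [AGE_CLASSES[i] for i in k],
            "promoter_ortho": ~nonortho,
        }
    )
    truth = SyntheticTruth(
        divergent_genes={gene_a[i] for i in range(g) if divergent[i]},
        age_class={gene_a[i]: AGE_CLASSES[k[i]] for i in range(g)},
        promoter_ortho={gene_a[i]: bool(~nonortho[i]) for i in range(g)},
        go_assignments=go_assignments,
        true_lfc={gene_a[i]: float(lfc[i]) for i in range(g)},
        enriched_go_term=enriched_term,
    )
    return cm_a, cm_b, ortho, truth


def generate_motif_data(
    config: SyntheticConfig,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame], dict[str, pd.DataFrame]]:
    """Planted motif-activity model for both species.

    Per species: TFBS counts N (promoters x motifs, Poisson(1)),
    activities A* (motifs x cell types); expression
    E = N.A* + intercept + Gaussian noise.  For matched cell types the
    two species' activities are correlated at
    ``activity_cross_species_corr`` (A_b = rho A_a + sqrt(1-rho^2) eps).

    Returns ({species: N}, {species: E}, {species: A*}).
    """
    rng = _streams(config.seed)["motifs"]
    sp_a, sp_b = config.species_pair
    motifs = [f"M{m:03d}" for m in range(config.n_motifs)]
    elements = [f"p{e:05d}" for e in range(config.n_promoters)]
    cell_types = [f"ct{j:02d}" for j in range(config.n_cell_types)]
    rho = config.activity_cross_species_corr

    A_a = rng.normal(0.0, 1.0, size=(config.n_motifs, config.n_cell_types))
    eps = rng.normal(0.0, 1.0, size=A_a.shape)
    A_b = rho * A_a + np.sqrt(max(1.0 - rho**2, 0.0)) * eps

    out_N, out_E, out_A = {}, {}, {}
    for sp, A in ((sp_a, A_a), (sp_b, A_b)):
        N = rng.poisson(1.0, size=(config.n_promoters, config.n_motifs)).astype(float)
        intercept = (
            rng.normal(0.0, config.motif_intercept_sd, size=config.n_cell_types)
            if config.motif_intercept_sd > 0
            else np.zeros(config.n_cell_types)
        )
        noise = (
            rng.normal(0.0, config.motif_noise_sd, size=(config.n_promoters, config.n_cell_types))
            if config.motif_noise_sd > 0
            else 0.0
        )
        E = N @ A + intercept + noise
        out_N[sp] = pd.DataFrame(N, index=elements, columns=motifs)
        out_E[sp] = pd.DataFrame(E, index=elements, columns=cell_types)
        out_A[sp] = pd.DataFrame(A, index=motifs, columns=cell_types)
    return out_N, out_E, out_A


def generate_promoter_fasta(
    config: SyntheticConfig, fasta_path, bed_path, n_block_fraction: float = 0.3
) -> list[str]:
    """Genome-like FASTA plus a BED of TSS promoter windows.

    One chromosome holds all genes, TSSs spaced so that +/-halfwidth
    windows do not overlap; the first gene's TSS sits closer to the
    sequence start than the halfwidth, so its window is clipped at
    position 0.  A ``high_n_fraction`` subset of genes receives a run
    of N covering ``n_block_fraction`` of its promoter window.  BED is
    0-based half-open with the gene id in column 4.  Returns the gene
    ids whose windows were given the N block.
    """
    rng = _streams(config.seed)["fasta"]
    hw = config.promoter_halfwidth
    spacing = 4 * hw
    gene_ids = [f"g{i:05d}_{config.species_pair[0]}" for i in range(config.n_genes)]
    # first TSS inside the clipping zone on purpose; the rest well separated
    tss = [hw // 2] + [hw // 2 + spacing * i for i in range(1, config.n_genes)]
    length = tss[-1] + 2 * spacing
    seq = rng.choice(list("ACGT"), size=length)

    n_high = int(round(config.high_n_fraction * config.n_genes))
    flagged = sorted(rng.choice(config.n_genes, size=n_high, replace=False).tolist())
    flagged_ids = [gene_ids[i] for i in flagged]
    for i in flagged:
        start = max(tss[i] - hw, 0)
        end = min(tss[i] + hw, length)
        run = int(np.ceil(n_block_fraction * (end - start)))
        seq[start : start + run] = "N"

    with open(fasta_path, "w") as fh:
        fh.write(">chr1\n")
        s = "".join(seq)
        for i in range(0, len(s), 60):
            fh.write(s[i : i + 60] + "\n")
    with open(bed_path, "w") as fh:
        for gid, t in zip(gene_ids, tss):
            fh.write(f"chr1\t{max(t - hw, 0)}\t{min(t + hw, length)}\t{gid}\n")
    return flagged_ids


def simulate_to_dir(config: SyntheticConfig, outdir) -> dict[str, Path]:
    """Run the full generator and write every artifact as text files.

    Writes counts + sample sheets per species, the ortholog map, gene
    metadata, GO assignments (long TSV), TFBS and expression matrices
    per species, true activities, FASTA + BED, and the truth record as
    JSON.  Returns a name -> path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sp_a, sp_b = config.species_pair
    cm_a, cm_b, ortho, truth = generate_counts(config)
    Ns, Es, As = generate_motif_data(config)
    truth.true_activities = As

    paths: dict[str, Path] = {}

    def save(name: str, fn) -> None:
        paths[name] = outdir / name
        fn(paths[name])

    save(f"counts_{sp_a}.tsv", lambda p: cm_a.counts.to_csv(p, sep="\t", index_label="gene_id"))
    save(f"counts_{sp_b}.tsv", lambda p: cm_b.counts.to_csv(p, sep="\t", index_label="gene_id"))
    save(f"samples_{sp_a}.tsv", lambda p: cm_a.sample_frame.to_csv(p, sep="\t", index=False))
    save(f"samples_{sp_b}.tsv", lambda p: cm_b.sample_frame.to_csv(p, sep="\t", index=False))
    save("orthologs.tsv", lambda p: ortho.to_csv(p, sep="\t", index=False))
    go_long = pd.DataFrame(
        [(gid, t) for gid, ts in sorted(truth.go_assignments.items()) for t in sorted(ts)],
        columns=["gene_id", "term_id"],
    )
    save("go_terms.tsv", lambda p: go_long.to_csv(p, sep="\t", index=False))
    for sp in (sp_a, sp_b):
        save(f"tfbs_{sp}.tsv", lambda p, sp=sp: Ns[sp].to_csv(p, sep="\t", index_label="element"))
        save(
            f"motif_expr_{sp}.tsv",
            lambda p, sp=sp: Es[sp].to_csv(p, sep="\t", index_label="element"),
        )
    save("truth.json", truth.to_json)
    paths["genome.fa"] = outdir / "genome.fa"
    paths["promoters.bed"] = outdir / "promoters.bed"
    generate_promoter_fasta(config, paths["genome.fa"], paths["promoters.bed"])
    return paths
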
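"""End-to-end synthetic benchmark: simulate -> VST -> DE -> conservation -> ICC -> enrichment -> MARA.

Runs every stage in dependency order on generated data, collects the
headline statistics of each stage (DE percentages, median conservation
correlations and their Mann-Whitney p-values against the nulls,
age-trend and promoter-stratum tests with Fisher combination across
cell types, ICC median and AFA, matched-background GO enrichment of
the planted term, motif-activity conservation p-value), and scores
recovery against the generator's ground truth.  The report is a plain
dict, JSON-serializable, with all seeds and parameters echoed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from xsc import conservation, diffexpr, enrichment, expression, icc as icc_mod, mara, synthetic

log = logging.getLogger("xsc")

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Configuration of a full benchmark run (YAML round-trippable)."""

    synthetic: synthetic.SyntheticConfig = field(default_factory=synthetic.SyntheticConfig)
    outdir: str = "xsc_run"
    fdr: float = 0.1
    min_expr: float = 5.0
    k_nearest: int = 10
    min_term: int = 10
    null_draws: int = 5
    icc_perms: int = 5
    mara_lambda: float | None = None
    stages: tuple[str, ...] = ("de", "conservation", "icc", "enrichment", "mara")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["synthetic"]["species_pair"] = list(d["synthetic"]["species_pair"])
        d["synthetic"]["age_class_probs"] = list(d["synthetic"]["age_class_probs"])
        d["stages"] = list(d["stages"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        syn = d.pop("synthetic", {})
        syn["species_pair"] = tuple(syn.get("species_pair", ("human", "mouse")))
        syn["age_class_probs"] = tuple(syn.get("age_class_probs", (0.5, 0.3, 0.2)))
        d["stages"] = tuple(d.get("stages", ("de", "conservation", "icc", "enrichment", "mara")))
        return cls(synthetic=synthetic.SyntheticConfig(**syn), **d)


def _stage(name: str, report: dict):
    """Context manager logging stage timing and re-raising with the stage name."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.time()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.time() - self.t0
            if exc_type is not None:
                log.error("stage %s: FAILED after %.1fs: %s", name, dt, exc)
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            report.setdefault("timings_s", {})[name] = round(dt, 2)
            log.info("stage %s: done in %.1fs", name, dt)
            return False

    return _Ctx()


def run_all(config: RunConfig) -> dict:
    """Execute the benchmark and return the consolidated report."""
    cfg = config.synthetic
    sp_a, sp_b = cfg.species_pair
    report: dict = {
        "config": {
            "synthetic": dataclasses.asdict(cfg),
            "fdr": config.fdr,
            "min_expr": config.min_expr,
            "k_nearest": config.k_nearest,
            "min_term": config.min_term,
            "null_draws": config.null_draws,
            "icc_perms": config.icc_perms,
        }
    }
    rng_seed = cfg.seed

    with _stage("simulate", report):
        cm_a, cm_b, ortho, truth = synthetic.generate_counts(cfg)
        Ns, Es, As = synthetic.generate_motif_data(cfg)
        truth.true_activities = As

    with _stage("vst", report):
        sf_a = expression.size_factors(cm_a)
        sf_b = expression.size_factors(cm_b)
        alpha = float(
            np.mean([expression.estimate_alpha(cm_a, sf_a), expression.estimate_alpha(cm_b, sf_b)])
        )
        vst_a = expression.vst(expression.normalize_counts(cm_a, sf_a), alpha)
        vst_b = expression.vst(expression.normalize_counts(cm_b, sf_b), alpha)
        avg_a = expression.average_replicates(vst_a, cm_a.samples)
        avg_b = expression.average_replicates(vst_b, cm_b.samples)
        report["alpha_hat"] = alpha

    cell_types = sorted({s.cell_type for s in cm_a.samples})
    gene_a = ortho["gene_a"].tolist()
    de_tables: dict[str, pd.DataFrame] = {}

    if "de" in config.stages:
        with _stage("de", report):
            summaries = []
            for ct in cell_types:
                cols_a = [s.sample_id for s in cm_a.samples if s.cell_type == ct]
                cols_b = [s.sample_id for s in cm_b.samples if s.cell_type == ct]
                tab = diffexpr.de_table(
                    cm_a.counts.loc[gene_a, cols_a].to_numpy(),
                    cm_b.counts.loc[ortho["gene_b"], cols_b].to_numpy(),
                    gene_a,
                    ortho["gene_b"],
                    sf_a[cols_a].to_numpy(),
                    sf_b[cols_b].to_numpy(),
                    alpha,
                    fdr=config.fdr,
                    min_expr=config.min_expr,
                )
                de_tables[ct] = tab
                s = diffexpr.summarize_de(tab, ct, (sp_a, sp_b))
                summaries.append(
                    {"cell_type": ct, "n_expressed": s.n_expressed,
                     "pct_up": s.pct_up, "pct_down": s.pct_down}
                )
            pct_de = [s["pct_up"] + s["pct_down"] for s in summaries]
            de_any = (
                pd.concat([t.set_index("gene_a")["is_de"] for t in de_tables.values()], axis=1)
                .any(axis=1)
            )
            truth_div = de_any.index.isin(truth.divergent_genes)
            called = de_any.to_numpy()
            report["de"] = {
                "per_cell_type": summaries,
                "mean_pct_de": float(np.mean(pct_de)),
                "recovery": {
                    "sensitivity": float(called[truth_div].mean()) if truth_div.any() else None,
                    "fdr_observed": float((~truth_div[called]).mean()) if called.any() else None,
                    "planted_fraction": float(np.mean([t in truth.divergent_genes for t in gene_a])),
                },
            }

    if "conservation" in config.stages and de_tables:
        with _stage("conservation", report):
            expr_a = avg_a[sp_a]
            expr_a = expr_a.loc[gene_a]
            expr_b = avg_b[sp_b].loc[ortho["gene_b"]]
            expr_b.index = gene_a
            pg = conservation.pergene_correlation(expr_a, expr_b)
            obs_r = pg.loc[pg["defined"], "r"].to_numpy()
            null_gene = conservation.correlation_null(
                expr_a, expr_b, "gene_permute", n_draws=config.null_draws, seed=rng_seed + 1
            )
            null_sample = conservation.correlation_null(
                expr_a, expr_b, "sample_permute", n_draws=config.null_draws, seed=rng_seed + 2
            )
            _, p_gene = conservation.compare_to_null(obs_r, null_gene)
            _, p_sample = conservation.compare_to_null(obs_r, null_sample)
            per_ct = conservation.pergroup_correlation(expr_a, expr_b)

            de_flags_by_ct = {
                ct: dict(zip(t["gene_a"], t["is_de"])) for ct, t in de_tables.items()
            }
            nonortho = {g: not truth.promoter_ortho[g] for g in gene_a}
            prom_ps, prom_ors = [], []
            age_ps, age_slopes = [], []
            for ct, flags in de_flags_by_ct.items():
                expressed = de_tables[ct].set_index("gene_a")["expressed"]
                flags_expr = {g: flags[g] for g in flags if expressed[g]}
                try:
                    o, p = conservation.stratified_fisher(
                        flags_expr, {g: nonortho[g] for g in flags_expr}
                    )
                    prom_ps.append(p)
                    prom_ors.append(o)
                except ValueError:
                    pass
                res = conservation.age_trend(flags_expr, truth.age_class)
                age_ps.append(res.p_one_sided)
                age_slopes.append(res.slope)
            report["conservation"] = {
                "median_r": float(np.median(obs_r)),
                "n_defined": int(pg["defined"].sum()),
                "mw_p_vs_gene_permute": p_gene,
                "mw_p_vs_sample_permute": p_sample,
                "median_r_per_cell_type": float(np.median(per_ct["r"].dropna())),
                "promoter_stratum": {
                    "median_odds_ratio": float(np.median(prom_ors)) if prom_ors else None,
                    "fisher_combined_p": conservation.fisher_combine(prom_ps) if prom_ps else None,
                },
                "age_trend": {
                    "median_slope": float(np.median(age_slopes)),
                    "fisher_combined_p": conservation.fisher_combine(age_ps),
                },
            }

    if "icc" in config.stages:
        with _stage("icc", report):
            # linear-scale expression, replicates collapsed by median,
            # quantile-normalized per species
            norm_a = expression.normalize_counts(cm_a, sf_a)
            norm_b = expression.normalize_counts(cm_b, sf_b)

            def collapse(norm: pd.DataFrame, samples) -> pd.DataFrame:
                groups: dict[str, list[str]] = {}
                for s in samples:
                    groups.setdefault(s.cell_type, []).append(s.sample_id)
                return pd.DataFrame({ct: norm[cols].median(axis=1) for ct, cols in sorted(groups.items())})

            lin_a = icc_mod.quantile_normalize(collapse(norm_a, cm_a.samples).loc[gene_a])
            lin_b_raw = collapse(norm_b, cm_b.samples).loc[ortho["gene_b"]]
            lin_b_raw.index = gene_a
            lin_b = icc_mod.quantile_normalize(lin_b_raw)
            res = icc_mod.integrative_correlation(lin_a, lin_b)
            vals = res.loc[res["defined"], "icc"].to_numpy()
            null = icc_mod.icc_null(lin_a, lin_b, n_perm=config.icc_perms, seed=rng_seed + 3)
            _, p_icc = conservation.compare_to_null(vals, null)
            afa_table = icc_mod.afa(
                res["icc"].dropna().to_dict(),
                {t: {g for g, ts in truth.go_assignments.items() if t in ts}
                 for t in {t for ts in truth.go_assignments.values() for t in ts}},
                min_genes=config.min_term,
            )
            report["icc"] = {
                "median_icc": float(np.median(vals)),
                "mw_p_vs_sample_permute": p_icc,
                "n_afa_terms": int(len(afa_table)),
                "afa_min_p_adj": float(afa_table["p_adj"].min()) if len(afa_table) else None,
            }

    if "enrichment" in config.stages and de_tables:
        with _stage("enrichment", report):
            mean_expr = avg_a[sp_a].loc[gene_a].mean(axis=1).to_dict()
            term_sets = {
                t: {g for g, ts in truth.go_assignments.items() if t in ts}
                for t in {t for ts in truth.go_assignments.values() for t in ts}
            }
            planted_ps = []
            for ct, tab in de_tables.items():
                de_genes = set(tab.loc[tab["is_de"], "gene_a"])
                pool = set(tab.loc[tab["expressed"], "gene_a"]) - de_genes
                if len(de_genes) < 5 or len(pool) < config.k_nearest:
                    continue
                bg = enrichment.matched_background(de_genes, mean_expr, pool, k=config.k_nearest)
                tab_go = enrichment.go_fisher(de_genes, bg, term_sets)
                hit = tab_go[tab_go["term_id"] == truth.enriched_go_term]
                if len(hit):
                    planted_ps.append(float(hit["p_over"].iloc[0]))
            report["enrichment"] = {
                "planted_term": truth.enriched_go_term,
                "planted_term_combined_p_over": (
                    conservation.fisher_combine(planted_ps) if planted_ps else None
                ),
                "n_comparisons": len(planted_ps),
            }

    if "mara" in config.stages:
        with _stage("mara", report):
            model_a = mara.fit_activities(Es[sp_a], Ns[sp_a], lam=config.mara_lambda)
            model_b = mara.fit_activities(Es[sp_b], Ns[sp_b], lam=config.mara_lambda)
            table, u, p = mara.compare_activities(model_a, model_b, seed=rng_seed + 4)
            rec = conservation.rowwise_pearson(
                model_a.A.to_numpy(), As[sp_a].loc[model_a.A.index].to_numpy()
            )
            report["mara"] = {
                "median_r_matched": float(np.nanmedian(table["r_matched"])),
                "mw_p_vs_mismatched": p,
                "median_activity_recovery_r": float(np.nanmedian(rec)),
            }

    return report


def write_report(report: dict, outdir) -> Path:
    """Write the JSON report plus a short human-readable summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "report.json"
    path.write_text(json.dumps(report, indent=1, sort_keys=True, default=str))
    lines = ["xsc benchmark report", "===================="]
    if "de" in report:
        lines.append(f"mean DE % across cell types: {report['de']['mean_pct_de']:.1f}")
    if "conservation" in report:
        c = report["conservation"]
        lines.append(
            f"median per-gene r: {c['median_r']:.3f} "
            f"(vs gene-permute null p={c['mw_p_vs_gene_permute']:.3g})"
        )
        lines.append(f"age-trend combined p: {c['age_trend']['fisher_combined_p']:.3g}")
    if "icc" in report:
        lines.append(f"median ICC: {report['icc']['median_icc']:.3f}")
    if "mara" in report:
        lines.append(
            f"median matched motif-activity r: {report['mara']['median_r_matched']:.3f} "
            f"(p={report['mara']['mw_p_vs_mismatched']:.3g})"
        )
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
    return path
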
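# xsc — cross-species transcriptome conservation analysis

`xsc` asks how well gene expression programs are conserved between
species when the comparison is made in *matched primary cell types*
rather than whole tissues (where cell-type composition confounds every
comparison).  It implements, as a tested and reusable pipeline, the
statistical toolkit of promoter-level (CAGE-style) cross-species
comparative transcriptomics:

- **Normalization & VST** — total-count/median size factors and the
  closed-form negative-binomial variance-stabilizing transform
  `x' = (2·asinh(√(αx)) − ln α − ln 4) / ln 2`, which behaves like
  log2(x) for large counts and has mean-independent variance under
  Var = μ + αμ².
- **Differential expression** — per cell type, an NB Wald test between
  the two species' ortholog counts with a shared dispersion α,
  Benjamini–Hochberg correction, and DE calls at adjusted P < 0.1.
- **Conservation correlations** — per-ortholog-pair Pearson r across
  cell types, and per-cell-type r across orthologs, judged against
  three nulls: permuted gene pairings, permuted samples, and the exact
  distribution of r for an uncorrelated bivariate normal
  (f(r) ∝ (1−r²)^((n−4)/2)); one-sided Mann–Whitney U for significance.
- **Evolutionary-age trends** — per-class DE counts modelled as
  Poisson with an equidistant age score (bilateria → vertebrate →
  mammal) and a log class-size offset; likelihood-ratio test, one-sided
  p, Fisher combination across comparisons.
- **Promoter-orthology stratification** — Fisher's exact test of DE
  enrichment among genes whose dominant promoter lacks an orthologous
  genomic region.
- **Integrative correlation coefficient (ICC)** — the per-gene
  correlation-of-correlations between the two species' gene × gene
  co-expression matrices, with a sample-permutation null and AFA
  (rank-sum enrichment of annotation terms along the ICC ranking).
- **Expression-matched GO enrichment** — Fisher's exact test of term
  membership among DE genes against a background of the 10
  nearest-in-expression genes per DE gene.
- **Motif activity (MARA-style)** — ridge decomposition E ≈ c + N·A of
  element expression over a TFBS count matrix, and cross-species /
  promoter-vs-enhancer activity comparison against a mismatched-motif
  background.

Because the analyses only make sense end-to-end on data with known
answers, the package ships a first-class synthetic-data generator
(`xsc.synthetic`) that plants every effect the pipeline is supposed to
find: NB counts per ortholog pair, a divergent-gene fraction with
logistic dependence on age class and promoter orthology, an enriched
GO term among divergent genes, and cross-species-correlated motif
activities.

## Worked example

```sh
xsc run --outdir bench      # default benchmark config
cat bench/report.txt
```

prints, for the default 2000-gene, 8-cell-type benchmark:

```
xsc benchmark report
====================
mean DE % across cell types: 42.5
median per-gene r: 0.970 (vs gene-permute null p=0)
age-trend combined p: 4.16e-195
median ICC: 0.930
median matched motif-activity r: 0.850 (p=1.3e-31)
```

Reading these numbers: 30.7% of ortholog pairs were planted as
divergent (the report's `de.recovery` block records this), and the
per-cell-type DE fraction recovers them at sensitivity 0.998; the
excess above the planted fraction comes from BH false discoveries at
the 0.1 threshold plus the composition bias of total-count
normalization, which is noticeable at 2000 genes and shrinks to a few
points at the 15,000-gene benchmark scale (see `docs/methods.md`).
Per-gene correlations across cell types are far above the permuted
pairing null, and the planted age trend (younger genes more divergent)
and motif-activity conservation are both detected.
`bench/report.json` carries the full machine-readable report,
including recovery metrics against the generator's ground-truth
record.

The same stages are available as individual commands over TSV files
(`xsc simulate`, `xsc vst`, `xsc de`, `xsc conserve`, `xsc age-trend`,
`xsc icc`, `xsc enrich`, `xsc mara`, `xsc mara-compare`,
`xsc filter-n`) and as plain library functions; see `docs/methods.md`
for the statistical details and design choices.

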
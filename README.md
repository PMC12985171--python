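# sccismr

Single-cell **cis**-Mendelian-randomization gene prioritization from summary
statistics.

## The problem

Genome-wide association studies of immune-mediated diseases point mostly at
non-coding variants whose effects are regulatory and often cell-type
specific. Per-cell-type cis-eQTL panels from single-cell cohorts make it
possible to ask, for every gene *g* and immune cell type *c*, whether the
genetically regulated expression of *g* **in that cell type** affects disease
risk. `sccismr` implements the full summary-statistics pipeline for that
question:

1. **Instrument selection** — cis-eQTLs within ±1 Mb of the gene body with
   p ≤ 10⁻⁵, greedily LD-clumped at r² < 0.1, and kept only when the
   approximate F statistic (β/SE)² ≥ 10.
2. **Harmonization** — exposure and outcome effects aligned to the same
   allele, palindromic (A/T, C/G) variants removed, followed by Steiger
   filtering (a variant explaining more outcome than exposure variance is
   excluded, with r² ≈ z²/(z² + n)).
3. **Two-sample MR** — the Wald ratio β̂ = b_Y/b_X for one instrument; the
   inverse-variance-weighted estimate (origin-constrained WLS with weights
   1/SE²_Y and multiplicative random-effects inflation max(1, √(Q/(k−1))))
   for k ≥ 2; weighted median and MR-Egger for k ≥ 3; MR-PRESSO above 4.
   Primary p-values are BH-FDR corrected across all gene × cell-type tests.
4. **Pleiotropy-robust cis likelihood** — a region-wide Gaussian model
   estimating jointly the causal effect α and a residual pleiotropic
   variance σ_y, with LD propagated explicitly through the correlation
   matrix R:  b_Y ~ N(α·Rγ + Rc, s²_y·R), γ ~ N(0, σ_x·I), c ~ N(0, σ_y·I).
   Likelihood-ratio tests give p(α = 0) and the boundary-corrected
   p(σ_y = 0); a gene passes the gate when p(α) ≤ 0.05 and p(σ_y) ≥ 0.05.
5. **Colocalization** — Wakefield approximate Bayes factors
   (log ABF = ½[log(1−r) + r·z²], r = W/(V+W)) under a single-causal-variant
   assumption; a region colocalizes when PP.H4/(PP.H3 + PP.H4) ≥ 0.6.
6. **Prioritization and reporting** — a gene × cell-type association is
   *prioritized* when it clears FDR + directional sensitivity consistency,
   the pleiotropy gate, and colocalization. Reporting includes mapping to
   genome-wide-significant loci (lead clumping at p ≤ 5×10⁻⁸, r² < 0.001,
   ±500 kb; genes assigned within ±1 Mb of a lead), per-cell-type Fisher
   enrichment with conditional-MLE odds ratios, and concordance of
   single-cell versus bulk estimates.

A seeded summary-statistic simulator (`sccismr.synthetic_data`) generates
the whole input bundle — per-cell-type eQTL tables in both the β/SE and the
Spearman ρ/p dialects, an outcome GWAS, LD matrices and gene coordinates —
with known ground truth, so every stage is testable end to end without any
external download.

## Worked example

```python
from sccismr import SimConfig, simulate_dataset, run_all, PipelineConfig

cfg = SimConfig(n_genes=30, n_cell_types=3, variants_per_region=60,
                causal_gene_fraction=0.2, alpha_spec=("fixed", 0.3), seed=77)
dataset = simulate_dataset(cfg)
result = run_all(dataset, PipelineConfig(seed=1))

print("tested gene-cell pairs:", result.log["n_gene_cell_tested"])
print("FDR-significant primaries:", result.log["n_fdr_significant"])
print("prioritized:", result.log["n_prioritized"])
print(result.records[result.records["prioritized"]]
      [["gene_id", "cell_type"]].to_string(index=False))
```

prints

```
tested gene-cell pairs: 45
FDR-significant primaries: 15
prioritized: 8
 gene_id cell_type
GENE0008    cell00
GENE0009    cell00
GENE0013    cell00
GENE0017    cell00
GENE0023    cell00
GENE0009    cell01
GENE0009    cell02
GENE0020    cell02
```

Of 45 testable gene × cell-type pairs, 15 pass the FDR screen and 8 survive
all three prioritization steps. Every prioritized gene here is truly causal
in the simulation (the generator planted effects in GENE0008/9/13/17/19/20/23);
`GENE0009` is recovered in all three cell types in which it has an eQTL.

The enrichment machinery works directly from per-cell-type counts. On the
published table of an atopic-dermatitis single-cell MR analysis
(`sccismr.prioritize.AD_CELLTYPE_GENE_COUNTS`, 297 significant associations
over 13,289 gene × cell-type tests):

```python
from sccismr.prioritize import AD_CELLTYPE_GENE_COUNTS, fisher_enrichment
rows = fisher_enrichment(
    [(c, k, n) for c, (k, n) in AD_CELLTYPE_GENE_COUNTS.items()])
```

reproduces the published conditional-MLE odds ratios, e.g. CD4_SOX4
OR = 2.898 (p = 0.009), NK OR = 0.689 (p = 0.052), DC OR = 1.554.

## Command line

```bash
sccismr simulate --out data/ --desk-scale --seed 1   # synthetic input bundle
sccismr run-all --data data/ --out results/ --seed 1 # full pipeline
sccismr mr --data data/ --out results/               # single stage
```

Thresholds can be overridden with a plain key-value YAML file passed as
`--config`; every run writes `run_log.json` recording the seed, versions,
thresholds and row counts at each filter.

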
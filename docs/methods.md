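# Methods

This note documents the statistical models implemented in `sccismr`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that matter.

## Summary-statistic conventions

All effects are treated as standardized per-allele effects. Exposure tables
carrying a Spearman correlation ρ instead of β/SE are converted with

    β = ρ / sqrt(2 f (1 − f)),   SE = |β| / Z,   Z = Φ⁻¹(1 − p/2),

where *f* is the effect-allele frequency. The conversion guarantees
|β/SE| = Z exactly and round-trips back to (ρ, p) to high precision; the
normal quantile is evaluated as `isf(p/2)` so that p-values as small as
1e−300 remain stable, and p = 0 is clamped to the smallest positive normal
double before the transform. Coordinates are 1-based inclusive; variants are
matched by identifier, never by position. Harmonization aligns the outcome
to the exposure effect allele, removes palindromic (A/T, C/G) variants
outright — no frequency-based rescue — and drops irreconcilable allele sets,
logging every removal.

## Instrument selection

Candidates are cis variants (gene body ± 1 Mb) with p ≤ 1e−5; greedy
clumping visits them by ascending p (ties broken lexicographically by
variant id, making the output invariant to input order) and discards
anything with r² ≥ 0.1 against a kept variant. Instrument strength uses the
single-variant approximation F = (β/SE)², thresholded at 10. Steiger
filtering compares variance explained, r² ≈ z²/(z² + n), on the observed
scale for both traits; no liability-scale correction is applied to the
binary outcome, and pairs with unknown sample size are retained with a
warning rather than silently dropped. No genomic region (including the HLA
region) is excluded anywhere.

## Two-sample MR estimators

* **Wald ratio** (1 instrument): b_Y/b_X with the first-order delta SE
  SE_Y/|b_X|. Higher-order terms are negligible for instruments passing
  F ≥ 10.
* **IVW** (≥ 2): weighted regression of b_Y on b_X through the origin with
  weights 1/SE²_Y. The standard error uses multiplicative random effects —
  inflation by max(1, √(Q/(k−1))) with Cochran's Q — mirroring the common
  two-sample MR default; a fixed-effect variant is available via argument.
* **MR-Egger** (≥ 3): free-intercept WLS after orienting b_X ≥ 0; slope and
  intercept p-values use the t distribution on k − 2 degrees of freedom with
  the residual variance unrestricted, which makes the intercept test exactly
  calibrated under normality. Numerically exact fits (residuals below
  1e−10 of the outcome scale) are snapped to zero so idealized inputs behave
  as in exact arithmetic.
* **Weighted median** (≥ 3): per-instrument ratios combined with
  inverse-variance weights (b_X/SE_Y)², interpolating the standardized
  cumulative weight at one half; the SE is a parametric bootstrap (default
  1000 draws) with a fixed seed, so results are reproducible.
* **MR-PRESSO** (> 4): the observed statistic is the weighted leave-one-out
  residual sum of squares; the null distribution comes from parametric
  simulation (default 1000 draws) under the no-pleiotropy model. The global
  p-value uses the add-one convention, so a run with no exceedances reports
  1/(n_sim + 1) rather than zero. Outliers are instruments extreme at the
  Bonferroni-corrected 0.05 level; when the global test rejects, the
  reported estimate is the outlier-removed IVW. The distortion test is not
  implemented (only the global and outlier tests feed the pipeline).

The method ladder is dispatched purely on instrument count (1 → Wald,
≥ 2 → IVW primary, ≥ 3 adds weighted median and Egger, > 4 adds PRESSO).
Primary p-values are pooled across **all** gene × cell-type tests for the
BH-FDR correction; a per-cell-type pool is a one-line change at the call
site but pooling is the default because the discovery claim spans all
contexts jointly.

## Cis-region likelihood (pleiotropy gate)

Most gene × cell-type pairs have a single independent instrument, where
Egger-style sensitivity analysis is impossible. The gate instead models all
associated variants of the region jointly. With R the signed LD matrix,
joint eQTL effects γ and joint pleiotropic effects c are treated as random:

    b_X = Rγ + e_X,          γ ~ N(0, σ_x I),   e_X ~ N(0, s²_x R)
    b_Y = α·Rγ + Rc + e_Y,   c ~ N(0, σ_y I),   e_Y ~ N(0, s²_y R)

s²_x and s²_y are the squared median summary-statistic standard errors.
Because every covariance term shares the eigenbasis of R, one symmetric
eigendecomposition turns the likelihood into independent 2×2 Gaussian
factors per eigencomponent, making each fit O(m²) once and O(m) per
likelihood evaluation. The three parameters (α, σ_x, σ_y) are estimated by
L-BFGS-B from several starting points (moment-based and null starts);
variances are bounded at zero.

Two design points matter. First, treating the exposure signal as *random*
rather than fixed is what removes regression-dilution attenuation: with a
fixed-signal (flat-prior) formulation the α estimate is biased toward zero
both by exposure sampling noise and by significance selection, which we
verified in simulation; the random-effects form recovers a simulated
α = 0.3 essentially unbiased (mean α̂ ≈ 0.295) even when the region is
restricted to variants passing the p ≤ 1e−5 screen, because the Gaussian
prior shrinks winner's-curse noise. Second, the LRT for σ_y = 0 sits on the
parameter boundary, so its p-value uses the 50:50 mixture of a point mass at
zero and χ²₁; the LRT for α = 0 is interior and uses plain χ²₁. Both
p-values are approximately uniform under their nulls (Kolmogorov–Smirnov
p > 0.01 on 500 simulated regions, checked in the acceptance suite).

Near-singular LD is handled spectrally: eigencomponents below 1e−8 of the
largest eigenvalue are discarded (logged), which is equivalent to a ridge on
the inverse and keeps duplicated or perfectly correlated variants from
breaking the fit. A non-converged fit is flagged and automatically fails the
gate. The gate passes when p(α = 0) ≤ 0.05 and p(σ_y = 0) ≥ 0.05.

This module is an original implementation in the spirit of published
single-locus cis-MR likelihood methods; numerical agreement with any
particular software is not claimed or tested.

## Colocalization

Per-variant evidence is the Wakefield approximate Bayes factor with
shrinkage r = W/(V + W); prior effect standard deviations default to 0.2 per
expression SD for the quantitative trait and 0.15 on the log-odds scale for
the binary outcome, with per-variant configuration priors
p1 = p2 = 1e−4 and p12 = 1e−5. Hypothesis sums are accumulated with
log-sum-exp throughout (the H3 cross term uses a stable log1p-of-difference
form), so no probability underflows; posteriors match a brute-force
enumeration over all variant-pair configurations to machine precision on
small regions. Colocalization consumes the **full** cis region, not the
clumped instruments — the single-causal-variant framework needs the complete
local signal. The decision rule PP.H4/(PP.H3 + PP.H4) ≥ 0.6 is inclusive;
regions with fewer than two shared variants are flagged insufficient and
never colocalize.

## Prioritization and reporting

Step 1 requires FDR ≤ 0.05 on the primary estimate plus, where the
instrument count allowed them, nominally significant sensitivity estimates
(weighted median, Egger, PRESSO) with the primary's sign and a
non-significant Egger intercept (p ≥ 0.05); with a single instrument the
rule passes vacuously and the burden shifts to step 2. Step 2 is the
pleiotropy gate; step 3 the colocalization call; a record is prioritized iff
all three hold, and relaxing any threshold can only grow the prioritized
set.

Lead variants for genome-wide-significant loci are clumped at p ≤ 5e−8
enforcing jointly r² < 0.001 and pairwise distance > 500 kb; genes are
assigned to a locus when any part of the gene body lies within ±1 Mb of a
lead.

Cell-type enrichment contrasts each context against the pooled remaining
contexts with the two-sided Fisher exact test and reports the conditional
maximum-likelihood odds ratio of the noncentral hypergeometric model (the
convention of R's `fisher.test`, via
`scipy.stats.contingency.odds_ratio(kind="conditional")`). The default 2×2
layout puts (significant, total tested) in the focal row against
(significant, remaining non-significant) elsewhere: this is the convention
that reproduces published single-cell MR enrichment tables to their printed
precision, as checked in the acceptance suite against a 14-cell-type
atopic-dermatitis analysis (e.g. CD4_SOX4 OR 2.895, NK 0.686). The textbook
layout with (significant, non-significant) in both rows is available as
`margins="nonsig"`; the two agree closely because significant genes are a
small fraction of each margin, and the sample cross-product OR agrees with
the conditional MLE within 15% on all published rows.

Bulk concordance treats the bulk dataset as a 15th context analyzed with
identical filter settings: per cell type it reports the fraction of
prioritized genes that are also bulk-FDR-significant with a concordant sign,
and the Pearson correlation of shared genes' estimates (undefined below 3
shared genes), BH-FDR adjusted across cell types.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, on
the summary-statistic scale only — no individual-level genotypes or
liability-scale simulation, since the pipeline never sees them:

* per-gene cis regions of `variants_per_region` variants with AR(1) LD
  (r_ij = decay^|i−j|), regions unlinked from each other;
* sparse joint eQTL effects — one causal variant per gene, occasionally two
  (`secondary_causal_fraction`, default 0.05) — shared across the cell
  types in which the gene has an eQTL; a configurable fraction of genes
  (default 2/3, matching the observed single-context share) is specific to
  exactly one cell type;
* observed marginals = LD-propagated joint effects + correlated noise with
  covariance R/n; exposure tables are emitted in both statistic dialects;
* outcome effects α·Rγ plus an optional LD-propagated pleiotropic component
  (variance σ_y in a configurable fraction of regions) at `n_outcome`;
* harmonization hazards injected at configurable rates: strand-ambiguous
  allele pairs (default 5%) and swapped-orientation outcome rows with
  negated beta and complemented frequency (default 10%).

Default study conditions: 14 cell-type contexts, n_exposure = 982 (the
scale of current single-cell eQTL cohorts), n_outcome = 50,000 as a
scaled-down stand-in for a biobank-scale binary-trait GWAS (the full-scale
sample size only sharpens outcome SEs and would slow tests without changing
behavior), joint eQTL effect magnitudes 0.2–0.35 per expression SD and LD
decay 0.7 between adjacent variants. The effect and decay defaults were
calibrated so the generator realizes the sparse architecture it is meant to
emulate — greedy clumping at r² = 0.1 recovers exactly one instrument for
over 90% of genes — reflecting that single-cell eQTL z-scores sit close to
the significance threshold. Per-gene causal effects default to
N(0, 0.3²) in 10% of genes. The desk-scale preset (200 genes × 4 cell
types × 200 variants) completes the full pipeline in minutes; the full
14-context default is used where context count matters.

What the generator does **not** emulate: realistic block-structured LD
(AR(1) only), allele-frequency-dependent effect sizes, sample overlap
between exposure and outcome, population stratification, multi-gene loci
with shared causal variants, and trans effects. Passing tests therefore
demonstrate the pipeline's statistical correctness under its own
assumptions, not robustness to those real-data complications.

## Numerical choices

* Likelihood and posterior computations in log space; log-sum-exp for all
  hypothesis sums; `norm.isf` rather than `1 − cdf` quantile arithmetic.
* Greedy clumping ties in p broken lexicographically by variant id.
* LD matrices validated on construction (symmetry, unit diagonal, entries
  in [−1, 1]); correlations from dosage panels symmetrized and clipped.
* The cis likelihood discards eigencomponents below 1e−8 of the spectral
  radius; MR-PRESSO p-values use the add-one convention; variance
  components are optimized with a zero lower bound and boundary-corrected
  tests.
* Problem sizes in the validation suite (500 replicates for coverage and
  calibration, 100 for end-to-end recovery, regions of 50–100 variants)
  were chosen to keep Monte-Carlo error comfortably inside the asserted
  bands while completing in well under a minute each.

## Known limitations

* The Steiger r² approximation ignores the binary outcome's
  liability-scale correction; with extreme case/control imbalance the
  filter is conservative in an unquantified direction.
* The cis likelihood assumes Gaussian joint effects; true cis
  architectures are sparse. In simulation the α estimate remains unbiased
  under sparsity, but σ_x itself has no structural interpretation.
* IVW coverage statements assume instrument effects measured precisely
  relative to the outcome (the usual no-measurement-error condition);
  with weak exposures and a very large outcome GWAS the random-effects
  inflation absorbs the excess dispersion only on average.
* Enrichment odds ratios follow the published margin convention by
  default, which differs from the textbook 2×2 layout (see above); both
  are exposed.
* One published enrichment row pair (CD4_NC, CD8_NC) is not reproduced
  exactly by any margin convention we examined; the discrepancy is in the
  source table, not in the exact-test implementation, and those rows are
  not part of the validated set.
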
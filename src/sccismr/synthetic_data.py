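"""Summary-statistic simulator with known ground truth.

Generates the full input bundle the pipeline consumes — per-cell-type
cis-eQTL tables (in both the beta/se and the Spearman rho/p dialects), a
binary-trait outcome GWAS table, an LD reference and gene coordinates —
directly on the summary-statistic scale, so every stage of the analysis is
testable without individual-level data.

The generative model per gene region with m variants and AR(1) LD matrix R
(``r[i][j] = decay**|i-j|``), all on the standardized per-allele scale:

* joint eQTL effects ``gamma`` are sparse — one causal variant per gene in
  most regions, occasionally two — and shared across the cell types in which
  the gene has an eQTL (a configurable fraction of genes is specific to
  exactly one cell type);
* observed marginal exposure effects are ``bX = R gamma + L eps / sqrt(n_x)``
  with ``L`` the Cholesky factor of R, i.e. LD-propagated joint effects plus
  correlated sampling noise with covariance ``R / n_x``;
* observed marginal outcome effects (log-odds scale; effects are simulated
  directly on the summary-statistic scale, no individual-level liability
  model) are ``bY = alpha * R gamma + R c + L eps / sqrt(n_y)`` where
  ``alpha`` is the gene's causal effect and ``c ~ N(0, sigma_y I)`` is a
  joint pleiotropic component present in a configurable fraction of regions;
* a configurable fraction of variants carries strand-ambiguous (A/T or C/G)
  alleles, and a configurable fraction of outcome rows is emitted with the
  allele orientation swapped (beta negated, frequency complemented) to
  exercise harmonization.

Everything is a pure function of (SimConfig, seed): the same configuration
reproduces byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import LDMatrix
from .sumstats import GeneRecord

#: non-palindromic allele pairs cycled over non-ambiguous variants
_SAFE_ALLELES = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
_PALINDROMIC_ALLELES = [("A", "T"), ("C", "G")]

_REGION_SPACING = 10_000_000  # bp between gene starts on one chromosome
_GENE_LENGTH = 20_000
_N_CHROMS = 22


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults emulate the structure of the real analysis: 14 immune cell
    contexts, an exposure panel of 982 individuals, sparse cis architectures
    (mostly one causal variant per gene) and a large binary-trait outcome
    GWAS.  The outcome sample size is a scaled-down stand-in for a
    biobank-scale meta-analysis; the desk-scale preset
    (:meth:`desk_scale`) shrinks the gene/context grid so the full pipeline
    completes in minutes.
    """

    n_genes: int = 200
    n_cell_types: int = 14
    variants_per_region: int = 200
    ld_decay: float = 0.7
    n_exposure: int = 982
    n_outcome: int = 50_000
    n_bulk: int = 10_000
    #: ("fixed", value) or ("normal", sd) per-gene causal effect alpha
    alpha_spec: tuple[str, float] = ("normal", 0.3)
    #: fraction of genes with a nonzero causal effect on the outcome
    causal_gene_fraction: float = 0.1
    #: (fraction of regions with pleiotropy, per-variant pleiotropic variance)
    pleiotropy: tuple[float, float] = (0.1, 1e-3)
    #: fraction of genes whose eQTL exists in exactly one cell type
    cell_specific_fraction: float = 2.0 / 3.0
    #: probability a region carries a second, independent causal eQTL
    secondary_causal_fraction: float = 0.05
    #: per-SD magnitude range of joint eQTL effects
    eqtl_effect_range: tuple[float, float] = (0.2, 0.35)
    palindromic_fraction: float = 0.05
    flip_fraction: float = 0.1
    n_ld_panel: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_cell_types, self.variants_per_region,
               self.n_exposure, self.n_outcome) <= 0:
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ValueError("ld_decay must lie in [0, 1)")
        for frac in (self.causal_gene_fraction, self.cell_specific_fraction,
                     self.palindromic_fraction, self.flip_fraction,
                     self.pleiotropy[0]):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")

    @classmethod
    def desk_scale(cls, **overrides) -> "SimConfig":
        """Preset completing the full pipeline in minutes: 200 genes x 4
        cell types x 200 variants per region."""
        base = dict(n_genes=200, n_cell_types=4, variants_per_region=200)
        base.update(overrides)
        return cls(**base)


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset.

    ``table`` has one row per gene x cell-type with the causal variant ids,
    the joint eQTL effect, the causal effect alpha and the pleiotropy
    parameters; ``gamma`` maps gene_id to the full joint-effect vector.
    """

    config: SimConfig
    seed: int
    table: pd.DataFrame
    gamma: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    pleio: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


@dataclass
class SimDataset:
    """Simulated inputs plus their ground truth."""

    config: SimConfig
    genes: list[GeneRecord]
    variants: dict[str, pd.DataFrame]  # gene_id -> variant metadata
    ld: dict[str, LDMatrix]  # gene_id -> region LD
    exposure: dict[str, pd.DataFrame]  # cell_type -> eQTL table (beta dialect)
    outcome: pd.DataFrame
    truth: SimTruth
    bulk: pd.DataFrame | None = None

    def ld_by_chrom(self) -> dict[str, LDMatrix]:
        """Block-diagonal per-chromosome LD (regions are unlinked)."""
        by_chrom: dict[str, list[str]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.chrom, []).append(g.gene_id)
        out = {}
        for chrom, gene_ids in by_chrom.items():
            ids: list[str] = []
            blocks = []
            for gid in gene_ids:
                ids.extend(self.ld[gid].variant_ids)
                blocks.append(self.ld[gid].r)
            m = len(ids)
            r = np.zeros((m, m))
            ofs = 0
            for b in blocks:
                k = b.shape[0]
                r[ofs:ofs + k, ofs:ofs + k] = b
                ofs += k
            out[chrom] = LDMatrix(ids, r)
        return out


def ar1_corr(m: int, decay: float) -> np.ndarray:
    """AR(1) correlation matrix, ``r[i][j] = decay**|i-j|``."""
    idx = np.arange(m)
    return decay ** np.abs(idx[:, None] - idx[None, :])


def simulate_ld_panel(m: int, decay: float, seed: int,
                      n_panel: int = 1_000) -> tuple[LDMatrix, np.ndarray]:
    """AR(1) LD matrix plus a genotype-dosage panel realizing it.

    Dosages are continuous (imputation-style): correlated Gaussians rescaled
    to mean ``2 f`` and variance ``2 f (1 - f)`` per variant, so their
    empirical correlation converges to the theoretical matrix as the panel
    grows.
    """
    if not 0.0 <= decay < 1.0:
        raise ValueError("decay must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    r = ar1_corr(m, decay)
    chol = np.linalg.cholesky(r + 1e-12 * np.eye(m))
    z = rng.standard_normal((n_panel, m)) @ chol.T
    f = rng.uniform(0.05, 0.95, size=m)
    dosages = 2.0 * f + z * np.sqrt(2.0 * f * (1.0 - f))
    ids = [f"panelvar_{i:05d}" for i in range(m)]
    return LDMatrix(ids, r), dosages


def _gene_layout(cfg: SimConfig) -> tuple[list[GeneRecord], dict[str, pd.DataFrame]]:
    """Place genes on chromosomes and lay variants across each cis region."""
    genes: list[GeneRecord] = []
    variants: dict[str, pd.DataFrame] = {}
    m = cfg.variants_per_region
    span = 1_000_000  # variants span +/- 500 kb around the gene start
    for g in range(cfg.n_genes):
        chrom = str(g % _N_CHROMS + 1)
        start = 2_000_000 + (g // _N_CHROMS) * _REGION_SPACING
        gene_id = f"GENE{g:04d}"
        genes.append(GeneRecord(gene_id, chrom, start, start + _GENE_LENGTH))
        pos = start - span // 2 + (np.arange(m) * (span // m))
        variants[gene_id] = pd.DataFrame({
            "variant_id": [f"var_{g:04d}_{i:04d}" for i in range(m)],
            "chrom": chrom,
            "pos": pos.astype(int),
            "gene_region": gene_id,
        })
    return genes, variants


def build_truth(cfg: SimConfig) -> tuple[SimTruth, list[GeneRecord],
                                         dict[str, pd.DataFrame],
                                         dict[str, LDMatrix]]:
    """Draw ground truth: layout, alleles, effects, pleiotropy assignments."""
    rng = np.random.default_rng(cfg.seed)
    genes, variants = _gene_layout(cfg)
    cells = [f"cell{c:02d}" for c in range(cfg.n_cell_types)]
    m = cfg.variants_per_region
    r = ar1_corr(m, cfg.ld_decay)

    ld: dict[str, LDMatrix] = {}
    rows = []
    gamma: dict[str, np.ndarray] = {}
    pleio: dict[str, np.ndarray] = {}
    pleio_frac, sigma_y = cfg.pleiotropy
    lo, hi = cfg.eqtl_effect_range

    for gene, vmeta in zip(genes, variants.values()):
        gid = gene.gene_id
        ld[gid] = LDMatrix(list(vmeta["variant_id"]), r)
        # allele assignment and frequencies
        eaf = rng.uniform(0.05, 0.95, size=m)
        pal = rng.random(m) < cfg.palindromic_fraction
        pairs = [
            _PALINDROMIC_ALLELES[int(rng.integers(2))] if is_pal
            else _SAFE_ALLELES[int(rng.integers(4))]
            for is_pal in pal
        ]
        vmeta["effect_allele"] = [p[0] for p in pairs]
        vmeta["other_allele"] = [p[1] for p in pairs]
        vmeta["eaf"] = eaf

        # sparse joint eQTL effects, shared across this gene's cell types
        g_vec = np.zeros(m)
        causal_idx = [int(rng.integers(m))]
        if rng.random() < cfg.secondary_causal_fraction:
            far = [i for i in range(m) if abs(i - causal_idx[0]) > m // 4]
            if far:
                causal_idx.append(int(rng.choice(far)))
        for ci in causal_idx:
            g_vec[ci] = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
        gamma[gid] = g_vec

        # which cell types express an eQTL for this gene
        if rng.random() < cfg.cell_specific_fraction or cfg.n_cell_types == 1:
            eqtl_cells = [cells[int(rng.integers(cfg.n_cell_types))]]
        else:
            size = int(rng.integers(2, cfg.n_cell_types + 1))
            eqtl_cells = sorted(rng.choice(cells, size=size, replace=False))

        # causal effect on the outcome and pleiotropy flag
        if rng.random() < cfg.causal_gene_fraction:
            kind, par = cfg.alpha_spec
            alpha = par if kind == "fixed" else float(rng.normal(0.0, par))
        else:
            alpha = 0.0
        has_pleio = rng.random() < pleio_frac
        pleio[gid] = (rng.normal(0.0, np.sqrt(sigma_y), size=m)
                      if has_pleio else np.zeros(m))

        causal_ids = ",".join(vmeta["variant_id"].iloc[causal_idx])
        for cell in eqtl_cells:
            rows.append({
                "gene_id": gid, "cell_type": cell,
                "causal_variants": causal_ids,
                "gamma_max": float(g_vec[causal_idx[0]]),
                "alpha": alpha,
                "pleiotropic": has_pleio,
                "sigma_y": sigma_y if has_pleio else 0.0,
            })

    truth = SimTruth(cfg, cfg.seed, pd.DataFrame(rows), gamma, pleio)
    return truth, genes, variants, ld


def _marginal_table(vmeta: pd.DataFrame, gene_id: str, mean: np.ndarray,
                    chol: np.ndarray, n: int, rng: np.random.Generator,
                    cell_type: str | None = None) -> pd.DataFrame:
    """Observed marginal effects: mean + correlated noise at sample size n."""
    m = len(vmeta)
    se = 1.0 / np.sqrt(n)
    beta = mean + chol @ rng.standard_normal(m) * se
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    df = vmeta[["variant_id", "chrom", "pos", "effect_allele",
                "other_allele", "eaf"]].copy()
    df["beta"] = beta
    df["se"] = se
    df["p"] = p
    df["n"] = n
    df["gene_id"] = gene_id
    if cell_type is not None:
        df["cell_type"] = cell_type
    return df


def simulate_cell_eqtl(cfg: SimConfig, truth: SimTruth,
                       variants: dict[str, pd.DataFrame],
                       rng: np.random.Generator) -> dict[str, pd.DataFrame]:
    """Per-cell-type cis-eQTL summary tables (beta dialect, rho columns added).

    Marginal effects are LD-propagated joint effects plus sampling noise with
    covariance ``R / n_exposure``.  The emitted tables carry both dialects:
    beta/se plus the equivalent Spearman ``rho`` (so that
    ``spearman_to_beta(rho, eaf, p)`` reproduces beta/se to round-trip
    tolerance).
    """
    m = cfg.variants_per_region
    chol = np.linalg.cholesky(ar1_corr(m, cfg.ld_decay) + 1e-12 * np.eye(m))
    cells = [f"cell{c:02d}" for c in range(cfg.n_cell_types)]
    by_cell: dict[str, list[pd.DataFrame]] = {c: [] for c in cells}
    pairs = truth.table.set_index(["gene_id", "cell_type"])
    r = ar1_corr(m, cfg.ld_decay)
    for gid, vmeta in variants.items():
        marg = r @ truth.gamma[gid]
        for cell in cells:
            if (gid, cell) not in pairs.index:
                continue
            df = _marginal_table(vmeta, gid, marg, chol, cfg.n_exposure, rng,
                                 cell_type=cell)
            df["rho"] = df["beta"] * np.sqrt(2.0 * df["eaf"] * (1.0 - df["eaf"]))
            by_cell[cell].append(df)
    return {
        cell: (pd.concat(frames, ignore_index=True) if frames
               else pd.DataFrame())
        for cell, frames in by_cell.items()
    }


def to_rho_dialect(table: pd.DataFrame) -> pd.DataFrame:
    """Spearman-dialect view of an exposure table (drops beta/se)."""
    return table.drop(columns=["beta", "se"])


def simulate_outcome_gwas(cfg: SimConfig, truth: SimTruth,
                          variants: dict[str, pd.DataFrame],
                          rng: np.random.Generator) -> pd.DataFrame:
    """Outcome GWAS summary table over all regions (log-odds scale).

    Marginal effects are ``alpha * R gamma + R c`` plus sampling noise at
    ``n_outcome``; a configured fraction of rows is emitted with swapped
    allele orientation (beta negated, eaf complemented) and palindromic
    variants carry ambiguous alleles, to exercise harmonization.
    """
    m = cfg.variants_per_region
    r = ar1_corr(m, cfg.ld_decay)
    chol = np.linalg.cholesky(r + 1e-12 * np.eye(m))
    alpha_by_gene = (truth.table.drop_duplicates("gene_id")
                     .set_index("gene_id")["alpha"])
    frames = []
    for gid, vmeta in variants.items():
        alpha = float(alpha_by_gene.get(gid, 0.0))
        mean = alpha * (r @ truth.gamma[gid]) + r @ truth.pleio[gid]
        df = _marginal_table(vmeta, gid, mean, chol, cfg.n_outcome, rng)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    flip = rng.random(len(out)) < cfg.flip_fraction
    ea = out["effect_allele"].to_numpy(copy=True)
    oa = out["other_allele"].to_numpy(copy=True)
    out.loc[flip, "effect_allele"] = oa[flip]
    out.loc[flip, "other_allele"] = ea[flip]
    out.loc[flip, "beta"] = -out.loc[flip, "beta"]
    out.loc[flip, "eaf"] = 1.0 - out.loc[flip, "eaf"]
    return out.drop(columns=["gene_id"])


def simulate_bulk_eqtl(cfg: SimConfig, truth: SimTruth,
                       variants: dict[str, pd.DataFrame],
                       rng: np.random.Generator,
                       mixture_noise_sd: float = 0.05) -> pd.DataFrame:
    """Bulk-tissue eQTL table: a mixture of cell-type effects plus noise.

    The bulk joint effect per gene is the cell-type-shared joint effect
    attenuated by the fraction of contexts expressing the eQTL, plus
    independent perturbation of magnitude ``mixture_noise_sd`` — emulating
    how cell-specific regulation dilutes into whole-tissue profiles.
    """
    m = cfg.variants_per_region
    r = ar1_corr(m, cfg.ld_decay)
    chol = np.linalg.cholesky(r + 1e-12 * np.eye(m))
    n_cells_by_gene = truth.table.groupby("gene_id")["cell_type"].nunique()
    frames = []
    for gid, vmeta in variants.items():
        w = float(n_cells_by_gene.get(gid, 0)) / cfg.n_cell_types
        g_bulk = w * truth.gamma[gid].copy()
        nz = truth.gamma[gid] != 0
        g_bulk[nz] += rng.normal(0.0, mixture_noise_sd, size=int(nz.sum()))
        df = _marginal_table(vmeta, gid, r @ g_bulk, chol, cfg.n_bulk, rng,
                             cell_type="bulk")
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def simulate_dataset(cfg: SimConfig, include_bulk: bool = False) -> SimDataset:
    """Generate a complete dataset; a pure function of (cfg, cfg.seed)."""
    truth, genes, variants, ld = build_truth(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    exposure = simulate_cell_eqtl(cfg, truth, variants, rng)
    outcome = simulate_outcome_gwas(cfg, truth, variants, rng)
    bulk = (simulate_bulk_eqtl(cfg, truth, variants, rng)
            if include_bulk else None)
    return SimDataset(cfg, genes, variants, ld, exposure, outcome, truth, bulk)


__all__ = [
    "SimConfig",
    "SimDataset",
    "SimTruth",
    "ar1_corr",
    "build_truth",
    "simulate_bulk_eqtl",
    "simulate_cell_eqtl",
    "simulate_dataset",
    "simulate_ld_panel",
    "simulate_outcome_gwas",
    "to_rho_dialect",
]
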
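"""End-to-end orchestration: instruments -> MR -> gate -> coloc -> prioritize.

:func:`run_all` drives the whole analysis over an in-memory
:class:`~sccismr.synthetic_data.SimDataset` (or any object exposing the same
fields, e.g. one assembled from files via :func:`load_dataset`) and returns
tidy DataFrames per stage plus a machine-readable run log recording the
seed, every threshold and the row counts at every filter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cis_likelihood import CisMLResult, fit_cis_region, pleiotropy_gate
from .coloc import DEFAULT_PRIORS, ColocResult, coloc_abf
from .instruments import InstrumentConfig, LDMatrix, filter_by_f, ld_clump, \
    select_cis_candidates, steiger_filter
from .mr_core import MRResult, results_to_frame, run_gene_mr
from .prioritize import attach_fdr, assign_genes_to_loci, bulk_concordance, \
    enrichment_to_frame, fisher_enrichment, gws_leads, records_to_frame, \
    single_context_share, three_step_filter
from .sumstats import GeneRecord, harmonize_pair, read_gene_table, \
    read_summary_table

logger = logging.getLogger("sccismr")


@dataclass
class PipelineConfig:
    """Every analysis threshold, with the study defaults."""

    instrument: InstrumentConfig = field(default_factory=InstrumentConfig)
    fdr_threshold: float = 0.05
    coloc_threshold: float = 0.6
    coloc_priors: tuple[float, float, float] = DEFAULT_PRIORS
    gws_p: float = 5e-8
    gws_clump_r2: float = 0.001
    gws_window: int = 500_000
    locus_window: int = 1_000_000
    n_boot: int = 1000
    n_presso_sim: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        inst_keys = {"cis_window", "p_threshold", "clump_r2", "min_f_stat"}
        inst = InstrumentConfig(**{k: v for k, v in raw.items() if k in inst_keys})
        kwargs = {k: v for k, v in raw.items() if k not in inst_keys}
        if "coloc_priors" in kwargs:
            kwargs["coloc_priors"] = tuple(kwargs["coloc_priors"])
        return cls(instrument=inst, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coloc_priors"] = list(self.coloc_priors)
        return d


@dataclass
class PipelineResult:
    """All stage outputs plus the run log."""

    mr: pd.DataFrame
    gate: pd.DataFrame
    coloc: pd.DataFrame
    records: pd.DataFrame
    enrichment: pd.DataFrame
    leads: pd.DataFrame
    log: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("mr", "gate", "coloc", "records", "enrichment", "leads"):
            getattr(self, name).to_csv(outdir / f"{name}.tsv", sep="\t",
                                       index=False)
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(self.log, fh, indent=2, default=str)


def _gate_frame(gate: dict[tuple[str, str], CisMLResult]) -> pd.DataFrame:
    rows = []
    for (gid, cell), res in gate.items():
        rows.append({
            "gene_id": gid, "cell_type": cell, "alpha_hat": res.alpha_hat,
            "alpha_p": res.alpha_p, "sigma_y": res.sigma_y,
            "sigma_y_p": res.sigma_y_p, "n_variants_used": res.n_variants_used,
            "converged": res.converged, "gate_pass": pleiotropy_gate(res),
        })
    return pd.DataFrame(rows)


def _coloc_frame(coloc: dict[tuple[str, str], ColocResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in coloc.values()])


def run_gene_cell(
    gene: GeneRecord,
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ld: LDMatrix,
    cfg: PipelineConfig,
    cell_type: str,
    counts: dict | None = None,
) -> tuple[list[MRResult] | None, CisMLResult | None, ColocResult | None]:
    """Full per-gene x cell-type analysis; None entries when a stage is empty.

    The MR arm consumes clumped, strength- and Steiger-filtered instruments;
    the cis-likelihood gate consumes *all* associated variants (the p-screen
    only); colocalization consumes the full harmonized cis region.
    """
    counts = counts if counts is not None else {}
    icfg = cfg.instrument
    cis_all = exposure[
        (exposure["chrom"].astype(str) == gene.chrom)
        & (exposure["pos"] >= gene.start - icfg.cis_window)
        & (exposure["pos"] <= gene.end + icfg.cis_window)
    ]
    counts["cis_variants"] = len(cis_all)
    candidates = select_cis_candidates(gene, cis_all, icfg)
    counts["p_screen"] = len(candidates)
    if candidates.empty:
        return None, None, None

    # --- MR arm: clump -> F -> harmonize -> Steiger -> estimator ladder
    clumped = ld_clump(candidates, ld, clump_r2=icfg.clump_r2)
    counts["clumped"] = len(clumped)
    strong = filter_by_f(clumped, icfg.min_f_stat)
    counts["f_filter"] = len(strong)
    mr_results = None
    if not strong.empty:
        pairs = harmonize_pair(strong, outcome)
        counts["harmonized"] = len(pairs)
        pairs = steiger_filter(pairs)
        counts["steiger"] = len(pairs)
        if len(pairs):
            mr_results = run_gene_mr(
                pairs, gene.gene_id, cell_type,
                n_boot=cfg.n_boot, n_sim=cfg.n_presso_sim, seed=cfg.seed,
            )
        else:
            logger.info("%s/%s: no instruments survived; gene skipped",
                        gene.gene_id, cell_type)

    # --- gate arm: all associated variants, harmonized, with LD
    region_pairs = harmonize_pair(candidates, outcome)
    gate_result = None
    if len(region_pairs):
        exp_cis = region_pairs.rename(columns={"bx": "beta", "sex": "se"})[
            ["variant_id", "beta", "se"]]
        out_cis = region_pairs.rename(columns={"by": "beta", "sey": "se"})[
            ["variant_id", "beta", "se"]]
        gate_result = fit_cis_region(exp_cis, out_cis, ld,
                                     gene.gene_id, cell_type)

    # --- coloc arm: the full cis region (not only associated variants)
    full_pairs = harmonize_pair(cis_all, outcome)
    coloc_result = None
    if len(full_pairs) >= 2:
        t1 = full_pairs.rename(columns={"bx": "beta", "sex": "se"})[
            ["variant_id", "beta", "se"]]
        t2 = full_pairs.rename(columns={"by": "beta", "sey": "se"})[
            ["variant_id", "beta", "se"]]
        coloc_result = coloc_abf(t1, t2, priors=cfg.coloc_priors,
                                 gene_id=gene.gene_id, cell_type=cell_type)
    return mr_results, gate_result, coloc_result


def run_all(dataset, cfg: PipelineConfig | None = None,
            include_bulk: bool = False) -> PipelineResult:
    """Run the full analysis over a dataset.

    ``dataset`` must expose ``genes`` (GeneRecord list), ``exposure``
    (cell_type -> eQTL DataFrame), ``outcome`` (GWAS DataFrame), ``ld``
    (gene_id -> LDMatrix) and ``ld_by_chrom()``; a
    :class:`~sccismr.synthetic_data.SimDataset` qualifies.
    """
    cfg = cfg or PipelineConfig()
    mr: dict[tuple[str, str], list[MRResult]] = {}
    gate: dict[tuple[str, str], CisMLResult] = {}
    coloc: dict[tuple[str, str], ColocResult] = {}
    filter_counts: dict[str, dict] = {}
    testable: dict[str, set] = {}

    for cell_type, table in dataset.exposure.items():
        if table.empty:
            continue
        for gene in dataset.genes:
            sub = table[table["gene_id"] == gene.gene_id] \
                if "gene_id" in table.columns else table
            if sub.empty:
                continue
            counts: dict = {}
            m, g, c = run_gene_cell(gene, sub, dataset.outcome,
                                    dataset.ld[gene.gene_id], cfg, cell_type,
                                    counts)
            filter_counts[f"{gene.gene_id}/{cell_type}"] = counts
            key = (gene.gene_id, cell_type)
            if m is not None:
                mr[key] = m
                testable.setdefault(cell_type, set()).add(gene.gene_id)
            if g is not None:
                gate[key] = g
            if c is not None:
                coloc[key] = c

    attach_fdr(mr)
    records = three_step_filter(mr, gate, coloc,
                                fdr_threshold=cfg.fdr_threshold,
                                coloc_threshold=cfg.coloc_threshold)

    leads = gws_leads(dataset.outcome, dataset.ld_by_chrom(),
                      p_threshold=cfg.gws_p, clump_r2=cfg.gws_clump_r2,
                      window=cfg.gws_window)
    locus_map = assign_genes_to_loci(dataset.genes, leads,
                                     window=cfg.locus_window)
    for rec in records:
        rec.in_gws_locus = locus_map.get(rec.gene_id, False)

    mr_frame = results_to_frame([r for results in mr.values() for r in results])
    rec_frame = records_to_frame(records)

    # per-cell-type enrichment of FDR-significant genes among testable genes
    enrich_frame = pd.DataFrame()
    if len(testable) >= 2 and len(mr_frame):
        primary = mr_frame[mr_frame["method"].isin(["wald", "ivw"])]
        sig = primary[primary["fdr_q"] <= cfg.fdr_threshold]
        counts_list = []
        for cell_type, genes_tested in sorted(testable.items()):
            k = sig[sig["cell_type"] == cell_type]["gene_id"].nunique()
            counts_list.append((cell_type, int(k), len(genes_tested)))
        if sum(k for _, k, _ in counts_list) > 0:
            enrich_frame = enrichment_to_frame(fisher_enrichment(counts_list))

    log = {
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": cfg.to_dict(),
        "n_gene_cell_tested": len(mr),
        "n_prioritized": int(rec_frame["prioritized"].sum()) if len(rec_frame) else 0,
        "filter_counts": filter_counts,
    }
    if len(mr_frame):
        primary = mr_frame[mr_frame["method"].isin(["wald", "ivw"])]
        sig = primary[primary["fdr_q"] <= cfg.fdr_threshold]
        log["n_fdr_significant"] = int(len(sig))
        if len(sig):
            n_single, n_unique, pct = single_context_share(sig)
            log["single_context_share_pct"] = pct

    result = PipelineResult(mr_frame, _gate_frame(gate), _coloc_frame(coloc),
                            rec_frame, enrich_frame, leads, log)

    if include_bulk and getattr(dataset, "bulk", None) is not None:
        bulk_mr = _run_bulk(dataset, cfg)
        sc = mr_frame[mr_frame["method"].isin(["wald", "ivw"])].copy()
        pri = {(r.gene_id, r.cell_type): r.prioritized for r in records}
        sc["prioritized"] = [pri.get((g, c), False)
                             for g, c in zip(sc["gene_id"], sc["cell_type"])]
        inter, corr = bulk_concordance(sc, bulk_mr,
                                       fdr_threshold=cfg.fdr_threshold)
        result.log["bulk_intersection"] = inter.to_dict(orient="records")
        result.log["bulk_correlation"] = corr.to_dict(orient="records")
    return result


def _run_bulk(dataset, cfg: PipelineConfig) -> pd.DataFrame:
    """Primary MR over the bulk exposure with identical filter settings."""
    rows = []
    for gene in dataset.genes:
        sub = dataset.bulk[dataset.bulk["gene_id"] == gene.gene_id]
        if sub.empty:
            continue
        m, _, _ = run_gene_cell(gene, sub, dataset.outcome,
                                dataset.ld[gene.gene_id], cfg, "bulk")
        if m is not None:
            rows.append(m[0])
    frame = results_to_frame(rows)
    if len(frame):
        from .mr_core import bh_fdr

        frame["fdr_q"] = bh_fdr(frame["p"].to_numpy())
    return frame


def load_dataset(indir) -> "LoadedDataset":
    """Assemble a dataset from a directory of tab-delimited files.

    Expected layout (as written by the CLI ``simulate`` command):
    ``genes.tsv``, ``outcome.tsv``, ``exposure_<cell>.tsv`` and per-region
    ``ld_<gene>.tsv`` matrices (variant ids as header).
    """
    indir = Path(indir)
    genes = read_gene_table(indir / "genes.tsv")
    outcome = read_summary_table(indir / "outcome.tsv", role="outcome")
    exposure = {}
    for path in sorted(indir.glob("exposure_*.tsv")):
        cell = path.stem.removeprefix("exposure_")
        exposure[cell] = read_summary_table(path, role="exposure")
    ld = {}
    for gene in genes:
        path = indir / f"ld_{gene.gene_id}.tsv"
        mat = pd.read_csv(path, sep="\t")
        ld[gene.gene_id] = LDMatrix(list(mat.columns), mat.to_numpy())
    bulk = exposure.pop("bulk", None)
    return LoadedDataset(genes, exposure, outcome, ld, bulk)


@dataclass
class LoadedDataset:
    """File-backed dataset satisfying the :func:`run_all` interface."""

    genes: list[GeneRecord]
    exposure: dict[str, pd.DataFrame]
    outcome: pd.DataFrame
    ld: dict[str, LDMatrix]
    bulk: pd.DataFrame | None = None

    def ld_by_chrom(self) -> dict[str, LDMatrix]:
        from .synthetic_data import SimDataset

        return SimDataset.ld_by_chrom(self)  # reuse the block-diagonal logic


def write_dataset(dataset, outdir) -> None:
    """Write a dataset as the tab-delimited bundle ``load_dataset`` reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [{"gene_id": g.gene_id, "chrom": g.chrom, "start": g.start,
          "end": g.end} for g in dataset.genes]
    ).to_csv(outdir / "genes.tsv", sep="\t", index=False)
    dataset.outcome.to_csv(outdir / "outcome.tsv", sep="\t", index=False)
    for cell, table in dataset.exposure.items():
        table.to_csv(outdir / f"exposure_{cell}.tsv", sep="\t", index=False)
    if getattr(dataset, "bulk", None) is not None:
        dataset.bulk.to_csv(outdir / "exposure_bulk.tsv", sep="\t", index=False)
    for gid, ld in dataset.ld.items():
        pd.DataFrame(ld.r, columns=ld.variant_ids).to_csv(
            outdir / f"ld_{gid}.tsv", sep="\t", index=False)
    if hasattr(dataset, "truth"):
        dataset.truth.table.to_csv(outdir / "truth.tsv", sep="\t", index=False)


__all__ = [
    "LoadedDataset",
    "PipelineConfig",
    "PipelineResult",
    "load_dataset",
    "run_all",
    "run_gene_cell",
    "write_dataset",
]
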
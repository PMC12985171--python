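"""Reading, validation, transformation and harmonization of summary statistics.

Exposure tables are per-cell-type cis-eQTL summary statistics; the association
statistic may arrive either as a standardized per-allele effect (``beta``,
``se``) or as a Spearman correlation (``rho``) with its p-value, in which case
:func:`spearman_to_beta` converts it onto the standardized-beta scale.
Outcome tables are GWAS summary statistics on the log-odds scale for a binary
trait.  All downstream stages consume the harmonized exposure/outcome pairs
produced by :func:`harmonize_pair`.

Tables are plain tab-delimited text with a header; column names are
configurable through a column map.  Coordinates are 1-based inclusive and
variants are matched by identifier, never by position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("sccismr")

#: canonical column names used internally and written by default
DEFAULT_COLUMNS: tuple[str, ...] = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "p",
    "n",
    "rho",
    "gene_id",
    "cell_type",
)

#: columns that must be present (after column-map renaming) in any table
_CORE_REQUIRED = ("variant_id", "effect_allele", "other_allele")

#: unordered allele pairs that are strand-ambiguous
PALINDROMIC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

#: smallest positive normal double; p-values of exactly 0 are clamped here
#: before any quantile transform to keep Z finite
TINY_P = np.finfo(float).tiny


@dataclass(frozen=True)
class GeneRecord:
    """Genomic coordinates of one gene (1-based, inclusive)."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True when the allele pair is strand-ambiguous (A/T or C/G)."""
    return (str(effect_allele).upper(), str(other_allele).upper()) in PALINDROMIC_PAIRS


def spearman_to_beta(rho, f, p):
    """Convert a Spearman correlation to a standardized allelic effect.

    The effect is ``beta = rho / sqrt(2 f (1 - f))`` with standard error
    ``se = |beta| / Z`` where ``Z`` is the two-sided normal quantile of the
    supplied p-value, ``Z = Phi^-1(1 - p/2)``.  By construction
    ``|beta / se| == Z`` exactly.

    Parameters
    ----------
    rho : float or array
        Spearman correlation in (-1, 1).
    f : float or array
        Effect-allele frequency, strictly inside (0, 1).
    p : float or array
        Association p-value in (0, 1); zeros are clamped to the smallest
        positive normal float.

    Returns
    -------
    (beta, se) : tuple of floats or arrays
    """
    rho = np.asarray(rho, dtype=float)
    f = np.asarray(f, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any((f <= 0.0) | (f >= 1.0)):
        raise ValueError("allele frequency must lie strictly inside (0, 1)")
    if np.any(np.abs(rho) >= 1.0):
        raise ValueError("Spearman rho must lie strictly inside (-1, 1)")
    if np.any(p >= 1.0):
        raise ValueError("p-value must be < 1 for the quantile transform")
    p = np.maximum(p, TINY_P)
    beta = rho / np.sqrt(2.0 * f * (1.0 - f))
    z = stats.norm.isf(p / 2.0)  # = Phi^-1(1 - p/2), stable for tiny p
    se = np.abs(beta) / z
    if beta.ndim == 0:
        return float(beta), float(se)
    return beta, se


def beta_to_spearman(beta, se, f):
    """Inverse of :func:`spearman_to_beta`: recover (rho, p) from (beta, se)."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    f = np.asarray(f, dtype=float)
    rho = beta * np.sqrt(2.0 * f * (1.0 - f))
    z = np.abs(beta) / se
    p = 2.0 * stats.norm.sf(z)
    if rho.ndim == 0:
        return float(rho), float(p)
    return rho, p


def _apply_column_map(df: pd.DataFrame, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    if column_map:
        rename = {src: dst for dst, src in column_map.items() if src in df.columns}
        df = df.rename(columns=rename)
    return df


def read_summary_table(
    path,
    role: str = "exposure",
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read and validate a tab-delimited summary-statistics table.

    Parameters
    ----------
    path : str or file-like
        Tab-delimited file with a header row.
    role : {"exposure", "outcome"}
        Only used for log messages; both roles share the same schema.
    column_map : mapping, optional
        ``{canonical_name: file_column_name}`` renames applied before
        validation.

    Returns
    -------
    DataFrame with canonical columns.  Records carrying only a Spearman
    statistic are converted to beta/se via :func:`spearman_to_beta`; rows
    where that conversion is impossible (missing ``eaf``) are dropped and
    counted in the log.

    Raises
    ------
    ValueError
        When the header supplies neither (beta, se) nor (rho, p).
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    df = _apply_column_map(df, column_map)

    missing = [c for c in _CORE_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"summary table is missing required columns: {missing}")
    has_beta = "beta" in df.columns and "se" in df.columns
    has_rho = "rho" in df.columns and "p" in df.columns
    if not has_beta and not has_rho:
        raise ValueError(
            "summary table must carry either (beta, se) or (rho, p); "
            "found neither"
        )

    n_in = len(df)
    for col in ("eaf", "beta", "se", "p", "n", "rho", "pos"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "chrom" in df.columns:
        df["chrom"] = df["chrom"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    df = df.dropna(subset=["variant_id"])
    df = df[(df["effect_allele"] != "") & (df["other_allele"] != "")]
    df = df[df["effect_allele"] != df["other_allele"]]

    if has_beta:
        ok = df["beta"].notna() & df["se"].notna() & (df["se"] > 0)
    else:
        # rho dialect: the transformation needs rho, p and eaf
        if "eaf" not in df.columns:
            raise ValueError(
                "rho-dialect table requires an eaf column for the "
                "Spearman-to-beta transformation"
            )
        ok = (
            df["rho"].notna()
            & df["p"].notna()
            & df["eaf"].notna()
            & (df["eaf"] > 0)
            & (df["eaf"] < 1)
        )
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%s table: dropped %d/%d rows with missing or invalid "
                       "effect fields", role, n_bad, n_in)
    df = df[ok].copy()

    if not has_beta:
        beta, se = spearman_to_beta(
            df["rho"].to_numpy(), df["eaf"].to_numpy(), df["p"].to_numpy()
        )
        df["beta"] = beta
        df["se"] = se
    if "p" not in df.columns:
        df["p"] = 2.0 * stats.norm.sf(np.abs(df["beta"] / df["se"]))
    logger.info("%s table: read %d records (%d input rows)", role, len(df), n_in)
    return df.reset_index(drop=True)


def write_summary_table(df: pd.DataFrame, path) -> None:
    """Write a summary table in the same tab-delimited dialect it is read in."""
    df.to_csv(path, sep="\t", index=False)


def read_gene_table(path, column_map: Mapping[str, str] | None = None) -> list[GeneRecord]:
    """Read a gene coordinate table (gene_id, chrom, start, end)."""
    df = pd.read_csv(path, sep="\t")
    df = _apply_column_map(df, column_map)
    missing = [c for c in ("gene_id", "chrom", "start", "end") if c not in df.columns]
    if missing:
        raise ValueError(f"gene table is missing required columns: {missing}")
    return [
        GeneRecord(str(r.gene_id), str(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples()
    ]


def harmonize_pair(exposure: pd.DataFrame, outcome: pd.DataFrame) -> pd.DataFrame:
    """Align exposure and outcome records onto the exposure effect allele.

    Only variants present in both tables survive.  Palindromic (A/T, C/G)
    variants are removed unconditionally, as are variants whose allele sets
    cannot be reconciled.  When the outcome's effect allele equals the
    exposure's other allele, the outcome beta sign is flipped and its allele
    frequency complemented.

    Returns
    -------
    DataFrame with columns ``variant_id, eaf, bx, sex, px, nx, by, sey, py,
    ny`` (plus ``gene_id``/``cell_type`` carried over from the exposure when
    present).  Removals are logged with reasons; no error is raised.
    """
    exp_cols = ["variant_id", "effect_allele", "other_allele", "eaf", "beta", "se", "p"]
    if "n" in exposure.columns:
        exp_cols.append("n")
    for extra in ("gene_id", "cell_type", "chrom", "pos"):
        if extra in exposure.columns:
            exp_cols.append(extra)
    out_cols = ["variant_id", "effect_allele", "other_allele", "beta", "se", "p"]
    if "n" in outcome.columns:
        out_cols.append("n")
    if "eaf" in outcome.columns:
        out_cols.append("eaf")

    merged = exposure[exp_cols].merge(
        outcome[out_cols], on="variant_id", suffixes=("_x", "_y"), how="inner"
    )
    n_shared = len(merged)

    ea_x = merged["effect_allele_x"]
    oa_x = merged["other_allele_x"]
    ea_y = merged["effect_allele_y"]
    oa_y = merged["other_allele_y"]

    palindromic = [is_palindromic(a, b) for a, b in zip(ea_x, oa_x)]
    palindromic = np.asarray(palindromic, dtype=bool)
    same = (ea_x == ea_y) & (oa_x == oa_y)
    swapped = (ea_x == oa_y) & (oa_x == ea_y)
    reconcilable = (same | swapped).to_numpy()

    n_pal = int(palindromic.sum())
    n_mismatch = int((~reconcilable & ~palindromic).sum())
    keep = reconcilable & ~palindromic
    if n_pal:
        logger.info("harmonize: removed %d palindromic variants", n_pal)
    if n_mismatch:
        logger.info("harmonize: removed %d variants with irreconcilable alleles",
                    n_mismatch)
    merged = merged[keep].copy()
    flip = swapped.to_numpy()[keep]

    by = merged["beta_y"].to_numpy(copy=True)
    by[flip] = -by[flip]
    out = pd.DataFrame(
        {
            "variant_id": merged["variant_id"].to_numpy(),
            "eaf": merged["eaf"].to_numpy() if "eaf" in merged.columns
            else merged["eaf_x"].to_numpy(),
            "bx": merged["beta_x"].to_numpy(),
            "sex": merged["se_x"].to_numpy(),
            "px": merged["p_x"].to_numpy(),
            "by": by,
            "sey": merged["se_y"].to_numpy(),
            "py": merged["p_y"].to_numpy(),
        }
    )
    exp_has_n = "n" in exposure.columns
    out_has_n = "n" in outcome.columns
    if exp_has_n and out_has_n:
        out["nx"] = merged["n_x"].to_numpy()
        out["ny"] = merged["n_y"].to_numpy()
    else:
        out["nx"] = merged["n"].to_numpy() if exp_has_n else np.nan
        out["ny"] = merged["n"].to_numpy() if out_has_n else np.nan
    for extra in ("gene_id", "cell_type", "chrom", "pos"):
        if extra in merged.columns:
            out[extra] = merged[extra].to_numpy()
    logger.info("harmonize: %d shared variants -> %d harmonized pairs",
                n_shared, len(out))
    return out.reset_index(drop=True)


def write_harmonized(pairs: pd.DataFrame, path) -> None:
    """Write harmonized exposure/outcome pairs as tab-delimited text."""
    pairs.to_csv(path, sep="\t", index=False)


__all__ = [
    "DEFAULT_COLUMNS",
    "GeneRecord",
    "PALINDROMIC_PAIRS",
    "TINY_P",
    "beta_to_spearman",
    "harmonize_pair",
    "is_palindromic",
    "read_gene_table",
    "read_summary_table",
    "spearman_to_beta",
    "write_harmonized",
    "write_summary_table",
]
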
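"""Instrument selection: cis window, significance, LD clumping, strength, Steiger.

Instrumental variables for one gene x cell-type are chosen by composing
row-removing filters in a fixed order: cis-window and p-value screen
(:func:`select_cis_candidates`), greedy LD clumping (:func:`ld_clump`),
instrument-strength filter (:func:`f_statistic` / :func:`filter_by_f`) and,
after harmonization with the outcome, directionality filtering
(:func:`steiger_filter`).  Every step only removes rows and logs its counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import GeneRecord

logger = logging.getLogger("sccismr")


@dataclass
class LDMatrix:
    """Signed pairwise correlation matrix over an ordered variant list.

    Clumping consumes r squared; the sign is preserved internally because the
    cis-likelihood model needs it.
    """

    variant_ids: list[str]
    r: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.variant_ids = [str(v) for v in self.variant_ids]
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.variant_ids)
        if self.r.shape != (m, m):
            raise ValueError("LD matrix shape does not match variant list")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-6):
            raise ValueError("LD matrix must have unit diagonal")
        if np.any(np.abs(self.r) > 1.0 + 1e-8):
            raise ValueError("LD entries must lie in [-1, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def index(self, variant_id: str) -> int:
        return self._index[variant_id]

    def submatrix(self, variant_ids) -> np.ndarray:
        idx = [self._index[v] for v in variant_ids]
        return self.r[np.ix_(idx, idx)]

    def r2(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]] ** 2)

    @classmethod
    def from_dosages(cls, dosages: np.ndarray, variant_ids) -> "LDMatrix":
        """Pearson correlation of genotype dosages (columns = variants)."""
        d = np.asarray(dosages, dtype=float)
        r = np.corrcoef(d, rowvar=False)
        r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(r, 1.0)
        return cls(list(variant_ids), r)


@dataclass
class InstrumentConfig:
    """Thresholds for instrument selection.

    cis_window
        Half-width of the cis region around the gene body, in bp.
    p_threshold
        Soft significance screen for candidate eQTLs.
    clump_r2
        Variants correlated at or above this r squared with a kept variant
        are discarded during greedy clumping.
    min_f_stat
        Minimum approximate F statistic (z squared) for instrument strength.
    """

    cis_window: int = 1_000_000
    p_threshold: float = 1e-5
    clump_r2: float = 0.1
    min_f_stat: float = 10.0

    def __post_init__(self) -> None:
        if self.cis_window <= 0 or self.clump_r2 <= 0 or self.min_f_stat <= 0:
            raise ValueError("instrument thresholds must be positive")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must lie in (0, 1)")


def select_cis_candidates(
    gene: GeneRecord, assocs: pd.DataFrame, cfg: InstrumentConfig | None = None
) -> pd.DataFrame:
    """Retain variants inside the gene's cis window passing the p screen.

    A variant qualifies when it sits on the gene's chromosome, its position
    lies within ``[start - cis_window, end + cis_window]`` and its p-value is
    at or below ``p_threshold``.  An empty result is legal.
    """
    cfg = cfg or InstrumentConfig()
    lo = gene.start - cfg.cis_window
    hi = gene.end + cfg.cis_window
    keep = (
        (assocs["chrom"].astype(str) == gene.chrom)
        & (assocs["pos"] >= lo)
        & (assocs["pos"] <= hi)
        & (assocs["p"] <= cfg.p_threshold)
    )
    out = assocs[keep].reset_index(drop=True)
    logger.debug("cis screen %s: %d/%d variants retained", gene.gene_id,
                 len(out), len(assocs))
    return out


def ld_clump(
    candidates: pd.DataFrame,
    ld: LDMatrix,
    clump_r2: float = 0.1,
    min_distance: int | None = None,
) -> pd.DataFrame:
    """Greedy p-value-ordered clumping to an independent variant set.

    Variants are visited by ascending p (ties broken lexicographically by
    variant id, making the result invariant to input order).  A variant is
    kept when its r squared with every already-kept variant is below
    ``clump_r2`` and, if ``min_distance`` is given, it also lies more than
    ``min_distance`` bp from every kept variant on the same chromosome.
    Candidates absent from the LD matrix are dropped with a warning.
    """
    present = candidates["variant_id"].map(lambda v: v in ld)
    n_missing = int((~present).sum())
    if n_missing:
        logger.warning("clump: dropped %d candidates missing from the LD matrix",
                       n_missing)
    cand = candidates[present].sort_values(
        ["p", "variant_id"], kind="mergesort"
    )
    kept_rows = []
    kept_ids: list[str] = []
    for row in cand.itertuples():
        vid = row.variant_id
        independent = all(ld.r2(vid, k) < clump_r2 for k in kept_ids)
        if independent and min_distance is not None and kept_rows:
            for k in kept_rows:
                if str(k.chrom) == str(row.chrom) and abs(int(k.pos) - int(row.pos)) <= min_distance:
                    independent = False
                    break
        if independent:
            kept_rows.append(row)
            kept_ids.append(vid)
    out = pd.DataFrame(kept_rows)
    if len(out):
        out = out.drop(columns=["Index"], errors="ignore")
    else:
        out = candidates.iloc[0:0].copy()
    logger.debug("clump: kept %d/%d variants", len(out), len(candidates))
    return out.reset_index(drop=True)


def f_statistic(bx, sex):
    """Approximate single-instrument F statistic, ``(bx / sex) ** 2``."""
    bx = np.asarray(bx, dtype=float)
    sex = np.asarray(sex, dtype=float)
    if np.any(sex <= 0):
        raise ValueError("standard errors must be positive")
    f = (bx / sex) ** 2
    return float(f) if f.ndim == 0 else f


def filter_by_f(assocs: pd.DataFrame, min_f_stat: float = 10.0) -> pd.DataFrame:
    """Drop candidate instruments with F below ``min_f_stat``."""
    f = f_statistic(assocs["beta"].to_numpy(), assocs["se"].to_numpy())
    out = assocs[np.atleast_1d(f) >= min_f_stat].reset_index(drop=True)
    logger.debug("F filter: kept %d/%d variants", len(out), len(assocs))
    return out


def steiger_r2(z, n):
    """Variance explained by one variant from its z statistic, z^2/(z^2+n)."""
    z = np.asarray(z, dtype=float)
    n = np.asarray(n, dtype=float)
    return z**2 / (z**2 + n)


def steiger_filter(pairs: pd.DataFrame) -> pd.DataFrame:
    """Remove harmonized pairs explaining more outcome than exposure variance.

    Variance explained is approximated on the observed scale as
    ``r2 = z^2 / (z^2 + n)`` for each trait.  Pairs whose sample sizes are
    unknown cannot be evaluated and are retained with a warning.
    """
    zx = pairs["bx"].to_numpy() / pairs["sex"].to_numpy()
    zy = pairs["by"].to_numpy() / pairs["sey"].to_numpy()
    nx = pairs["nx"].to_numpy(dtype=float)
    ny = pairs["ny"].to_numpy(dtype=float)
    evaluable = np.isfinite(nx) & np.isfinite(ny)
    n_unknown = int((~evaluable).sum())
    if n_unknown:
        logger.warning("steiger: %d pairs lack sample sizes and are retained",
                       n_unknown)
    r2x = np.where(evaluable, steiger_r2(zx, np.where(evaluable, nx, 1.0)), np.inf)
    r2y = np.where(evaluable, steiger_r2(zy, np.where(evaluable, ny, 1.0)), 0.0)
    keep = ~evaluable | (r2x > r2y)
    out = pairs[keep].reset_index(drop=True)
    logger.debug("steiger: kept %d/%d pairs", len(out), len(pairs))
    return out


__all__ = [
    "InstrumentConfig",
    "LDMatrix",
    "f_statistic",
    "filter_by_f",
    "ld_clump",
    "select_cis_candidates",
    "steiger_filter",
    "steiger_r2",
]
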
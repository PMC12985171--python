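"""Two-sample Mendelian randomization estimators and sensitivity analyses.

All estimators consume harmonized exposure/outcome pairs (columns ``bx, sex,
by, sey``).  The primary estimate is the Wald ratio for a single instrument
and the inverse-variance-weighted (IVW) estimate for two or more; the
sensitivity ladder adds the weighted median and MR-Egger at three or more
instruments and MR-PRESSO above four (:func:`run_gene_mr`).

IVW uses multiplicative random effects: the fixed-effect standard error is
inflated by ``max(1, sqrt(Q / (k - 1)))`` where Q is Cochran's heterogeneity
statistic, mirroring the common two-sample MR default.  MR-Egger reports
t-distribution p-values on k - 2 degrees of freedom with the exposure effects
oriented non-negative.  The Wald-ratio standard error is the first-order
delta approximation ``sey / |bx|``; with instruments passing F >= 10 the
higher-order terms are negligible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("sccismr")

#: instrument-count thresholds of the method ladder
MIN_IV_IVW = 2
MIN_IV_SENSITIVITY = 3
MIN_IV_PRESSO = 5


@dataclass
class MRResult:
    """One estimator's output for one gene x cell-type."""

    gene_id: str
    cell_type: str
    method: str
    estimate: float
    se: float
    p: float
    n_iv: int
    q_stat: float | None = None
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None
    presso_global_p: float | None = None
    presso_outliers: list[str] = field(default_factory=list)
    fdr_q: float | None = None


def _norm_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def wald_ratio(pair, gene_id: str = "", cell_type: str = "") -> MRResult:
    """Single-instrument causal estimate ``by / bx``.

    The standard error is the first-order delta approximation
    ``sey / |bx|``; the p-value comes from the normal approximation.
    Raises when ``bx`` is zero.
    """
    bx, by, sey = float(pair["bx"]), float(pair["by"]), float(pair["sey"])
    if bx == 0.0:
        raise ValueError("Wald ratio undefined for bx = 0")
    est = by / bx
    se = sey / abs(bx)
    return MRResult(gene_id, cell_type, "wald", est, se, _norm_p(est / se), 1)


def ivw(pairs: pd.DataFrame, gene_id: str = "", cell_type: str = "",
        random_effects: bool = True) -> MRResult:
    """Inverse-variance-weighted estimate: origin-constrained regression of
    ``by`` on ``bx`` with weights ``1 / sey**2``.

    Under multiplicative random effects (the default) the standard error is
    inflated by ``max(1, sqrt(Q / (k - 1)))``; Cochran's Q is always
    reported.
    """
    if len(pairs) < MIN_IV_IVW:
        raise ValueError("IVW requires at least two instruments")
    bx = pairs["bx"].to_numpy(dtype=float)
    by = pairs["by"].to_numpy(dtype=float)
    sey = pairs["sey"].to_numpy(dtype=float)
    if np.any(bx == 0.0):
        raise ValueError("IVW requires all bx != 0")
    w = 1.0 / sey**2
    est = float(np.sum(w * bx * by) / np.sum(w * bx**2))
    se = float(1.0 / np.sqrt(np.sum(w * bx**2)))
    k = len(pairs)
    q = float(np.sum(w * (by - est * bx) ** 2))
    if random_effects and k > 1:
        se *= max(1.0, np.sqrt(q / (k - 1)))
    return MRResult(gene_id, cell_type, "ivw", est, se, _norm_p(est / se),
                    k, q_stat=q)


def mr_egger(pairs: pd.DataFrame, gene_id: str = "", cell_type: str = "") -> MRResult:
    """MR-Egger: weighted regression of ``by`` on ``bx`` with free intercept.

    Exposure effects are oriented non-negative (flipping ``by`` alongside)
    so the intercept measures directional pleiotropy.  Slope and intercept
    p-values use the t distribution on k - 2 degrees of freedom.  Raises for
    fewer than three instruments or a degenerate design (no spread in |bx|).
    """
    k = len(pairs)
    if k < MIN_IV_SENSITIVITY:
        raise ValueError("MR-Egger requires at least three instruments")
    sign = np.sign(pairs["bx"].to_numpy(dtype=float))
    sign[sign == 0] = 1.0
    bx = np.abs(pairs["bx"].to_numpy(dtype=float))
    by = pairs["by"].to_numpy(dtype=float) * sign
    sey = pairs["sey"].to_numpy(dtype=float)
    if np.ptp(bx) == 0.0:
        raise ValueError("MR-Egger design is degenerate: no spread in |bx|")
    w = 1.0 / sey**2
    X = np.column_stack([np.ones(k), bx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ by)
    resid = by - X @ coef
    df = k - 2
    scale = max(1.0, float(np.max(np.abs(by))))
    if np.max(np.abs(resid)) < 1e-10 * scale:  # numerically exact fit
        resid[:] = 0.0
        coef[np.abs(coef) < 1e-10 * scale] = 0.0
    sigma2 = float(np.sum(w * resid**2) / df)
    cov = np.linalg.inv(xtwx) * sigma2
    se = np.sqrt(np.diag(cov))

    def _t_p(coef_i: float, se_i: float) -> float:
        if se_i == 0.0:  # exact-fit degenerate case
            return 1.0 if coef_i == 0.0 else 0.0
        return float(2.0 * stats.t.sf(abs(coef_i / se_i), df))

    p_slope = _t_p(coef[1], se[1])
    p_int = _t_p(coef[0], se[0])
    q = float(np.sum(w * resid**2))
    return MRResult(
        gene_id, cell_type, "egger", float(coef[1]), float(se[1]), p_slope,
        k, q_stat=q, egger_intercept=float(coef[0]), egger_intercept_p=p_int,
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median via linear interpolation of the standardized
    cumulative weight function (Bowden's convention)."""
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= np.sum(w)
    if cum[0] >= 0.5:
        return float(v[0])
    if cum[-1] <= 0.5:
        return float(v[-1])
    i = int(np.searchsorted(cum, 0.5)) - 1
    frac = (0.5 - cum[i]) / (cum[i + 1] - cum[i])
    return float(v[i] + frac * (v[i + 1] - v[i]))


def weighted_median(pairs: pd.DataFrame, gene_id: str = "", cell_type: str = "",
                    n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted-median MR estimate with a parametric-bootstrap standard error.

    Per-instrument Wald ratios are combined with inverse-variance weights
    ``(bx / sey)**2``; the estimate is robust while less than half the weight
    comes from invalid instruments.  The bootstrap redraws ``bx`` and ``by``
    from their sampling distributions with a fixed seed, so repeated calls
    are deterministic.
    """
    if len(pairs) < MIN_IV_SENSITIVITY:
        raise ValueError("weighted median requires at least three instruments")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    bx = pairs["bx"].to_numpy(dtype=float)
    by = pairs["by"].to_numpy(dtype=float)
    sex = pairs["sex"].to_numpy(dtype=float)
    sey = pairs["sey"].to_numpy(dtype=float)
    ratios = by / bx
    weights = (bx / sey) ** 2
    est = _weighted_median(ratios, weights)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sex)
        by_b = rng.normal(by, sey)
        bx_b[bx_b == 0.0] = np.finfo(float).eps
        boot[b] = _weighted_median(by_b / bx_b, (bx_b / sey) ** 2)
    se = float(np.std(boot, ddof=1))
    p = _norm_p(est / se) if se > 0 else 1.0
    return MRResult(gene_id, cell_type, "weighted_median", est, se, p, len(pairs))


def _loo_ivw(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes for every instrument, vectorized."""
    num = np.sum(w * bx * by) - w * bx * by
    den = np.sum(w * bx**2) - w * bx**2
    return num / den


def mr_presso(pairs: pd.DataFrame, gene_id: str = "", cell_type: str = "",
              n_sim: int = 1000, seed: int = 0) -> MRResult:
    """MR-PRESSO global pleiotropy test with outlier detection.

    The observed statistic is the weighted leave-one-out residual sum of
    squares; its null distribution is built from ``n_sim`` parametric
    simulations under the no-pleiotropy model (``by ~ N(bx * beta_loo,
    sey)``, ``bx ~ N(bx, sex)``).  The global p-value is the add-one
    empirical exceedance probability, so a run with no exceedances reports
    ``1 / (n_sim + 1)`` rather than zero.  Instruments whose observed
    residual is extreme at the Bonferroni-corrected 0.05 level are flagged
    as outliers; when the global test rejects, the reported estimate is the
    outlier-removed IVW.
    """
    k = len(pairs)
    if k < MIN_IV_PRESSO:
        raise ValueError("MR-PRESSO requires more than four instruments")
    if n_sim < 500:
        raise ValueError("n_sim must be at least 500")
    bx = pairs["bx"].to_numpy(dtype=float)
    by = pairs["by"].to_numpy(dtype=float)
    sex = pairs["sex"].to_numpy(dtype=float)
    sey = pairs["sey"].to_numpy(dtype=float)
    w = 1.0 / sey**2

    beta_loo = _loo_ivw(bx, by, w)
    obs_resid2 = w * (by - beta_loo * bx) ** 2
    rss_obs = float(np.sum(obs_resid2))

    rng = np.random.default_rng(seed)
    exceed_global = 0
    exceed_each = np.zeros(k)
    for _ in range(n_sim):
        bx_s = rng.normal(bx, sex)
        by_s = rng.normal(bx * beta_loo, sey)
        bl = _loo_ivw(bx_s, by_s, w)
        r2 = w * (by_s - bl * bx_s) ** 2
        exceed_global += np.sum(r2) >= rss_obs
        exceed_each += r2 >= obs_resid2
    global_p = float((exceed_global + 1) / (n_sim + 1))
    outlier_p = (exceed_each + 1) / (n_sim + 1)
    outlier_mask = outlier_p < 0.05 / k
    variant_ids = (
        pairs["variant_id"].astype(str).to_numpy()
        if "variant_id" in pairs.columns
        else np.array([str(i) for i in range(k)])
    )
    outliers = list(variant_ids[outlier_mask])

    if global_p < 0.05 and outlier_mask.any() and (~outlier_mask).sum() >= 2:
        corrected = ivw(pairs[~outlier_mask], gene_id, cell_type)
        est, se, p, q = corrected.estimate, corrected.se, corrected.p, corrected.q_stat
    else:
        full = ivw(pairs, gene_id, cell_type)
        est, se, p, q = full.estimate, full.se, full.p, full.q_stat
    return MRResult(gene_id, cell_type, "presso", est, se, p, k, q_stat=q,
                    presso_global_p=global_p, presso_outliers=outliers)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def run_gene_mr(pairs: pd.DataFrame, gene_id: str = "", cell_type: str = "",
                n_boot: int = 1000, n_sim: int = 1000, seed: int = 0) -> list[MRResult]:
    """Dispatch the estimator ladder for one gene x cell-type.

    One instrument: Wald ratio only.  Two or more: IVW is the primary
    estimate.  Three or more: weighted median and MR-Egger are attached.
    More than four: MR-PRESSO is attached.  An empty instrument set is the
    caller's responsibility (the gene is skipped upstream with a log entry).
    """
    k = len(pairs)
    if k == 0:
        raise ValueError("run_gene_mr requires a non-empty instrument set")
    results: list[MRResult] = []
    if k == 1:
        results.append(wald_ratio(pairs.iloc[0], gene_id, cell_type))
        return results
    results.append(ivw(pairs, gene_id, cell_type))
    if k >= MIN_IV_SENSITIVITY:
        results.append(weighted_median(pairs, gene_id, cell_type,
                                       n_boot=n_boot, seed=seed))
        try:
            results.append(mr_egger(pairs, gene_id, cell_type))
        except ValueError as exc:  # degenerate design
            logger.warning("%s/%s: MR-Egger skipped (%s)", gene_id, cell_type, exc)
    if k >= MIN_IV_PRESSO:
        results.append(mr_presso(pairs, gene_id, cell_type,
                                 n_sim=n_sim, seed=seed + 1))
    return results


def results_to_frame(results: list[MRResult]) -> pd.DataFrame:
    """Flatten MRResult objects into a tidy DataFrame."""
    rows = []
    for r in results:
        rows.append(
            {
                "gene_id": r.gene_id,
                "cell_type": r.cell_type,
                "method": r.method,
                "estimate": r.estimate,
                "se": r.se,
                "p": r.p,
                "n_iv": r.n_iv,
                "q_stat": r.q_stat,
                "egger_intercept": r.egger_intercept,
                "egger_intercept_p": r.egger_intercept_p,
                "presso_global_p": r.presso_global_p,
                "presso_outliers": ",".join(r.presso_outliers),
                "fdr_q": r.fdr_q,
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "MRResult",
    "bh_fdr",
    "ivw",
    "mr_egger",
    "mr_presso",
    "results_to_frame",
    "run_gene_mr",
    "wald_ratio",
    "weighted_median",
]
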
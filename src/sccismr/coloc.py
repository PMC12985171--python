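"""Single-causal-variant colocalization via Wakefield approximate Bayes factors.

For one cis region the method asks whether the eQTL signal (trait 1) and the
outcome GWAS signal (trait 2) are driven by the same causal variant.  Five
hypotheses partition the configuration space: no association (H0), trait-1
only (H1), trait-2 only (H2), both traits with distinct causal variants (H3)
and both traits sharing one causal variant (H4).  Per-variant evidence is the
Wakefield approximate Bayes factor with shrinkage ``r = W / (V + W)``:

    log ABF = 0.5 * ( log(1 - r) + r * z**2 )

with ``V = se**2``, ``W = prior_sd**2`` and ``z = beta / se``.  Hypothesis
sums are accumulated in log space (log-sum-exp throughout; no probability
underflow) and combined with per-variant prior probabilities ``p1``, ``p2``
and ``p12``.  A region colocalizes when ``PP.H4 / (PP.H3 + PP.H4)`` reaches
the decision threshold (default 0.6, inclusive).

Default prior effect standard deviations follow the conventional choices for
a quantitative exposure (0.2 per SD of expression) and a binary outcome
(0.15 on the log-odds scale).  Colocalization consumes the full cis-region
summary statistics, not the clumped instruments, consistent with the
single-causal-variant framework.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger("sccismr")

DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)
PRIOR_SD_QUANTITATIVE = 0.2
PRIOR_SD_BINARY = 0.15
DECISION_THRESHOLD = 0.6

_HYP = ("pp_h0", "pp_h1", "pp_h2", "pp_h3", "pp_h4")


@dataclass
class ColocResult:
    """Posterior hypothesis probabilities and the shared-signal decision."""

    gene_id: str
    cell_type: str
    pp: np.ndarray  # PP.H0 .. PP.H4
    ratio: float  # PP.H4 / (PP.H3 + PP.H4); nan when the denominator is 0
    colocalized: bool
    n_variants: int
    flagged: str = ""

    def as_dict(self) -> dict:
        d = {"gene_id": self.gene_id, "cell_type": self.cell_type}
        d.update({k: float(v) for k, v in zip(_HYP, self.pp)})
        d.update(ratio=self.ratio, colocalized=self.colocalized,
                 n_variants=self.n_variants, flagged=self.flagged)
        return d


def log_abf(beta, se, prior_sd: float) -> np.ndarray:
    """Wakefield log approximate Bayes factor for one association."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    v = se**2
    w = float(prior_sd) ** 2
    r = w / (v + w)
    z2 = (beta / se) ** 2
    out = 0.5 * (np.log1p(-r) + r * z2)
    return float(out) if out.ndim == 0 else out


def coloc_abf(
    trait1: pd.DataFrame,
    trait2: pd.DataFrame,
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
    prior_sd1: float = PRIOR_SD_QUANTITATIVE,
    prior_sd2: float = PRIOR_SD_BINARY,
    gene_id: str = "",
    cell_type: str = "",
) -> ColocResult:
    """Posterior probabilities of the five colocalization hypotheses.

    ``trait1`` and ``trait2`` carry columns ``variant_id, beta, se`` over the
    harmonized region; only shared variants enter.  Regions with fewer than
    two shared variants are flagged ``insufficient`` (uniform-prior-free
    posteriors are not meaningful there) and never colocalize.
    """
    p1, p2, p12 = priors
    t1 = trait1.set_index("variant_id")
    t2 = trait2.set_index("variant_id")
    shared = [v for v in t1.index if v in t2.index]
    m = len(shared)
    if m < 2:
        logger.warning("coloc %s/%s: %d shared variants, flagged insufficient",
                       gene_id, cell_type, m)
        return ColocResult(gene_id, cell_type,
                           np.array([np.nan] * 5), np.nan, False, m,
                           flagged="insufficient")
    l1 = log_abf(t1.loc[shared, "beta"].to_numpy(),
                 t1.loc[shared, "se"].to_numpy(), prior_sd1)
    l2 = log_abf(t2.loc[shared, "beta"].to_numpy(),
                 t2.loc[shared, "se"].to_numpy(), prior_sd2)

    ls1 = logsumexp(l1)
    ls2 = logsumexp(l2)
    ls12 = logsumexp(l1 + l2)
    # sum over i != j of exp(l1_i + l2_j) = exp(ls1 + ls2) - exp(ls12)
    both = ls1 + ls2
    diff = ls12 - both
    if diff >= 0:
        # numerically, the shared-variant term exhausts the cross product
        lh3 = -np.inf
    else:
        lh3 = both + np.log1p(-np.exp(diff))

    log_unnorm = np.array([
        0.0,
        np.log(p1) + ls1,
        np.log(p2) + ls2,
        np.log(p1) + np.log(p2) + lh3,
        np.log(p12) + ls12,
    ])
    pp = np.exp(log_unnorm - logsumexp(log_unnorm))
    pp /= pp.sum()
    denom = pp[3] + pp[4]
    ratio = float(pp[4] / denom) if denom > 0 else np.nan
    result = ColocResult(gene_id, cell_type, pp, ratio, False, m)
    result.colocalized = coloc_decision(result)
    return result


def coloc_decision(result: ColocResult, threshold: float = DECISION_THRESHOLD) -> bool:
    """Shared-signal call: ``PP.H4 / (PP.H3 + PP.H4) >= threshold`` (inclusive).

    A flagged result, or one with ``PP.H3 + PP.H4 == 0``, never colocalizes.
    """
    if result.flagged:
        return False
    if not np.isfinite(result.ratio):
        return False
    return bool(result.ratio >= threshold)


__all__ = [
    "ColocResult",
    "DECISION_THRESHOLD",
    "DEFAULT_PRIORS",
    "PRIOR_SD_BINARY",
    "PRIOR_SD_QUANTITATIVE",
    "coloc_abf",
    "coloc_decision",
    "log_abf",
]
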
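"""Methylated-CG (mCG) calling against the bisulfite non-conversion background.

A cytosine with ``k`` methylated reads out of ``n`` is tested one-sided
against the background non-conversion rate ``p0`` (default 0.3%, the
fraction of truly unmethylated cytosines that escape bisulfite
conversion, as measured on unmethylated lambda DNA spike-ins):

    p = P(X >= k),  X ~ Binomial(n, p0)

P-values are Benjamini-Hochberg adjusted per methylome (one species x
stage sample) and a site is an mCG when q < 0.01 and its raw methylation
level k/n exceeds 5%.  Sites need at least five uniquely mapped reads to
be tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class McgCallParams:
    """Thresholds of the mCG caller.

    p0: binomial null success probability (non-conversion rate).
    min_reads: minimum total reads for a site to be tested (>=5 reads,
        i.e. "more than four").
    q_threshold: BH q-value cut-off (strict <).
    level_threshold: raw-level cut-off (strict >).
    """

    p0: float = 0.003
    min_reads: int = 5
    q_threshold: float = 0.01
    level_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.p0 < self.level_threshold < 1):
            raise ValueError("need 0 < p0 < level_threshold < 1")
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")


def depth_filter(sites: pd.DataFrame, min_reads: int = 5) -> pd.DataFrame:
    """Keep sites with total_reads >= min_reads."""
    return sites[sites["total_reads"] >= min_reads].reset_index(drop=True)


def binomial_tail_p(k, n, p0: float):
    """Upper-tail binomial probability P(X >= k) for X ~ Binomial(n, p0).

    Vectorised over ``k`` and ``n``.  Exact (scipy's regularised
    incomplete-beta survival function, no normal approximation).
    """
    k = np.asarray(k)
    n = np.asarray(n)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("need 0 <= k <= n")
    if not 0 < p0 < 1:
        raise ValueError("need 0 < p0 < 1")
    # sf is P(X > k-1) = P(X >= k)
    return stats.binom.sf(k - 1, n, p0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_mcgs(sites: pd.DataFrame, params: McgCallParams | None = None) -> pd.DataFrame:
    """Test every (depth-filtered) site and set pvalue/qvalue/is_mcg.

    BH is applied jointly over all sites of the given sample.  Rows are
    returned in deterministic (chrom, pos, strand) order.
    """
    params = params or McgCallParams()
    out = sites.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
    if len(out) == 0:
        logger.warning("call_mcgs: zero sites after filtering")
        return out
    out["pvalue"] = binomial_tail_p(out["meth_reads"].to_numpy(),
                                    out["total_reads"].to_numpy(), params.p0)
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    out["is_mcg"] = pd.array(
        (out["qvalue"].to_numpy() < params.q_threshold)
        & (out["level"].to_numpy() > params.level_threshold),
        dtype="boolean",
    )
    return out


def methylome_summary(sites: pd.DataFrame,
                      feature_categories: pd.Series | None = None) -> dict:
    """Summarise one called methylome.

    Returns the global mCG fraction, the overall weighted methylation
    level, the bimodality split among mCGs (fraction with level < 10%
    and > 70%), and, when a per-site feature category Series (aligned by
    position) is supplied, mCG counts per category.
    """
    called = sites[sites["is_mcg"].notna()]
    mcg = called[called["is_mcg"].astype(bool)]
    n_sites = len(called)
    n_mcg = len(mcg)
    total = called["total_reads"].sum()
    summary: dict = {
        "n_sites": int(n_sites),
        "n_mcg": int(n_mcg),
        "mcg_fraction": (n_mcg / n_sites) if n_sites else np.nan,
        "mean_level": (called["meth_reads"].sum() / total) if total else np.nan,
        "frac_mcg_level_below_10": (float((mcg["level"] < 0.10).mean()) if n_mcg else np.nan),
        "frac_mcg_level_above_70": (float((mcg["level"] > 0.70).mean()) if n_mcg else np.nan),
    }
    if feature_categories is not None:
        cats = feature_categories.loc[mcg.index]
        counts = cats.value_counts().to_dict()
        summary["mcg_per_feature"] = {str(k): int(v) for k, v in counts.items()}
    return summary
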
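"""Inferential statistics used across the pipeline.

Hypergeometric over-representation (GO enrichment) with BH adjustment,
Games-Howell post-hoc comparisons for unequal-variance groups,
Mann-Whitney-Wilcoxon rank tests (exact by enumeration for small
samples), a two-sided exact binomial comparison of two counts, and the
Pearson product-moment correlation test.

A GO term is significantly enriched when q < 0.05 and the overlap holds
at least five genes.  The enrichment universe is supplied by the caller
(by default the expressed ortholog set of the comparison at hand).
"""

from __future__ import annotations

import logging
import math
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .mcg_calling import bh_adjust

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# hypergeometric enrichment
# ---------------------------------------------------------------------------

def hypergeom_enrichment(gene_set, universe, term_map: pd.DataFrame,
                         q_threshold: float = 0.05,
                         min_genes: int = 5) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per term.

    ``term_map`` has columns gene/term (optional name).  Genes outside
    the universe are ignored; the gene set must be a subset of the
    universe.  BH is applied over all tested terms; a term is enriched
    when q < ``q_threshold`` and the overlap >= ``min_genes``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_set = set(gene_set)
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    tm = term_map[term_map["gene"].isin(universe)]
    names = (tm.drop_duplicates("term").set_index("term")["name"]
             if "name" in tm.columns else None)
    N, n = len(universe), len(gene_set)
    rows = []
    for term, genes in tm.groupby("term")["gene"]:
        members = set(genes)
        K = len(members)
        k = len(members & gene_set)
        # P(X >= k), X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "n_universe": N, "n_term": K,
                     "n_set": n, "n_overlap": k, "pvalue": p})
    out = pd.DataFrame(rows, columns=["term", "n_universe", "n_term", "n_set",
                                      "n_overlap", "pvalue"])
    if len(out):
        out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
        out["enriched"] = (out["qvalue"] < q_threshold) & (out["n_overlap"] >= min_genes)
        if names is not None:
            out.insert(1, "name", out["term"].map(names))
        out = out.sort_values(["qvalue", "term"], kind="mergesort").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Games-Howell post-hoc
# ---------------------------------------------------------------------------

def games_howell(groups: dict[str, np.ndarray] | list[np.ndarray]) -> pd.DataFrame:
    """All pairwise Games-Howell comparisons.

    Welch t statistics with Welch-Satterthwaite degrees of freedom,
    referred to the studentized-range distribution over all k groups
    (q = |t| * sqrt(2)).  Zero-variance pairs give NaN with a warning.
    """
    if isinstance(groups, dict):
        items = list(groups.items())
    else:
        items = [(str(i), g) for i, g in enumerate(groups)]
    if len(items) < 2:
        raise ValueError("need at least two groups")
    k = len(items)
    stats_per = []
    for name, values in items:
        v = np.asarray(values, dtype=float)
        if len(v) < 2:
            raise ValueError(f"group {name!r} needs n >= 2")
        stats_per.append((name, v.mean(), v.var(ddof=1), len(v)))
    rows = []
    for (na, ma, va, n1), (nb, mb, vb, n2) in combinations(stats_per, 2):
        if va == 0 and vb == 0:
            logger.warning("games_howell: zero variance in pair (%s, %s)", na, nb)
            rows.append({"group_a": na, "group_b": nb, "mean_diff": mb - ma,
                         "t": np.nan, "df": np.nan, "pvalue": np.nan})
            continue
        se2 = va / n1 + vb / n2
        t = (mb - ma) / math.sqrt(se2)
        df = se2**2 / ((va / n1)**2 / (n1 - 1) + (vb / n2)**2 / (n2 - 1))
        p = float(stats.studentized_range.sf(abs(t) * math.sqrt(2.0), k, df))
        rows.append({"group_a": na, "group_b": nb, "mean_diff": mb - ma,
                     "t": t, "df": df, "pvalue": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mann-Whitney-Wilcoxon
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of x over y with the midrank tie convention."""
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = ranks[: len(x)].sum()
    return r1 - len(x) * (len(x) + 1) / 2.0


def mann_whitney(x, y, exact_max_n: int = 12) -> tuple[float, float]:
    """Two-sided Mann-Whitney-Wilcoxon test; returns (U, p).

    Exact p by enumeration of all rank assignments when
    n_x + n_y <= ``exact_max_n``; otherwise the normal approximation
    with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    u_obs = _u_statistic(x, y)
    if n1 + n2 <= exact_max_n:
        pooled = np.concatenate([x, y])
        total = n1 * n2
        lo = min(u_obs, total - u_obs)
        hit = 0
        n_assign = 0
        for idx in combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(idx)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            if u <= lo + 1e-12 or u >= total - lo - 1e-12:
                hit += 1
            n_assign += 1
        return u_obs, min(1.0, hit / n_assign)
    # normal approximation with tie correction
    N = n1 + n2
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (N * (N - 1))
    sigma2 = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if sigma2 == 0:
        return u_obs, 1.0
    mean = n1 * n2 / 2.0
    z = (abs(u_obs - mean) - 0.5) / math.sqrt(sigma2)
    return u_obs, float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))


# ---------------------------------------------------------------------------
# two-count binomial comparison, Pearson test
# ---------------------------------------------------------------------------

def binomial_count_comparison(k1: int, k2: int) -> float:
    """Two-sided exact binomial test that two counts share one rate.

    Tests k1 successes in k1 + k2 trials against p = 1/2.
    """
    if k1 < 0 or k2 < 0 or k1 + k2 == 0:
        raise ValueError("need non-negative counts with k1 + k2 > 0")
    return float(stats.binomtest(k1, k1 + k2, 0.5, alternative="two-sided").pvalue)


def pearson_test(x, y) -> tuple[float, float]:
    """Pearson product-moment r with the two-sided t-test p (n - 2 df).

    Returns (NaN, NaN) for zero-variance input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("pearson_test: zero variance")
        return np.nan, np.nan
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
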
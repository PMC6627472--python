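"""TPM quantification, NB differential expression, and ortholog divergence.

Differential expression between adjacent stages is called with a
self-contained negative-binomial Wald test (median-of-ratios size
factors, method-of-moments dispersion shrunk toward the transcriptome
median with a floor): a drop-in for the count-model test an external
tool would normally provide, and interoperable with externally produced
DE tables.  A feature is differentially expressed when q < 0.01 and
|log2 fold change| > 1 (two-sided, base 2).

Ortholog pairs passing the alignment-coverage filter (consensus fraction
> 70% and consensus length > 300 bp) are classified per developmental
phase into five divergence classes from the two species' DE statuses:

    (none, none)           -> DE0
    (up/down, none)        -> DE1-Pt
    (none, up/down)        -> DE1-Pe
    (up, up) | (down, down) -> DE2-identical
    (up, down) | (down, up) -> DE2-opposite

Phase 1 is mycelium -> primordium, phase 2 primordium -> fruit body.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment_stats import pearson_test
from .mcg_calling import bh_adjust

logger = logging.getLogger(__name__)

DIVERGENCE_CLASSES = ("DE0", "DE1-Pt", "DE1-Pe", "DE2-identical", "DE2-opposite")


@dataclass(frozen=True)
class DeParams:
    q_threshold: float = 0.01
    lfc_threshold: float = 1.0
    dispersion_floor: float = 0.01
    dispersion_shrink: float = 0.5  # weight on the per-feature moment estimate


# ---------------------------------------------------------------------------
# TPM
# ---------------------------------------------------------------------------

def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: length-normalised rates scaled to 1e6 per sample.

    All-zero columns become all-NaN with a warning.  Zero or missing
    lengths are an error.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every feature needs a positive length")
    rate = counts.div(lengths, axis=0)
    colsum = rate.sum(axis=0)
    dead = colsum == 0
    if dead.any():
        logger.warning("compute_tpm: %d all-zero sample columns -> NaN", int(dead.sum()))
    tpm = rate.div(colsum.where(~dead), axis=1) * 1e6
    return tpm


def stage_mean_tpm(tpm: pd.DataFrame) -> pd.DataFrame:
    """Mean TPM over replicates, one column per stage (MultiIndex columns in)."""
    return tpm.T.groupby(level="stage", sort=False).mean().T


def expressed_mask(tpm: pd.DataFrame, threshold: float = 1.0) -> pd.Series:
    """Expressed iff replicate-mean TPM exceeds ``threshold`` in >= 1 stage."""
    if tpm.shape[1] == 0:
        return pd.Series(dtype=bool)
    return (stage_mean_tpm(tpm) > threshold).any(axis=1)


# ---------------------------------------------------------------------------
# NB Wald differential-expression test
# ---------------------------------------------------------------------------

def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Size factor per sample: median ratio to the per-feature geometric mean."""
    log_counts = np.log(counts.where(counts > 0))
    log_gmean = log_counts.mean(axis=1)
    usable = log_gmean.notna()
    if usable.sum() == 0:
        logger.warning("size factors: no feature positive in all samples; using totals")
        totals = counts.sum(axis=0).astype(float)
        return totals / np.exp(np.log(totals).mean())
    ratios = log_counts.loc[usable].sub(log_gmean[usable], axis=0)
    return np.exp(ratios.median(axis=0))


def de_test(counts: pd.DataFrame, stage_a: str, stage_b: str,
            params: DeParams | None = None) -> pd.DataFrame:
    """NB Wald test of stage_b (later) vs stage_a (earlier).

    ``counts`` has (stage, replicate) MultiIndex columns with >= 2
    replicates per stage.  Features with zero counts in every sample of
    both stages are untested (status ``none``, q NaN).  Returns a frame
    indexed by feature with log2fc / pvalue / qvalue / status and the
    normalised condition means.
    """
    params = params or DeParams()
    sub = counts.loc[:, counts.columns.get_level_values("stage").isin([stage_a, stage_b])]
    is_a = sub.columns.get_level_values("stage") == stage_a
    n_a, n_b = int(is_a.sum()), int((~is_a).sum())
    if n_a < 2 or n_b < 2:
        raise ValueError("need >= 2 replicates per condition")
    sf = median_of_ratios_size_factors(sub)
    norm = sub.div(sf, axis=1)
    A = norm.loc[:, is_a].to_numpy(dtype=float)
    B = norm.loc[:, ~is_a].to_numpy(dtype=float)
    mu_a, mu_b = A.mean(axis=1), B.mean(axis=1)
    var_a, var_b = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)

    # method-of-moments dispersion, shrunk toward the transcriptome median
    with np.errstate(invalid="ignore", divide="ignore"):
        disp_a = (var_a - mu_a) / mu_a**2
        disp_b = (var_b - mu_b) / mu_b**2
    fin_a, fin_b = np.isfinite(disp_a), np.isfinite(disp_b)
    raw = np.where(fin_a & fin_b, (np.where(fin_a, disp_a, 0) + np.where(fin_b, disp_b, 0)) / 2,
                   np.where(fin_a, disp_a, np.where(fin_b, disp_b, 0.0)))
    positive = raw[raw > 0]
    central = float(np.median(positive)) if positive.size else params.dispersion_floor
    w = params.dispersion_shrink
    alpha = np.maximum(w * np.maximum(raw, 0.0) + (1 - w) * central, params.dispersion_floor)

    tested = (mu_a > 0) | (mu_b > 0)
    lfc = np.log2(mu_b + 0.5) - np.log2(mu_a + 0.5)
    # delta-method variance of log mean under NB sampling
    v_ln = (1.0 / np.maximum(mu_a, 0.5) + alpha) / n_a \
        + (1.0 / np.maximum(mu_b, 0.5) + alpha) / n_b
    se_lfc = np.sqrt(v_ln) / np.log(2.0)
    wald = np.where(se_lfc > 0, lfc / se_lfc, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(wald))
    out = pd.DataFrame({
        "mean_a": mu_a, "mean_b": mu_b, "log2fc": lfc,
        "pvalue": np.where(tested, pvalue, np.nan),
        "qvalue": np.nan, "status": "none",
    }, index=counts.index)
    if tested.any():
        out.loc[tested, "qvalue"] = bh_adjust(pvalue[tested])
    sig = out["qvalue"] < params.q_threshold
    out.loc[sig & (out["log2fc"] > params.lfc_threshold), "status"] = "up"
    out.loc[sig & (out["log2fc"] < -params.lfc_threshold), "status"] = "down"
    out.attrs["transition"] = f"{stage_a}->{stage_b}"
    return out


# ---------------------------------------------------------------------------
# ortholog filtering and divergence classes
# ---------------------------------------------------------------------------

def filter_orthologs(pairs: pd.DataFrame,
                     min_fraction: float = 0.70,
                     min_length_bp: int = 300) -> pd.DataFrame:
    """Set the ``kept`` flag: consensus fraction > 70% and length > 300 bp (strict)."""
    out = pairs.copy()
    out["kept"] = (out["consensus_fraction"] > min_fraction) \
        & (out["consensus_length_bp"] > min_length_bp)
    return out


def classify_divergence(status_a, status_b):
    """Five-way divergence class from two DE statuses (vectorised).

    ``status_a`` belongs to the first species (Pt), ``status_b`` to the
    second (Pe).
    """
    a = pd.Series(status_a).to_numpy(dtype=object)
    b = pd.Series(status_b).to_numpy(dtype=object)
    valid = {"up", "down", "none"}
    bad = (set(a) | set(b)) - valid
    if bad:
        raise ValueError(f"unknown DE status {sorted(bad)}")
    out = np.where(
        (a == "none") & (b == "none"), "DE0",
        np.where((a != "none") & (b == "none"), "DE1-Pt",
                 np.where((a == "none") & (b != "none"), "DE1-Pe",
                          np.where(a == b, "DE2-identical", "DE2-opposite"))))
    if np.isscalar(status_a) or isinstance(status_a, str):
        return str(out.item() if out.ndim == 0 else out[0])
    return out


def classify_pairs(pairs: pd.DataFrame, de_a: pd.DataFrame, de_b: pd.DataFrame,
                   phase: str) -> pd.DataFrame:
    """Divergence class per kept ortholog pair for one phase.

    ``de_a``/``de_b`` are :func:`de_test` outputs for the same transition
    in species a (Pt) and b (Pe).
    """
    kept = pairs[pairs["kept"]] if "kept" in pairs.columns else pairs
    sa = de_a["status"].reindex(kept["gene_a"]).fillna("none").to_numpy()
    sb = de_b["status"].reindex(kept["gene_b"]).fillna("none").to_numpy()
    return pd.DataFrame({
        "gene_a": kept["gene_a"].to_numpy(),
        "gene_b": kept["gene_b"].to_numpy(),
        "phase": phase,
        "status_a": sa,
        "status_b": sb,
        "divergence_class": classify_divergence(sa, sb),
        "log2fc_a": de_a["log2fc"].reindex(kept["gene_a"]).to_numpy(),
        "log2fc_b": de_b["log2fc"].reindex(kept["gene_b"]).to_numpy(),
    })


def foldchange_correlation(classified: pd.DataFrame,
                           subset: str = "all") -> tuple[float, float, int]:
    """Pearson r between the species' log2 fold changes (one phase).

    ``subset``: ``all`` or ``non-DE0`` (pairs diverging in at least one
    species).  Returns (r, p, n); (NaN, NaN, n) for degenerate input.
    """
    df = classified
    if subset == "non-DE0":
        df = df[df["divergence_class"] != "DE0"]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    df = df.dropna(subset=["log2fc_a", "log2fc_b"])
    if len(df) < 3:
        return np.nan, np.nan, len(df)
    r, p = pearson_test(df["log2fc_a"].to_numpy(), df["log2fc_b"].to_numpy())
    return r, p, len(df)


# ---------------------------------------------------------------------------
# methylation-expression coupling
# ---------------------------------------------------------------------------

def methylation_expression_correlation(meth_levels: pd.Series,
                                       mean_tpm: pd.Series,
                                       min_tpm: float = 0.0) -> tuple[float, float, int]:
    """Pearson r between per-feature mCG level and log10 mean TPM.

    Only features with mean TPM > ``min_tpm`` enter (the expressed-TE
    convention).  Returns (r, p, n); NaNs when fewer than 3 features
    survive or a variance is zero.
    """
    joined = pd.concat([meth_levels.rename("meth"), mean_tpm.rename("tpm")],
                       axis=1, join="inner").dropna()
    joined = joined[joined["tpm"] > min_tpm]
    n = len(joined)
    if n < 3:
        return np.nan, np.nan, n
    r, p = pearson_test(joined["meth"].to_numpy(),
                        np.log10(joined["tpm"].to_numpy() + 1e-9))
    return r, p, n


def te_expression_summary(tes: pd.DataFrame, tpm: pd.DataFrame,
                          threshold: float = 1.0) -> pd.DataFrame:
    """Per TE class x stage: total TEs, expressed TEs (TPM > 1), proportion."""
    means = stage_mean_tpm(tpm)
    rows = []
    for klass, grp in tes.groupby("te_class", sort=True):
        ids = grp["id"]
        sub = means.reindex(ids).dropna(how="all")
        for stage in means.columns:
            n_expr = int((sub[stage] > threshold).sum())
            rows.append({"te_class": klass, "stage": stage, "n_total": len(ids),
                         "n_expressed": n_expr,
                         "proportion": n_expr / len(ids) if len(ids) else np.nan})
    return pd.DataFrame(rows)
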
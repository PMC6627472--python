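"""Sliding-window DMR detection between adjacent developmental stages.

Windows of 1 kb sliding by 200 bp tile each chromosome.  A window enters
testing when it holds at least 10 mCGs in at least one of the two stages.
For eligible windows the methylated vs unmethylated read counts pooled
over all covered CG sites form a 2x2 table tested with Fisher's exact
test (reads are the sampling unit, not sites); p-values are BH-adjusted
over the eligible windows of the transition.  Windows with q < 0.01 and
|pooled-level change| >= 0.15 are differential; overlapping windows with
the same direction merge into one DMR.  ``hyper`` means higher
methylation in the *later* stage.

The same machinery applies to fixed regions (methylated promoters and
gene bodies) via :func:`call_differential_regions`, with the >=10
mCG/kb density standing in for the window eligibility count and no
merging step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mcg_calling import bh_adjust

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DmrParams:
    window_size: int = 1000
    step: int = 200
    min_mcg: int = 10
    q_threshold: float = 0.01
    delta_threshold: float = 0.15

    def __post_init__(self) -> None:
        if not (self.window_size >= self.step > 0):
            raise ValueError("need window_size >= step > 0")


def make_windows(chrom_lengths: dict[str, int], size: int = 1000, step: int = 200) -> pd.DataFrame:
    """Tile each chromosome with [k*step, k*step+size) windows, truncated at the end."""
    if not size >= step > 0:
        raise ValueError("need size >= step > 0")
    frames = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, length, step, dtype="int64")
        ends = np.minimum(starts + size, length)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(frames, ignore_index=True)


def _per_chrom_arrays(sites: pd.DataFrame) -> dict[str, dict[str, np.ndarray]]:
    """Sorted position + cumulative count arrays per chromosome for fast range sums."""
    out = {}
    for chrom, grp in sites.groupby("chrom", sort=False):
        grp = grp.sort_values("pos", kind="mergesort")
        mcg = grp["is_mcg"].fillna(False).to_numpy(dtype=bool)
        out[chrom] = {
            "pos": grp["pos"].to_numpy(),
            "cum_meth": np.concatenate([[0], np.cumsum(grp["meth_reads"].to_numpy())]),
            "cum_total": np.concatenate([[0], np.cumsum(grp["total_reads"].to_numpy())]),
            "cum_mcg": np.concatenate([[0], np.cumsum(mcg.astype("int64"))]),
        }
    return out


def _range_sums(arrays, chrom: str, starts: np.ndarray, ends: np.ndarray):
    """(n_mcg, meth, total) summed over sites with start <= pos < end."""
    n = len(starts)
    if chrom not in arrays:
        z = np.zeros(n, dtype="int64")
        return z, z.copy(), z.copy()
    a = arrays[chrom]
    lo = np.searchsorted(a["pos"], starts, side="left")
    hi = np.searchsorted(a["pos"], ends, side="left")
    return (a["cum_mcg"][hi] - a["cum_mcg"][lo],
            a["cum_meth"][hi] - a["cum_meth"][lo],
            a["cum_total"][hi] - a["cum_total"][lo])


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the table [[a, b], [c, d]].

    Sum of hypergeometric probabilities of all tables with the observed
    margins that are no more probable than the observed one.  An all-zero
    margin yields p = 1 by convention.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        logger.warning("fisher_exact_2x2: degenerate margin, returning p=1")
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def _fisher_batch(meth_a, total_a, meth_b, total_b, chunk: int = 2000) -> np.ndarray:
    """Vectorised two-sided Fisher p per row (tables [[ma, ua], [mb, ub]]).

    Sums, over the hypergeometric support with the observed margins, the
    probabilities of all tables no more probable than the observed one;
    log-gamma arithmetic, chunked to bound memory.  Matches
    :func:`fisher_exact_2x2` (and brute-force enumeration) to float
    precision.
    """
    from scipy.special import gammaln

    ma = np.asarray(meth_a, dtype="int64")
    ta = np.asarray(total_a, dtype="int64")
    mb = np.asarray(meth_b, dtype="int64")
    tb = np.asarray(total_b, dtype="int64")
    out = np.empty(len(ma))

    def logC(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    for lo in range(0, len(ma), chunk):
        sl = slice(lo, min(lo + chunk, len(ma)))
        A, TA, B, TB = ma[sl], ta[sl], mb[sl], tb[sl]
        N = TA + TB
        K = TA            # row-1 margin
        n1 = A + B        # methylated-column margin
        kmin = np.maximum(0, K + n1 - N)
        kmax = np.minimum(K, n1)
        counts = (kmax - kmin + 1).astype("int64")
        idx = np.repeat(np.arange(len(A)), counts)
        offs = np.arange(counts.sum()) - np.repeat(np.cumsum(counts) - counts, counts)
        k = kmin[idx] + offs
        logpmf = (logC(K[idx], k) + logC(N[idx] - K[idx], n1[idx] - k)
                  - logC(N[idx], n1[idx]))
        logobs = (logC(K, A) + logC(N - K, n1 - A) - logC(N, n1))
        include = logpmf <= logobs[idx] + 1e-7
        p = np.bincount(idx[include], weights=np.exp(logpmf[include]), minlength=len(A))
        out[sl] = np.clip(p, 0.0, 1.0)
    return out


def _test_regions(regions: pd.DataFrame, sites_a: pd.DataFrame, sites_b: pd.DataFrame,
                  eligible: np.ndarray, params: DmrParams) -> pd.DataFrame:
    """Shared Fisher/BH/threshold machinery for windows and fixed regions."""
    arr_a = _per_chrom_arrays(sites_a)
    arr_b = _per_chrom_arrays(sites_b)
    tests = regions.loc[eligible].reset_index(drop=True).copy()
    cols = {"n_mcg_a": [], "meth_a": [], "total_a": [], "n_mcg_b": [], "meth_b": [], "total_b": []}
    for chrom, grp in tests.groupby("chrom", sort=False):
        s, e = grp["start"].to_numpy(), grp["end"].to_numpy()
        na, ma, ta = _range_sums(arr_a, chrom, s, e)
        nb, mb, tb = _range_sums(arr_b, chrom, s, e)
        tests.loc[grp.index, ["n_mcg_a", "meth_a", "total_a"]] = np.column_stack([na, ma, ta])
        tests.loc[grp.index, ["n_mcg_b", "meth_b", "total_b"]] = np.column_stack([nb, mb, tb])
    for c in ["n_mcg_a", "meth_a", "total_a", "n_mcg_b", "meth_b", "total_b"]:
        tests[c] = tests[c].astype("int64")
    with np.errstate(invalid="ignore", divide="ignore"):
        tests["level_a"] = np.where(tests["total_a"] > 0, tests["meth_a"] / tests["total_a"].replace(0, 1), np.nan)
        tests["level_b"] = np.where(tests["total_b"] > 0, tests["meth_b"] / tests["total_b"].replace(0, 1), np.nan)
    tests["delta"] = tests["level_b"] - tests["level_a"]
    tests["pvalue"] = _fisher_batch(tests["meth_a"].to_numpy(), tests["total_a"].to_numpy(),
                                    tests["meth_b"].to_numpy(), tests["total_b"].to_numpy())
    tests["qvalue"] = bh_adjust(tests["pvalue"].to_numpy())
    significant = tests["qvalue"] < params.q_threshold
    tests["status"] = "none"
    tests.loc[significant & (tests["delta"] >= params.delta_threshold), "status"] = "hyper"
    tests.loc[significant & (tests["delta"] <= -params.delta_threshold), "status"] = "hypo"
    return tests


def window_eligibility(n_mcg_a: np.ndarray, n_mcg_b: np.ndarray, min_mcg: int = 10) -> np.ndarray:
    """Eligible iff >= min_mcg mCGs in at least one stage."""
    return (np.asarray(n_mcg_a) >= min_mcg) | (np.asarray(n_mcg_b) >= min_mcg)


def call_dmrs(sites_a: pd.DataFrame, sites_b: pd.DataFrame,
              chrom_lengths: dict[str, int],
              params: DmrParams | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Window tests and merged DMRs for the transition earlier(a) -> later(b).

    Both site tables must carry is_mcg flags from the mCG caller.
    Returns (window test table over eligible windows, merged DMR table).
    """
    params = params or DmrParams()
    windows = make_windows(chrom_lengths, params.window_size, params.step)
    arr_a = _per_chrom_arrays(sites_a)
    arr_b = _per_chrom_arrays(sites_b)
    n_a = np.zeros(len(windows), dtype="int64")
    n_b = np.zeros(len(windows), dtype="int64")
    for chrom, grp in windows.groupby("chrom", sort=False):
        s, e = grp["start"].to_numpy(), grp["end"].to_numpy()
        n_a[grp.index], _, _ = _range_sums(arr_a, chrom, s, e)
        n_b[grp.index], _, _ = _range_sums(arr_b, chrom, s, e)
    eligible = window_eligibility(n_a, n_b, params.min_mcg)
    if not eligible.any():
        logger.warning("call_dmrs: no eligible windows")
        empty = pd.DataFrame(columns=["chrom", "start", "end", "status"])
        return empty, empty.copy()
    tests = _test_regions(windows, sites_a, sites_b, eligible, params)
    dmrs = merge_windows(tests[tests["status"] != "none"])
    return tests, dmrs


def merge_windows(windows: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping (>= 1 bp) same-status windows into maximal DMR runs.

    Book-ended windows (end == next start) are left unmerged.
    """
    empty = pd.DataFrame(columns=["chrom", "start", "end", "status", "n_windows",
                                  "max_abs_delta", "min_qvalue"])
    if len(windows) == 0:
        return empty
    parts = [_merge_one_status(grp) for _, grp in windows.groupby("status", sort=True)]
    merged = pd.concat(parts, ignore_index=True)
    return merged.sort_values(["chrom", "start", "status"], kind="mergesort").reset_index(drop=True)


def _merge_one_status(windows: pd.DataFrame) -> pd.DataFrame:
    w = windows.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    rows = []
    cur = None
    for r in w.itertuples(index=False):
        if (cur is not None and r.chrom == cur["chrom"] and r.start < cur["end"]):
            cur["end"] = max(cur["end"], r.end)
            cur["n_windows"] += 1
            cur["max_abs_delta"] = max(cur["max_abs_delta"], abs(r.delta))
            cur["min_qvalue"] = min(cur["min_qvalue"], r.qvalue)
        else:
            if cur is not None:
                rows.append(cur)
            cur = {"chrom": r.chrom, "start": int(r.start), "end": int(r.end),
                   "status": r.status, "n_windows": 1,
                   "max_abs_delta": abs(r.delta), "min_qvalue": r.qvalue}
    rows.append(cur)
    return pd.DataFrame(rows)


def evaluate_dmr_calls(dmrs: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Sensitivity/precision of called DMRs against a planted-truth table.

    A truth region is recovered when a called DMR of the same status
    overlaps it by >= 1 bp; a called DMR is a true positive when it
    overlaps a same-status truth region.
    """
    def overlaps(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
        hit = np.zeros(len(a), dtype=bool)
        for i, r in enumerate(a.itertuples(index=False)):
            sel = b[(b["chrom"] == r.chrom) & (b["status"] == r.status)]
            hit[i] = bool(((sel["start"] < r.end) & (r.start < sel["end"])).any())
        return hit

    n_truth, n_called = len(truth), len(dmrs)
    recovered = overlaps(truth.reset_index(drop=True), dmrs) if n_truth else np.array([], bool)
    true_pos = overlaps(dmrs.reset_index(drop=True), truth) if n_called else np.array([], bool)
    return {
        "n_truth": int(n_truth),
        "n_called": int(n_called),
        "sensitivity": float(recovered.mean()) if n_truth else np.nan,
        "precision": float(true_pos.mean()) if n_called else np.nan,
    }


def call_differential_regions(regions: pd.DataFrame,
                              sites_a: pd.DataFrame, sites_b: pd.DataFrame,
                              params: DmrParams | None = None,
                              min_mcg_per_kb: float = 10.0) -> pd.DataFrame:
    """Differential methylation test for fixed regions (MPs / MGBs).

    Eligibility uses the methylated-region density criterion (>= 10
    mCG/kb in at least one stage); eligible regions then run through the
    same Fisher/BH/delta machinery as windows, with no merging.
    ``regions`` needs chrom/start/end (and may carry an ``id`` column).
    """
    params = params or DmrParams()
    if len(regions) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "status"])
    regions = regions.reset_index(drop=True)
    arr_a = _per_chrom_arrays(sites_a)
    arr_b = _per_chrom_arrays(sites_b)
    kb = (regions["end"] - regions["start"]).to_numpy() / 1000.0
    n_a = np.zeros(len(regions), dtype="int64")
    n_b = np.zeros(len(regions), dtype="int64")
    for chrom, grp in regions.groupby("chrom", sort=False):
        s, e = grp["start"].to_numpy(), grp["end"].to_numpy()
        n_a[grp.index], _, _ = _range_sums(arr_a, chrom, s, e)
        n_b[grp.index], _, _ = _range_sums(arr_b, chrom, s, e)
    eligible = (n_a / kb >= min_mcg_per_kb) | (n_b / kb >= min_mcg_per_kb)
    if not eligible.any():
        logger.warning("call_differential_regions: no eligible regions")
        return pd.DataFrame(columns=list(regions.columns) + ["status"])
    return _test_regions(regions, sites_a, sites_b, eligible, params)
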
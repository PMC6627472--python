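"""Genomic feature geography and methylation-by-feature analyses.

Derives promoters (1 kb upstream of the TSS), downstream-1kb regions,
introns and intergenic space from a gene/TE annotation; assigns cytosine
sites to a single feature category under a fixed precedence; identifies
methylated promoters / gene bodies (>= 10 mCG per kb in at least one
stage); and computes metaprofiles, promoter-to-TE distance
distributions, and methylation-by-expression-class comparisons.

Site-to-feature precedence when features overlap (gene-centric, as in
feature-distribution accounting):

    exon > intron > promoter > downstream1kb > TE > intergenic

TE-level analyses use the TE annotation directly and are unaffected by
this flattening.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import GenomeAnnotation

logger = logging.getLogger(__name__)

#: ascending precedence; higher code wins when painting
CATEGORY_CODES = {
    "intergenic": 0,
    "TE": 1,
    "downstream1kb": 2,
    "promoter": 3,
    "intron": 4,
    "exon": 5,
}
CODE_TO_CATEGORY = {v: k for k, v in CATEGORY_CODES.items()}


# ---------------------------------------------------------------------------
# derived features
# ---------------------------------------------------------------------------

def derive_features(annotation: GenomeAnnotation,
                    promoter_bp: int = 1000,
                    downstream_bp: int = 1000) -> GenomeAnnotation:
    """Attach promoter / downstream1kb / intron tables to the annotation.

    Promoters sit strand-upstream of the TSS and are truncated at
    chromosome bounds; downstream regions are the strand-downstream
    analogue at the TES.  Introns are the gene interval minus its exons;
    a gene without exons is treated as a single exon (with a warning).
    Returns a new annotation object; the input is not modified.
    """
    proms, downs, introns = [], [], []
    exons_by_gene = (dict(tuple(annotation.exons.groupby("gene_id", sort=False)))
                     if len(annotation.exons) else {})
    n_exonless = 0
    for g in annotation.genes.itertuples(index=False):
        L = annotation.chrom_lengths[g.chrom]
        if g.strand == "-":
            p = (g.end, min(L, g.end + promoter_bp))
            d = (max(0, g.start - downstream_bp), g.start)
        else:
            p = (max(0, g.start - promoter_bp), g.start)
            d = (g.end, min(L, g.end + downstream_bp))
        if p[0] < p[1]:
            proms.append((g.chrom, p[0], p[1], g.strand, g.id))
        if d[0] < d[1]:
            downs.append((g.chrom, d[0], d[1], g.strand, g.id))
        ex = exons_by_gene.get(g.id)
        if ex is None or len(ex) == 0:
            n_exonless += 1
            continue  # whole body is exonic; no introns
        ex_sorted = ex.sort_values("start")
        prev_end = g.start
        for e in ex_sorted.itertuples(index=False):
            if e.start > prev_end:
                introns.append((g.chrom, prev_end, e.start, g.strand, g.id))
            prev_end = max(prev_end, e.end)
        if g.end > prev_end:
            introns.append((g.chrom, prev_end, g.end, g.strand, g.id))
    if n_exonless:
        logger.warning("derive_features: %d genes without exons treated as single-exon", n_exonless)
    cols = ["chrom", "start", "end", "strand", "gene_id"]
    derived = {
        "promoter": pd.DataFrame(proms, columns=cols),
        "downstream1kb": pd.DataFrame(downs, columns=cols),
        "intron": pd.DataFrame(introns, columns=cols),
    }
    return GenomeAnnotation(annotation.chrom_lengths, annotation.genes,
                            annotation.exons, annotation.tes, derived)


def _effective_exons(annotation: GenomeAnnotation) -> pd.DataFrame:
    """Exon table with exonless genes contributing their whole body."""
    if len(annotation.exons):
        with_ex = set(annotation.exons["gene_id"])
    else:
        with_ex = set()
    extra = annotation.genes[~annotation.genes["id"].isin(with_ex)]
    extra = extra.rename(columns={"id": "gene_id"})[["chrom", "start", "end", "strand", "gene_id"]]
    if len(annotation.exons) == 0:
        return extra
    return pd.concat([annotation.exons, extra], ignore_index=True)


def paint_categories(annotation: GenomeAnnotation, chrom: str) -> np.ndarray:
    """Per-basepair feature category codes for one chromosome (int8).

    Features are painted in ascending precedence so the highest-priority
    category wins at every base.  Requires derived features
    (:func:`derive_features`).
    """
    if "promoter" not in annotation.derived:
        raise ValueError("annotation lacks derived features; call derive_features first")
    L = annotation.chrom_lengths[chrom]
    arr = np.zeros(L, dtype=np.int8)  # intergenic

    def paint(df: pd.DataFrame, code: int) -> None:
        for r in df[df["chrom"] == chrom].itertuples(index=False):
            arr[max(0, r.start):min(L, r.end)] = code

    paint(annotation.tes, CATEGORY_CODES["TE"])
    paint(annotation.derived["downstream1kb"], CATEGORY_CODES["downstream1kb"])
    paint(annotation.derived["promoter"], CATEGORY_CODES["promoter"])
    paint(annotation.derived["intron"], CATEGORY_CODES["intron"])
    paint(_effective_exons(annotation), CATEGORY_CODES["exon"])
    return arr


def assign_sites_to_features(sites: pd.DataFrame,
                             annotation: GenomeAnnotation) -> pd.Series:
    """Category label per site (index-aligned with ``sites``).

    Every site receives exactly one category, so category counts sum to
    the number of sites.
    """
    out = np.zeros(len(sites), dtype=np.int8)
    pos = sites["pos"].to_numpy()
    for chrom, idx in sites.groupby("chrom", sort=False).indices.items():
        if chrom not in annotation.chrom_lengths:
            raise KeyError(f"chromosome {chrom!r} absent from annotation")
        arr = paint_categories(annotation, chrom)
        out[idx] = arr[pos[idx]]
    return pd.Series([CODE_TO_CATEGORY[c] for c in out], index=sites.index, name="category")


# ---------------------------------------------------------------------------
# methylated promoters / gene bodies
# ---------------------------------------------------------------------------

def _region_table(annotation: GenomeAnnotation, kind: str) -> pd.DataFrame:
    if kind == "promoter":
        df = annotation.derived["promoter"].copy()
    elif kind == "gene_body":
        df = annotation.genes.rename(columns={"id": "gene_id"})[
            ["chrom", "start", "end", "strand", "gene_id"]].copy()
    else:
        raise ValueError(f"unknown region kind {kind!r}")
    return df


def identify_mp_mgb(sites_by_stage: Mapping[str, pd.DataFrame],
                    annotation: GenomeAnnotation,
                    density_per_kb: float = 10.0,
                    kind: str = "promoter") -> pd.DataFrame:
    """Methylated promoters (MP) or gene bodies (MGB).

    A region qualifies when its mCG density reaches ``density_per_kb``
    in at least one stage.  The returned table carries, per stage, the
    mCG count, the density, and the pooled methylation level
    (sum meth / sum total over covered CG sites).
    """
    from .dmr_detection import _per_chrom_arrays, _range_sums

    regions = _region_table(annotation, kind)
    if len(regions) == 0:
        return regions.assign(qualifies=pd.Series(dtype=bool))
    regions = regions.reset_index(drop=True)
    kb = (regions["end"] - regions["start"]).to_numpy() / 1000.0
    qualifies = np.zeros(len(regions), dtype=bool)
    for stage, sites in sites_by_stage.items():
        arrays = _per_chrom_arrays(sites)
        n_mcg = np.zeros(len(regions), dtype="int64")
        meth = np.zeros(len(regions), dtype="int64")
        total = np.zeros(len(regions), dtype="int64")
        for chrom, grp in regions.groupby("chrom", sort=False):
            s, e = grp["start"].to_numpy(), grp["end"].to_numpy()
            n_mcg[grp.index], meth[grp.index], total[grp.index] = _range_sums(arrays, chrom, s, e)
        dens = n_mcg / kb
        with np.errstate(invalid="ignore", divide="ignore"):
            level = np.where(total > 0, meth / np.maximum(total, 1), np.nan)
        regions[f"n_mcg_{stage}"] = n_mcg
        regions[f"density_{stage}"] = dens
        regions[f"level_{stage}"] = level
        qualifies |= dens >= density_per_kb
    regions["qualifies"] = qualifies
    stage_cols = [c for c in regions.columns if c.startswith("level_")]
    regions["mean_level"] = regions[stage_cols].mean(axis=1)
    return regions


# ---------------------------------------------------------------------------
# metaprofiles
# ---------------------------------------------------------------------------

def metaprofile(regions: pd.DataFrame,
                sites_by_stage: Mapping[str, pd.DataFrame],
                n_bins: int = 20,
                flank_bp: int = 1000,
                flank_bins: int = 10) -> pd.DataFrame:
    """Mean methylation level per scaled bin across a region set.

    Each region is rescaled to ``n_bins`` body bins with ``flank_bins``
    fixed-width flank bins on either side; site levels are pooled per
    bin weighted by read counts (sum meth / sum total).  Minus-strand
    regions are reversed so bin 0 is always the 5' flank end.  Bins with
    no coverage are NaN.
    """
    if len(regions) == 0:
        raise ValueError("metaprofile of an empty region set")
    total_bins = n_bins + 2 * flank_bins
    out = pd.DataFrame(index=pd.RangeIndex(total_bins, name="bin"))
    for stage, sites in sites_by_stage.items():
        arrays = {c: g.sort_values("pos", kind="mergesort")
                  for c, g in sites.groupby("chrom", sort=False)}
        meth_sum = np.zeros(total_bins)
        tot_sum = np.zeros(total_bins)
        for r in regions.itertuples(index=False):
            grp = arrays.get(r.chrom)
            if grp is None:
                continue
            pos = grp["pos"].to_numpy()
            lo = np.searchsorted(pos, r.start - flank_bp, side="left")
            hi = np.searchsorted(pos, r.end + flank_bp, side="left")
            if hi <= lo:
                continue
            p = pos[lo:hi].astype(float)
            meth = grp["meth_reads"].to_numpy()[lo:hi]
            tot = grp["total_reads"].to_numpy()[lo:hi]
            length = r.end - r.start
            bins = np.empty(len(p), dtype="int64")
            up = p < r.start
            down = p >= r.end
            body = ~(up | down)
            if flank_bins:
                bins[up] = np.clip(((p[up] - (r.start - flank_bp)) / flank_bp * flank_bins), 0,
                                   flank_bins - 1).astype("int64")
                bins[down] = flank_bins + n_bins + np.clip(
                    ((p[down] - r.end) / flank_bp * flank_bins), 0, flank_bins - 1).astype("int64")
            bins[body] = flank_bins + np.clip(((p[body] - r.start) / length * n_bins), 0,
                                              n_bins - 1).astype("int64")
            if getattr(r, "strand", "+") == "-":
                bins = total_bins - 1 - bins
            np.add.at(meth_sum, bins, meth)
            np.add.at(tot_sum, bins, tot)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[stage] = np.where(tot_sum > 0, meth_sum / np.maximum(tot_sum, 1), np.nan)
    return out


# ---------------------------------------------------------------------------
# TE distance & expression-class analyses
# ---------------------------------------------------------------------------

def nearest_te_distance(regions: pd.DataFrame, tes: pd.DataFrame) -> pd.Series:
    """bp gap to the nearest TE on the same chromosome (0 if overlapping, NaN if none)."""
    dist = np.full(len(regions), np.nan)
    te_by_chrom = {c: g.sort_values("start") for c, g in tes.groupby("chrom", sort=False)}
    regions = regions.reset_index(drop=True)
    for chrom, grp in regions.groupby("chrom", sort=False):
        g = te_by_chrom.get(chrom)
        if g is None or len(g) == 0:
            continue
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        max_end_before = np.maximum.accumulate(ends)
        for i, r in zip(grp.index, grp.itertuples(index=False)):
            # TEs with start < r.end sit at indices < after
            after = np.searchsorted(starts, r.end, side="left")
            if after >= 1 and max_end_before[after - 1] > r.start:
                dist[i] = 0.0  # overlap
                continue
            d_before = (r.start - max_end_before[after - 1]) if after >= 1 else np.inf
            d_after = (starts[after] - r.end) if after < len(starts) else np.inf
            dist[i] = min(d_before, d_after)
    return pd.Series(dist, index=regions.index, name="te_distance")


def _tertiles(values: pd.Series, labels=("low", "medium", "high")) -> pd.Series:
    """Split into three near-equal classes by rank, ties broken by index label."""
    order = sorted(values.index, key=lambda k: (values[k], str(k)))
    n = len(order)
    cuts = [n // 3, n - n // 3] if n % 3 != 2 else [(n + 1) // 3, n - (n + 1) // 3]
    out = pd.Series(index=values.index, dtype="object")
    out[order[:cuts[0]]] = labels[0]
    out[order[cuts[0]:cuts[1]]] = labels[1]
    out[order[cuts[1]:]] = labels[2]
    return out


def classify_promoters_by_methylation(mp_table: pd.DataFrame) -> pd.Series:
    """Four promoter classes for TE-distance analysis.

    ``none`` = covered promoter that is not an MP; MPs split into
    low/medium/high tertiles of mean mCG level averaged over stages.
    Indexed like ``mp_table``.
    """
    cls = pd.Series("none", index=mp_table.index, dtype="object")
    mp = mp_table[mp_table["qualifies"]]
    if len(mp):
        cls[mp.index] = _tertiles(mp["mean_level"])
    return cls


def te_distance_by_promoter_class(mp_table: pd.DataFrame, tes: pd.DataFrame) -> pd.DataFrame:
    """Distance to nearest TE per promoter, with its methylation class."""
    mp_table = mp_table.reset_index(drop=True)
    dist = nearest_te_distance(mp_table, tes)
    cls = classify_promoters_by_methylation(mp_table)
    return pd.DataFrame({
        "gene_id": mp_table["gene_id"],
        "meth_class": cls,
        "te_distance": dist,
    })


def methylation_by_expression_class(meth_levels: pd.Series,
                                    mean_tpm: pd.Series) -> pd.DataFrame:
    """Split genes into expression tertiles and tabulate their mCG levels.

    ``meth_levels``: mean promoter (or gene-body) mCG level per gene for
    genes harbouring an MP/MGB.  ``mean_tpm``: TPM averaged over stages.
    Tertiles are computed on log10(mean TPM + 1) with deterministic
    tie-breaking by gene id.
    """
    genes = meth_levels.index.intersection(mean_tpm.index)
    if len(genes) < 3:
        raise ValueError("need at least 3 genes for expression tertiles")
    log_tpm = np.log10(mean_tpm.loc[genes] + 1.0)
    cls = _tertiles(log_tpm)
    return pd.DataFrame({
        "gene_id": genes,
        "expr_class": cls.loc[genes].to_numpy(),
        "meth_level": meth_levels.loc[genes].to_numpy(),
        "mean_tpm": mean_tpm.loc[genes].to_numpy(),
    }).set_index("gene_id")
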
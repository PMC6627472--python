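"""Two-species, three-stage synthetic methylomes, annotations and expression.

The generator emulates the statistical structure the downstream analyses
assume, with full ground truth, so that every pipeline stage has a
no-download test bed:

* a fungal-style **bimodal CG methylome**: every CpG dyad draws a latent
  methylation level from a two-component Beta mixture whose low mode
  (~2%, effectively unmethylated) dominates genic space and whose high
  mode (~90%) dominates TEs and intergenic space;
* **TE-to-promoter spreading**: the probability that a promoter CpG is in
  the high component decays exponentially with the gene's distance to
  its nearest TE, and promoter methylation represses the gene's
  expression — the construction behind the TE-distance and
  expression-tertile analyses;
* observed counts: per-site read depth ~ 1 + Poisson(depth-1), methylated
  reads ~ Binomial(depth, level*(1-eps) + (1-level)*eps) with eps the
  bisulfite non-conversion rate (0.3%);
* **planted DMRs** per developmental transition: hyper regions step from a
  low baseline (~0.10) up by +delta in the later stage, hypo regions from
  the high mode down by -delta; shifts persist into later stages so each
  transition's truth is self-contained;
* **expression**: three-replicate negative-binomial counts per stage for
  both species, sharing 1:1 orthologs, with divergence classes (DE0,
  DE1 in one species, DE2 identical/opposite) planted per phase as
  persistent log2 shifts.

Identical configs (including the seed) produce byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import feature_annotation
from .io_formats import TE_CLASSES, GenomeAnnotation, make_sites_frame

logger = logging.getLogger(__name__)

STAGES = ("MY", "PR", "FB")
DIVERGENCE_CLASSES = ("DE0", "DE1-Pt", "DE1-Pe", "DE2-identical", "DE2-opposite")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; the seed fully determines every output."""

    seed: int = 0
    # genome geometry
    n_chroms: int = 2
    chrom_length_bp: int = 400_000
    n_genes: int = 150
    n_tes: int = 100
    gene_length_range: tuple[int, int] = (1500, 3500)
    te_length_range: tuple[int, int] = (500, 2000)
    te_class_proportions: tuple[float, ...] = (0.38, 0.24, 0.14, 0.12, 0.12)
    # methylome
    cpg_spacing_bp: float = 50.0
    depth_mean: float = 30.0
    nonconversion_rate: float = 0.003
    low_mode: float = 0.02
    high_mode: float = 0.90
    beta_concentration: float = 100.0
    low_weight_genic: float = 0.97
    low_weight_te: float = 0.30
    promoter_spread_max: float = 0.85
    te_spread_tau_bp: float = 400.0
    gene_body_spread_max: float = 0.45
    te_weight_alpha: float = 2.0   # per-TE high-component weight ~ Beta(a, b):
    te_weight_beta: float = 0.9    # right-skewed -> most TEs heavily methylated,
                                   # a minority incompletely or barely methylated
    # planted DMRs (per transition)
    n_planted_dmrs: int = 8
    dmr_delta: float = 0.30
    dmr_length_bp: int = 1000
    dmr_hyper_baseline: float = 0.10
    # expression
    n_replicates: int = 3
    nb_dispersion: float = 0.1
    expr_meanlog: float = np.log(150.0)
    expr_sdlog: float = 0.8
    n_de1_pt: int = 30
    n_de1_pe: int = 20
    n_de2_identical: int = 10
    n_de2_opposite: int = 5
    planted_log2_effect: float = 3.0
    meth_repression_log2: float = 8.0
    te_expr_meanlog: float = np.log(1.5)
    te_expr_sdlog: float = 1.0
    te_repression_log2: float = 6.0
    library_size_sdlog: float = 0.15
    # ortholog pair table
    ortholog_frac_alpha: float = 16.0
    ortholog_frac_beta: float = 4.0
    ortholog_length_range: tuple[int, int] = (250, 1500)

    def __post_init__(self) -> None:
        if abs(sum(self.te_class_proportions) - 1.0) > 1e-9 or len(self.te_class_proportions) != 5:
            raise ValueError("te_class_proportions must be a 5-vector summing to 1")
        for w in (self.low_weight_genic, self.low_weight_te, self.nonconversion_rate,
                  self.low_mode, self.high_mode):
            if not 0 <= w <= 1:
                raise ValueError("proportions must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        planted = (self.n_de1_pt + self.n_de1_pe + self.n_de2_identical + self.n_de2_opposite)
        if planted > self.n_genes:
            raise ValueError("planted divergence class counts exceed n_genes")


@dataclass
class MethylomeSim:
    """Per-species methylome simulation output."""

    stage_sites: dict[str, pd.DataFrame]        # observed per-cytosine tables
    truth_sites: pd.DataFrame                   # dyad-level latent truth
    truth_dmrs: pd.DataFrame                    # planted DMR record
    promoter_latent: pd.Series                  # gene_id -> mean latent promoter level
    te_latent: pd.Series                        # te_id -> mean latent TE level


@dataclass
class ExpressionSim:
    gene_counts: dict[str, pd.DataFrame]        # species -> counts (MultiIndex stage, rep)
    gene_lengths: dict[str, pd.Series]
    te_counts: dict[str, pd.DataFrame]
    te_lengths: dict[str, pd.Series]
    truth_classes: pd.DataFrame                 # pair x phase -> planted class
    ortholog_pairs: pd.DataFrame
    go_map: pd.DataFrame


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    annotations: dict[str, GenomeAnnotation]
    methylomes: dict[str, MethylomeSim]
    expression: ExpressionSim


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _place_non_overlapping(rng: np.random.Generator, length: int,
                           feature_lengths: np.ndarray) -> np.ndarray:
    """Start coordinates for non-overlapping intervals in [0, length)."""
    total = int(feature_lengths.sum())
    free = length - total
    if free < 0:
        raise ValueError(
            f"cannot place {len(feature_lengths)} features totalling {total} bp "
            f"on a {length} bp chromosome (density too high)")
    n = len(feature_lengths)
    gaps = rng.multinomial(free, np.full(n + 1, 1.0 / (n + 1)))
    starts = np.cumsum(gaps[:-1]) + np.concatenate([[0], np.cumsum(feature_lengths[:-1])]) \
        if n else np.array([], dtype="int64")
    return starts.astype("int64")


def simulate_annotation(config: SimulationConfig, species: str = "Pt",
                        rng: np.random.Generator | None = None) -> GenomeAnnotation:
    """Non-overlapping genes (1-5 exons each) and class-labelled TEs."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    chrom_lengths = {f"chr{i + 1}": config.chrom_length_bp for i in range(config.n_chroms)}
    # round-robin features over chromosomes, shuffled placement order
    kinds = np.array(["gene"] * config.n_genes + ["TE"] * config.n_tes)
    rng.shuffle(kinds)
    chrom_of = np.arange(len(kinds)) % config.n_chroms
    gene_rows, exon_rows, te_rows = [], [], []
    g_idx, t_idx = 0, 0
    for ci, chrom in enumerate(chrom_lengths):
        sel = kinds[chrom_of == ci]
        lengths = np.where(
            sel == "gene",
            rng.integers(*config.gene_length_range, size=len(sel)),
            rng.integers(*config.te_length_range, size=len(sel)),
        )
        starts = _place_non_overlapping(rng, config.chrom_length_bp, lengths)
        for kind, start, L in zip(sel, starts, lengths):
            start, L = int(start), int(L)
            if kind == "gene":
                g_idx += 1
                gid = f"{species}_g{g_idx:04d}"
                strand = "+" if rng.random() < 0.5 else "-"
                gene_rows.append((chrom, start, start + L, strand, gid))
                exon_rows.extend(_make_exons(rng, chrom, start, start + L, strand, gid))
            else:
                t_idx += 1
                klass = TE_CLASSES[rng.choice(5, p=config.te_class_proportions)]
                te_rows.append((chrom, start, start + L, ".", f"{species}_te{t_idx:04d}", klass))
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "strand", "id"])
    exons = pd.DataFrame(exon_rows, columns=["chrom", "start", "end", "strand", "gene_id"])
    tes = pd.DataFrame(te_rows, columns=["chrom", "start", "end", "strand", "id", "te_class"])
    return GenomeAnnotation(chrom_lengths, genes, exons, tes)


def _make_exons(rng, chrom, start, end, strand, gene_id,
                min_exon=50, min_intron=30) -> list[tuple]:
    L = end - start
    n_e = int(rng.integers(1, 6))
    while n_e > 1 and L < n_e * min_exon + (n_e - 1) * min_intron:
        n_e -= 1
    n_seg = 2 * n_e - 1
    mins = np.array([min_exon if i % 2 == 0 else min_intron for i in range(n_seg)])
    extra = rng.multinomial(L - mins.sum(), np.full(n_seg, 1.0 / n_seg))
    sizes = mins + extra
    bounds = start + np.concatenate([[0], np.cumsum(sizes)])
    return [(chrom, int(bounds[i]), int(bounds[i + 1]), strand, gene_id)
            for i in range(0, n_seg, 2)]


def jitter_annotation(annotation: GenomeAnnotation, config: SimulationConfig,
                      species: str = "Pe",
                      rng: np.random.Generator | None = None,
                      max_jitter_bp: int = 200) -> GenomeAnnotation:
    """Second-species annotation: same gene order/ids (renamed), TEs jittered.

    TE starts move by up to ``max_jitter_bp`` within the free gap to
    their neighbours, mirroring two genomes with near-identical TE
    content.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 102]))
    old_prefix = annotation.genes["id"].iloc[0].split("_")[0] if len(annotation.genes) else "Pt"

    def rename(s: pd.Series) -> pd.Series:
        return s.str.replace(f"^{old_prefix}_", f"{species}_", regex=True)

    genes = annotation.genes.copy()
    genes["id"] = rename(genes["id"])
    exons = annotation.exons.copy()
    if len(exons):
        exons["gene_id"] = rename(exons["gene_id"])
    tes = annotation.tes.copy()
    tes["id"] = rename(tes["id"])
    # jitter TEs within the gap to any neighbouring feature
    occupied = pd.concat([
        genes[["chrom", "start", "end"]],
        tes[["chrom", "start", "end"]],
    ]).sort_values(["chrom", "start"]).reset_index(drop=True)
    new_starts = tes["start"].to_numpy().copy()
    new_ends = tes["end"].to_numpy().copy()
    for i, te in enumerate(tes.itertuples(index=False)):
        same = occupied[(occupied["chrom"] == te.chrom)]
        prev_end = same.loc[same["end"] <= te.start, "end"].max()
        next_start = same.loc[same["start"] >= te.end, "start"].min()
        lo = -min(max_jitter_bp, te.start - (0 if pd.isna(prev_end) else int(prev_end)))
        hi = min(max_jitter_bp, ((annotation.chrom_lengths[te.chrom]
                                  if pd.isna(next_start) else int(next_start)) - te.end))
        if hi > lo:
            shift = int(rng.integers(lo, hi + 1))
            new_starts[i] += shift
            new_ends[i] += shift
    tes["start"], tes["end"] = new_starts, new_ends
    return GenomeAnnotation(dict(annotation.chrom_lengths), genes, exons, tes)


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

def _beta_around(rng, mode: float, conc: float, size: int) -> np.ndarray:
    a = max(mode * conc, 1e-3)
    b = max((1 - mode) * conc, 1e-3)
    return rng.beta(a, b, size=size)


def simulate_methylomes(annotation: GenomeAnnotation, config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> MethylomeSim:
    """Latent dyad levels, planted DMRs, and observed counts for all stages."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 103]))
    ann = feature_annotation.derive_features(annotation)

    # --- dyad positions (plus-strand anchor of each CpG)
    chrom_arr, pos_arr, kind_arr = [], [], []
    for chrom, L in ann.chrom_lengths.items():
        gaps = rng.geometric(1.0 / config.cpg_spacing_bp, size=int(3 * L / config.cpg_spacing_bp))
        pos = np.cumsum(gaps + 1)  # +1 -> dyads never butt against each other
        pos = pos[pos < L - 1]
        paint = feature_annotation.paint_categories(ann, chrom)
        chrom_arr.append(np.full(len(pos), chrom, dtype=object))
        pos_arr.append(pos)
        kind_arr.append(paint[pos])
    chroms = np.concatenate(chrom_arr)
    positions = np.concatenate(pos_arr).astype("int64")
    kinds = np.concatenate(kind_arr)
    n = len(positions)

    # --- per-dyad high-component probability
    p_high = np.full(n, 1.0 - config.low_weight_genic)
    p_high[kinds == feature_annotation.CATEGORY_CODES["intergenic"]] = 1.0 - config.low_weight_te
    # per-TE high weight: incomplete TE methylation — most elements heavily
    # methylated, a minority barely, so TE mean levels vary between elements
    tes = ann.tes.reset_index(drop=True)
    te_weights = rng.beta(config.te_weight_alpha, config.te_weight_beta, size=len(tes))
    _set_region_weights(p_high, chroms, positions,
                        kinds == feature_annotation.CATEGORY_CODES["TE"], tes, te_weights)
    # promoter / gene-body methylation spreads from the nearest TE
    prom = ann.derived["promoter"].reset_index(drop=True)
    prom_dist = feature_annotation.nearest_te_distance(prom, tes).fillna(np.inf).to_numpy()
    _set_region_weights(
        p_high, chroms, positions,
        kinds == feature_annotation.CATEGORY_CODES["promoter"], prom,
        config.promoter_spread_max * np.exp(-prom_dist / config.te_spread_tau_bp))
    bodies = ann.genes.rename(columns={"id": "gene_id"}).reset_index(drop=True)
    body_dist = feature_annotation.nearest_te_distance(bodies, tes).fillna(np.inf).to_numpy()
    in_body = np.isin(kinds, [feature_annotation.CATEGORY_CODES["exon"],
                              feature_annotation.CATEGORY_CODES["intron"]])
    _set_region_weights(
        p_high, chroms, positions, in_body, bodies,
        config.gene_body_spread_max * np.exp(-body_dist / config.te_spread_tau_bp))

    # --- base latent level
    in_high = rng.random(n) < p_high
    base = np.where(
        in_high,
        _beta_around(rng, config.high_mode, config.beta_concentration, n),
        _beta_around(rng, config.low_mode, config.beta_concentration, n),
    )

    # --- planted DMR intervals (persistent shifts from the later stage on)
    latent = {s: base.copy() for s in STAGES}
    truth_dmrs = _plant_dmrs(rng, ann, config, chroms, positions, kinds, latent)
    clamped = 0
    for s in STAGES:
        lo_hi = np.clip(latent[s], 0.0, 1.0)
        clamped += int((lo_hi != latent[s]).sum())
        latent[s] = lo_hi
    if clamped:
        logger.warning("simulate_methylomes: clamped %d latent levels into [0, 1]", clamped)

    truth_sites = pd.DataFrame({
        "chrom": chroms, "pos": positions,
        "kind": [feature_annotation.CODE_TO_CATEGORY[k] for k in kinds],
        "component": np.where(in_high, "high", "low"),
        **{f"latent_{s}": latent[s] for s in STAGES},
    })

    # --- observed counts, both strands of each dyad
    eps = config.nonconversion_rate
    stage_sites = {}
    for s in STAGES:
        lvl2 = np.repeat(latent[s], 2)
        p_obs = lvl2 * (1 - eps) + (1 - lvl2) * eps
        depth = 1 + rng.poisson(max(config.depth_mean - 1, 0.0), size=2 * n)
        meth = rng.binomial(depth, p_obs)
        dyad_chrom = np.repeat(chroms, 2)
        dyad_pos = np.repeat(positions, 2) + np.tile([0, 1], n)
        strand = np.tile(["+", "-"], n)
        stage_sites[s] = make_sites_frame(dyad_chrom, dyad_pos, strand, meth, depth)
        stage_sites[s].attrs["stage"] = s

    # --- mean latent levels per promoter / TE (for the expression coupling)
    truth_mean = truth_sites[[f"latent_{s}" for s in STAGES]].mean(axis=1).to_numpy()
    promoter_latent = _mean_latent_per_region(prom, "gene_id", chroms, positions, truth_mean)
    te_latent = _mean_latent_per_region(ann.tes.reset_index(drop=True), "id",
                                        chroms, positions, truth_mean)
    return MethylomeSim(stage_sites, truth_sites, truth_dmrs, promoter_latent, te_latent)


def _set_region_weights(p_high: np.ndarray, chroms: np.ndarray, positions: np.ndarray,
                        site_mask: np.ndarray, regions: pd.DataFrame,
                        weights: np.ndarray) -> None:
    """Assign per-region high-component weights to the sites inside each region."""
    if len(regions) == 0:
        return
    n = len(positions)
    for chrom, grp in regions.groupby("chrom", sort=False):
        idx = np.flatnonzero((chroms == chrom) & site_mask)
        if len(idx) == 0:
            continue
        starts = grp["start"].to_numpy()
        order = np.argsort(starts)
        starts_sorted = starts[order]
        rows = grp.index.to_numpy()[order]
        which = np.searchsorted(starts_sorted, positions[idx], side="right") - 1
        ok = which >= 0
        hit_rows = rows[which[ok]]
        inside = positions[idx[ok]] < regions.loc[hit_rows, "end"].to_numpy()
        p_high[idx[ok][inside]] = np.asarray(weights)[hit_rows[inside]]


def _mean_latent_per_region(regions: pd.DataFrame, id_col: str, chroms, positions,
                            values) -> pd.Series:
    out = {}
    pos_by_chrom = {}
    for chrom in regions["chrom"].unique():
        mask = chroms == chrom
        idx = np.flatnonzero(mask)
        order = np.argsort(positions[idx])
        pos_by_chrom[chrom] = (positions[idx][order], idx[order])
    for r in regions.itertuples(index=False):
        rid = getattr(r, id_col)
        pos_sorted, idx_sorted = pos_by_chrom.get(r.chrom, (np.array([]), np.array([])))
        lo = np.searchsorted(pos_sorted, r.start, side="left")
        hi = np.searchsorted(pos_sorted, r.end, side="left")
        out[rid] = float(values[idx_sorted[lo:hi]].mean()) if hi > lo else 0.0
    return pd.Series(out, name="mean_latent")


def _plant_dmrs(rng, ann, config, chroms, positions, kinds, latent) -> pd.DataFrame:
    """Choose intergenic/TE intervals per transition and shift latent levels."""
    rows = []
    taken: list[tuple[str, int, int]] = []
    transitions = [(STAGES[i], STAGES[i + 1]) for i in range(len(STAGES) - 1)]
    te_ig = np.isin(kinds, [feature_annotation.CATEGORY_CODES["TE"],
                            feature_annotation.CATEGORY_CODES["intergenic"]])
    chrom_names = list(ann.chrom_lengths)
    for t_idx, (early, late) in enumerate(transitions):
        later_stages = STAGES[STAGES.index(late):]
        for d in range(config.n_planted_dmrs):
            direction = "hyper" if d % 2 == 0 else "hypo"
            placed = False
            for _attempt in range(300):
                chrom = chrom_names[int(rng.integers(len(chrom_names)))]
                L = ann.chrom_lengths[chrom]
                start = int(rng.integers(0, max(1, L - config.dmr_length_bp)))
                end = start + config.dmr_length_bp
                if any(c == chrom and s < end and start < e for c, s, e in taken):
                    continue
                sel = (chroms == chrom) & (positions >= start) & (positions < end)
                if sel.sum() < 15 or te_ig[sel].mean() < 0.8:
                    continue
                baseline = (config.dmr_hyper_baseline if direction == "hyper"
                            else config.high_mode)
                shift = config.dmr_delta if direction == "hyper" else -config.dmr_delta
                base_lvls = _beta_around(rng, baseline, config.beta_concentration, int(sel.sum()))
                for s in STAGES:
                    latent[s][sel] = base_lvls
                for s in later_stages:
                    latent[s][sel] = base_lvls + shift
                taken.append((chrom, start, end))
                rows.append({"transition": f"{early}->{late}", "chrom": chrom,
                             "start": start, "end": end, "status": direction,
                             "delta": shift, "n_dyads": int(sel.sum())})
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place planted DMR {d} for transition {early}->{late}; "
                    "genome too dense or too small")
    return pd.DataFrame(rows, columns=["transition", "chrom", "start", "end",
                                       "status", "delta", "n_dyads"])


def simulate_null_sites(n_sites: int, depth_mean: float = 20.0,
                        nonconversion_rate: float = 0.003,
                        rng: np.random.Generator | None = None,
                        spacing_bp: int = 50) -> pd.DataFrame:
    """Truly unmethylated sites: only non-conversion noise survives bisulfite.

    The null bed for caller calibration — every methylated read is a
    non-conversion artefact, so any mCG call is a false call.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    depth = 1 + rng.poisson(max(depth_mean - 1, 0.0), size=n_sites)
    meth = rng.binomial(depth, nonconversion_rate)
    return make_sites_frame(
        np.full(n_sites, "chr1", dtype=object),
        np.arange(n_sites, dtype="int64") * spacing_bp,
        "+", meth, depth)


def simulate_methylome(annotation: GenomeAnnotation, config: SimulationConfig,
                       stage: str) -> pd.DataFrame:
    """Observed cytosine report for one stage (stages are mutually consistent).

    Thin wrapper over :func:`simulate_methylomes`; the full simulation is
    derived deterministically from ``config.seed``, so calling this per
    stage yields the same tables as one joint call.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    return simulate_methylomes(annotation, config).stage_sites[stage]


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _nb_draw(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with var = mean + dispersion * mean^2 (Poisson at mean 0)."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-8)
    n_param = 1.0 / dispersion
    p_param = n_param / (n_param + mean)
    return rng.negative_binomial(n_param, p_param)


def simulate_expression(config: SimulationConfig,
                        annotations: Mapping[str, GenomeAnnotation] | None = None,
                        promoter_latent: Mapping[str, pd.Series] | None = None,
                        te_latent: Mapping[str, pd.Series] | None = None,
                        rng: np.random.Generator | None = None) -> ExpressionSim:
    """Ortholog-paired NB counts with planted divergence classes.

    When per-gene promoter (or per-TE) latent methylation levels are
    supplied, expression means are repressed by
    ``2**(-meth_repression_log2 * level)``, wiring the methylation-
    expression coupling the directional analyses look for.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104]))
    species = ("Pt", "Pe")
    if annotations is not None:
        gene_ids = {sp: annotations[sp].genes["id"].tolist() for sp in species}
        gene_lengths = {sp: pd.Series(
            (annotations[sp].genes["end"] - annotations[sp].genes["start"]).to_numpy(),
            index=annotations[sp].genes["id"]) for sp in species}
        te_ids = {sp: annotations[sp].tes["id"].tolist() for sp in species}
        te_lengths = {sp: pd.Series(
            (annotations[sp].tes["end"] - annotations[sp].tes["start"]).to_numpy(),
            index=annotations[sp].tes["id"]) for sp in species}
    else:
        gene_ids = {sp: [f"{sp}_g{i + 1:04d}" for i in range(config.n_genes)] for sp in species}
        gene_lengths = {sp: pd.Series(
            rng.integers(*config.gene_length_range, size=config.n_genes),
            index=gene_ids[sp]) for sp in species}
        te_ids = {sp: [f"{sp}_te{i + 1:04d}" for i in range(config.n_tes)] for sp in species}
        te_lengths = {sp: pd.Series(
            rng.integers(*config.te_length_range, size=config.n_tes),
            index=te_ids[sp]) for sp in species}
    n_genes = len(gene_ids["Pt"])
    if len(gene_ids["Pe"]) != n_genes:
        raise ValueError("species gene sets must be 1:1 for the ortholog table")

    # shared ancestral means; species add mild lognormal divergence
    base = rng.lognormal(config.expr_meanlog, config.expr_sdlog, size=n_genes)
    species_factor = {sp: rng.lognormal(0.0, 0.2, size=n_genes) for sp in species}

    # planted divergence classes, drawn per phase over disjoint gene subsets
    phases = {"phase1": ("MY", "PR"), "phase2": ("PR", "FB")}
    class_counts = [("DE1-Pt", config.n_de1_pt), ("DE1-Pe", config.n_de1_pe),
                    ("DE2-identical", config.n_de2_identical),
                    ("DE2-opposite", config.n_de2_opposite)]
    truth_rows = []
    # per species: stage multiplier matrix (genes x stages), shifts persist
    log2_mult = {sp: np.zeros((n_genes, len(STAGES))) for sp in species}
    for phase, (_early, late) in phases.items():
        perm = rng.permutation(n_genes)
        cursor = 0
        assigned = pd.Series("DE0", index=range(n_genes))
        for klass, count in class_counts:
            chosen = perm[cursor:cursor + count]
            cursor += count
            assigned.iloc[chosen] = klass
            signs = rng.choice([-1.0, 1.0], size=count)
            late_idx = STAGES.index(late)
            for j, g in enumerate(chosen):
                eff = signs[j] * config.planted_log2_effect
                if klass == "DE1-Pt":
                    log2_mult["Pt"][g, late_idx:] += eff
                elif klass == "DE1-Pe":
                    log2_mult["Pe"][g, late_idx:] += eff
                elif klass == "DE2-identical":
                    log2_mult["Pt"][g, late_idx:] += eff
                    log2_mult["Pe"][g, late_idx:] += eff
                elif klass == "DE2-opposite":
                    log2_mult["Pt"][g, late_idx:] += eff
                    log2_mult["Pe"][g, late_idx:] -= eff
        for g in range(n_genes):
            truth_rows.append({"gene_a": gene_ids["Pt"][g], "gene_b": gene_ids["Pe"][g],
                               "phase": phase, "true_class": assigned.iloc[g]})
    truth_classes = pd.DataFrame(truth_rows)

    # counts
    gene_counts, te_counts = {}, {}
    cols = pd.MultiIndex.from_tuples(
        [(s, str(r + 1)) for s in STAGES for r in range(config.n_replicates)],
        names=["stage", "replicate"])
    for sp in species:
        repress = np.ones(n_genes)
        if promoter_latent is not None and sp in promoter_latent:
            lvl = promoter_latent[sp].reindex(gene_ids[sp]).fillna(0.0).to_numpy()
            repress = 2.0 ** (-config.meth_repression_log2 * lvl)
        mu0 = base * species_factor[sp] * repress
        mat = np.empty((n_genes, len(cols)), dtype="int64")
        for si, s in enumerate(STAGES):
            mu_s = mu0 * 2.0 ** log2_mult[sp][:, si]
            for r in range(config.n_replicates):
                lib = rng.lognormal(0.0, config.library_size_sdlog)
                mat[:, si * config.n_replicates + r] = _nb_draw(rng, mu_s * lib,
                                                                config.nb_dispersion)
        gene_counts[sp] = pd.DataFrame(mat, index=gene_ids[sp], columns=cols)

        n_tes = len(te_ids[sp])
        te_base = rng.lognormal(config.te_expr_meanlog, config.te_expr_sdlog, size=n_tes)
        if te_latent is not None and sp in te_latent:
            lvl = te_latent[sp].reindex(te_ids[sp]).fillna(0.0).to_numpy()
            te_base = te_base * 2.0 ** (-config.te_repression_log2 * lvl)
        te_mat = np.empty((n_tes, len(cols)), dtype="int64")
        for si in range(len(STAGES)):
            stage_wobble = rng.lognormal(0.0, 0.1, size=n_tes)
            for r in range(config.n_replicates):
                lib = rng.lognormal(0.0, config.library_size_sdlog)
                te_mat[:, si * config.n_replicates + r] = _nb_draw(
                    rng, te_base * stage_wobble * lib, config.nb_dispersion)
        te_counts[sp] = pd.DataFrame(te_mat, index=te_ids[sp], columns=cols)

    # ortholog pair table with alignment-coverage columns
    pairs = pd.DataFrame({
        "gene_a": gene_ids["Pt"],
        "gene_b": gene_ids["Pe"],
        "consensus_fraction": rng.beta(config.ortholog_frac_alpha,
                                       config.ortholog_frac_beta, size=n_genes),
        "consensus_length_bp": rng.integers(*config.ortholog_length_range, size=n_genes),
    })

    go_map = _simulate_go_map(rng, gene_ids["Pt"], truth_classes)
    return ExpressionSim(gene_counts, gene_lengths, te_counts, te_lengths,
                         truth_classes, pairs, go_map)


def _simulate_go_map(rng, genes: list[str], truth_classes: pd.DataFrame,
                     n_terms: int = 25) -> pd.DataFrame:
    """Random gene->term map; one term is concentrated in diverged genes."""
    terms = [f"GO:{7000000 + i}" for i in range(n_terms)]
    rows = []
    for g in genes:
        for t in rng.choice(n_terms, size=int(rng.integers(1, 4)), replace=False):
            rows.append((g, terms[t]))
    diverged = truth_classes.loc[
        (truth_classes["phase"] == "phase1")
        & (truth_classes["true_class"] != "DE0"), "gene_a"]
    rows.extend((g, "GO:7999999") for g in diverged)
    return pd.DataFrame(rows, columns=["gene", "term"]).drop_duplicates(ignore_index=True)


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Annotations, methylomes and expression for both species, with truth."""
    ss = np.random.SeedSequence([config.seed, 100])
    keys = ["ann", "jitter", "meth_pt", "meth_pe", "expr"]
    rngs = dict(zip(keys, (np.random.default_rng(c) for c in ss.spawn(len(keys)))))
    ann_pt = simulate_annotation(config, "Pt", rngs["ann"])
    ann_pe = jitter_annotation(ann_pt, config, "Pe", rngs["jitter"])
    meth = {
        "Pt": simulate_methylomes(ann_pt, config, rngs["meth_pt"]),
        "Pe": simulate_methylomes(ann_pe, config, rngs["meth_pe"]),
    }
    expr = simulate_expression(
        config,
        annotations={"Pt": ann_pt, "Pe": ann_pe},
        promoter_latent={sp: meth[sp].promoter_latent for sp in meth},
        te_latent={sp: meth[sp].te_latent for sp in meth},
        rng=rngs["expr"],
    )
    return SimulatedDataset(config, {"Pt": ann_pt, "Pe": ann_pe}, meth, expr)


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A fast, reduced-scale configuration for examples and tests."""
    base = SimulationConfig(
        seed=seed, n_chroms=1, chrom_length_bp=250_000, n_genes=40, n_tes=30,
        n_planted_dmrs=4, n_de1_pt=10, n_de1_pe=8, n_de2_identical=4, n_de2_opposite=2,
    )
    return replace(base, **overrides)
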
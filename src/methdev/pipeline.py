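"""End-to-end orchestration of the comparative methylome/transcriptome workflow.

One :class:`PipelineConfig` (thresholds + either a simulation config or
paths to real inputs) drives the full chain:

    simulate-or-ingest -> mCG calling per species x stage
    -> DMRs per transition -> feature geography, MP/MGB and their
    differential tests -> TPM / DE / ortholog divergence classes
    -> fold-change and methylation-expression correlations
    -> GO enrichment of diverged orthologs -> report + manifest

Every table is written as plain TSV/BED under the run directory; the
manifest records the package version, every threshold, the seed and the
SHA-256 of every output, so a run is reproducible bit-for-bit from the
manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, dmr_detection, expression_divergence as ed, feature_annotation as fa
from . import enrichment_stats as es
from . import io_formats as io
from . import mcg_calling as mc
from . import synthetic_data as sd

logger = logging.getLogger(__name__)

STAGES = sd.STAGES
TRANSITIONS = [(STAGES[i], STAGES[i + 1]) for i in range(len(STAGES) - 1)]
PHASES = {"phase1": TRANSITIONS[0], "phase2": TRANSITIONS[1]}


@dataclass(frozen=True)
class Thresholds:
    """All decision thresholds of the workflow (defaults = study values)."""

    p0: float = 0.003
    min_reads: int = 5
    mcg_q: float = 0.01
    mcg_level: float = 0.05
    window_size: int = 1000
    step: int = 200
    min_mcg: int = 10
    dmr_q: float = 0.01
    dmr_delta: float = 0.15
    mp_mgb_density: float = 10.0
    tpm_expressed: float = 1.0
    de_q: float = 0.01
    de_lfc: float = 1.0
    ortholog_min_fraction: float = 0.70
    ortholog_min_length: int = 300
    go_q: float = 0.05
    go_min_genes: int = 5


@dataclass
class PipelineConfig:
    outdir: str | Path = "methdev_run"
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    simulate: sd.SimulationConfig | None = None   # None -> ingest mode
    inputs: dict | None = None                    # paths for ingest mode

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {"outdir", "seed", "thresholds", "simulate", "inputs"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        thr = raw.get("thresholds") or {}
        bad = set(thr) - {f.name for f in dataclasses.fields(Thresholds)}
        if bad:
            raise ValueError(f"unknown threshold keys: {sorted(bad)}")
        sim = raw.get("simulate")
        sim_cfg = None
        if sim is not None:
            bad = set(sim) - {f.name for f in dataclasses.fields(sd.SimulationConfig)}
            if bad:
                raise ValueError(f"unknown simulate keys: {sorted(bad)}")
            sim = dict(sim)
            sim.setdefault("seed", raw.get("seed", 0))
            sim_cfg = sd.SimulationConfig(**sim)
        return cls(outdir=raw.get("outdir", "methdev_run"), seed=raw.get("seed", 0),
                   thresholds=Thresholds(**thr), simulate=sim_cfg,
                   inputs=raw.get("inputs"))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the workflow; returns the run directory (contains manifest.json)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    report: dict = {"seed": config.seed}

    # ------------------------------------------------------------------ inputs
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        dataset = sd.simulate_dataset(sim)
        annotations = dataset.annotations
        methylomes = {sp: m.stage_sites for sp, m in dataset.methylomes.items()}
        truth_dmrs = {sp: m.truth_dmrs for sp, m in dataset.methylomes.items()}
        gene_counts = dataset.expression.gene_counts
        gene_lengths = dataset.expression.gene_lengths
        te_counts = dataset.expression.te_counts
        te_lengths = dataset.expression.te_lengths
        pairs = dataset.expression.ortholog_pairs
        go_map = dataset.expression.go_map
        for sp, m in dataset.methylomes.items():
            m.truth_dmrs.to_csv(out / f"truth_dmrs_{sp}.tsv", sep="\t", index=False)
        dataset.expression.truth_classes.to_csv(out / "truth_classes.tsv", sep="\t", index=False)
    elif config.inputs:
        annotations, methylomes, truth_dmrs = {}, {}, {}
        gene_counts, gene_lengths, te_counts, te_lengths = {}, {}, {}, {}
        for sp, spec in config.inputs["species"].items():
            chrom_lengths = io.read_chrom_sizes(spec["chrom_sizes"])
            annotations[sp] = io.read_annotation(spec["gff"], spec.get("te_bed"),
                                                 chrom_lengths)
            methylomes[sp] = {stage: io.read_cytosine_report(path, stage)
                              for stage, path in spec["cytosine_reports"].items()}
            gene_counts[sp], gene_lengths[sp] = io.read_count_matrix(spec["gene_counts"])
            if spec.get("te_counts"):
                te_counts[sp], te_lengths[sp] = io.read_count_matrix(spec["te_counts"])
        pairs = io.read_ortholog_pairs(config.inputs["orthologs"])
        go_map = (io.read_go_map(config.inputs["go_map"])
                  if config.inputs.get("go_map") else pd.DataFrame(columns=["gene", "term"]))
    else:
        raise ValueError("config needs either 'simulate' or 'inputs'")
    species = list(annotations)

    # ------------------------------------------------------ mCG calling
    mcg_params = mc.McgCallParams(thr.p0, thr.min_reads, thr.mcg_q, thr.mcg_level)
    called: dict[str, dict[str, pd.DataFrame]] = {}
    for sp in species:
        called[sp] = {}
        annotations[sp] = fa.derive_features(annotations[sp])
        for stage, sites in methylomes[sp].items():
            c = mc.call_mcgs(mc.depth_filter(sites, thr.min_reads), mcg_params)
            called[sp][stage] = c
            io.write_sites_tsv(c, out / f"mcg_{sp}_{stage}.tsv")
            cats = fa.assign_sites_to_features(c, annotations[sp])
            report[f"mcg_summary_{sp}_{stage}"] = mc.methylome_summary(c, cats)

    # ------------------------------------------------------ DMRs
    dmr_params = dmr_detection.DmrParams(thr.window_size, thr.step, thr.min_mcg,
                                         thr.dmr_q, thr.dmr_delta)
    for sp in species:
        for early, late in TRANSITIONS:
            tests, dmrs = dmr_detection.call_dmrs(called[sp][early], called[sp][late],
                                                  annotations[sp].chrom_lengths, dmr_params)
            tests.to_csv(out / f"dmr_windows_{sp}_{early}_{late}.tsv", sep="\t", index=False)
            io.write_regions_bed(
                dmrs.assign(delta=dmrs["max_abs_delta"]) if len(dmrs) else dmrs,
                out / f"dmr_{sp}_{early}_{late}.bed")
            key = f"dmr_{sp}_{early}->{late}"
            report[key] = {"n_dmrs": int(len(dmrs)),
                           "n_hyper": int((dmrs["status"] == "hyper").sum()) if len(dmrs) else 0,
                           "n_hypo": int((dmrs["status"] == "hypo").sum()) if len(dmrs) else 0}
            if config.simulate is not None:
                tr = truth_dmrs[sp]
                tr = tr[tr["transition"] == f"{early}->{late}"]
                report[key]["vs_truth"] = dmr_detection.evaluate_dmr_calls(dmrs, tr)

    # ------------------------------------------------------ MP/MGB + differential
    mp_tables: dict[str, pd.DataFrame] = {}
    for sp in species:
        for kind, label in (("promoter", "mp"), ("gene_body", "mgb")):
            table = fa.identify_mp_mgb(called[sp], annotations[sp],
                                       thr.mp_mgb_density, kind)
            table.to_csv(out / f"{label}_{sp}.tsv", sep="\t", index=False)
            if kind == "promoter":
                mp_tables[sp] = table
            qualified = table[table["qualifies"]]
            report[f"n_{label}_{sp}"] = int(len(qualified))
            for early, late in TRANSITIONS:
                diff = dmr_detection.call_differential_regions(
                    qualified[["chrom", "start", "end", "gene_id"]],
                    called[sp][early], called[sp][late], dmr_params, thr.mp_mgb_density)
                diff.to_csv(out / f"{label}_diff_{sp}_{early}_{late}.tsv",
                            sep="\t", index=False)

    # ------------------------------------------------------ expression
    tpm, mean_tpm = {}, {}
    de: dict[str, dict[str, pd.DataFrame]] = {}
    de_params = ed.DeParams(thr.de_q, thr.de_lfc)
    for sp in species:
        tpm[sp] = ed.compute_tpm(gene_counts[sp], gene_lengths[sp])
        tpm[sp].to_csv(out / f"tpm_genes_{sp}.tsv", sep="\t")
        mean_tpm[sp] = ed.stage_mean_tpm(tpm[sp]).mean(axis=1)
        de[sp] = {}
        for phase, (early, late) in PHASES.items():
            res = ed.de_test(gene_counts[sp], early, late, de_params)
            res.to_csv(out / f"de_{sp}_{phase}.tsv", sep="\t")
            de[sp][phase] = res
            report[f"n_deg_{sp}_{phase}"] = int((res["status"] != "none").sum())

    pairs = ed.filter_orthologs(pairs, thr.ortholog_min_fraction, thr.ortholog_min_length)
    pairs.to_csv(out / "ortholog_pairs.tsv", sep="\t", index=False)
    report["n_ortholog_pairs_kept"] = int(pairs["kept"].sum())
    sp_a, sp_b = species[0], species[-1]
    classified_all = []
    for phase in PHASES:
        classified = ed.classify_pairs(pairs, de[sp_a][phase], de[sp_b][phase], phase)
        classified_all.append(classified)
        counts = classified["divergence_class"].value_counts().to_dict()
        report[f"divergence_classes_{phase}"] = {k: int(v) for k, v in counts.items()}
        for subset in ("all", "non-DE0"):
            r, p, n = ed.foldchange_correlation(classified, subset)
            report[f"foldchange_correlation_{phase}_{subset}"] = {"r": r, "p": p, "n": n}
    pd.concat(classified_all, ignore_index=True).to_csv(
        out / "divergence_classes.tsv", sep="\t", index=False)

    # ------------------------------------------------------ TE analyses
    for sp in species:
        if sp not in te_counts:
            logger.info("no TE counts for %s; skipping TE expression analyses", sp)
            continue
        tes = annotations[sp].tes
        if len(tes) == 0:
            logger.info("no TE annotation for %s; skipping TE analyses", sp)
            continue
        te_tpm = ed.compute_tpm(te_counts[sp], te_lengths[sp])
        summary = ed.te_expression_summary(tes, te_tpm, thr.tpm_expressed)
        summary.to_csv(out / f"te_expression_{sp}.tsv", sep="\t", index=False)
        all_sites = pd.concat(called[sp].values(), ignore_index=True)
        te_meth = _region_pooled_levels(tes, all_sites)
        r, p, n = ed.methylation_expression_correlation(
            te_meth, ed.stage_mean_tpm(te_tpm).mean(axis=1), min_tpm=0.0)
        report[f"te_meth_expr_correlation_{sp}"] = {"r": r, "p": p, "n": n}
        dist = fa.te_distance_by_promoter_class(mp_tables[sp], tes)
        dist.to_csv(out / f"promoter_te_distance_{sp}.tsv", sep="\t", index=False)
        mp_q = mp_tables[sp][mp_tables[sp]["qualifies"]].set_index("gene_id")
        if len(mp_q) >= 3:
            by_expr = fa.methylation_by_expression_class(mp_q["mean_level"], mean_tpm[sp])
            by_expr.to_csv(out / f"mp_expression_classes_{sp}.tsv", sep="\t")
            groups = {k: g["meth_level"].to_numpy()
                      for k, g in by_expr.groupby("expr_class")}
            if all(len(g) >= 2 for g in groups.values()):
                gh = es.games_howell(groups)
                gh.to_csv(out / f"mp_expression_gameshowell_{sp}.tsv",
                          sep="\t", index=False)
                report[f"mp_meth_by_expr_gameshowell_{sp}"] = {
                    f"{r.group_a}-{r.group_b}": r.pvalue for r in gh.itertuples()}

    # ------------------------------------------------------ GO enrichment
    if len(go_map):
        kept = pairs[pairs["kept"]]
        expressed = ed.expressed_mask(tpm[sp_a], thr.tpm_expressed)
        universe = [g for g in kept["gene_a"] if expressed.get(g, False)]
        diverged_ids = set(pd.concat(classified_all).query(
            "divergence_class != 'DE0'")["gene_a"]) & set(universe)
        if universe and diverged_ids:
            enr = es.hypergeom_enrichment(diverged_ids, universe, go_map,
                                          thr.go_q, thr.go_min_genes)
            enr.to_csv(out / "go_enrichment.tsv", sep="\t", index=False)
            report["n_enriched_go_terms"] = int(enr["enriched"].sum()) if len(enr) else 0

    # ------------------------------------------------------ report + manifest
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    manifest = {
        "package": "methdev",
        "version": __version__,
        "seed": config.seed,
        "thresholds": dataclasses.asdict(thr),
        "simulate": dataclasses.asdict(sim) if config.simulate is not None else None,
        "outputs": {p.name: _sha256(p) for p in sorted(out.iterdir())
                    if p.is_file() and p.name != "manifest.json"},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_jsonable)
    return out


def _region_pooled_levels(regions: pd.DataFrame, sites: pd.DataFrame) -> pd.Series:
    """Pooled methylation level (sum meth / sum total) per region id."""
    from .dmr_detection import _per_chrom_arrays, _range_sums

    arrays = _per_chrom_arrays(sites)
    regions = regions.reset_index(drop=True)
    meth = np.zeros(len(regions), dtype="int64")
    total = np.zeros(len(regions), dtype="int64")
    for chrom, grp in regions.groupby("chrom", sort=False):
        s, e = grp["start"].to_numpy(), grp["end"].to_numpy()
        _, meth[grp.index], total[grp.index] = _range_sums(arrays, chrom, s, e)
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(total > 0, meth / np.maximum(total, 1), np.nan)
    return pd.Series(level, index=regions["id"].to_numpy()
                     if "id" in regions.columns else regions.index, name="level")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.ndarray,)):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")
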
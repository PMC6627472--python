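"""Readers and writers for the pipeline's external file formats.

This module is the single source of truth for coordinate conventions:
every interval inside the package is **0-based, half-open** ``[start, end)``.
Conversions happen only at the I/O boundary:

* Bismark-style cytosine reports carry 1-based positions -> converted on read.
* GFF3 is 1-based inclusive -> converted on read.
* BED is natively 0-based half-open -> passed through.

Per-cytosine data are held in a pandas DataFrame with the canonical columns
in :data:`SITE_COLUMNS` (one row per cytosine per strand).  CpG dyads are
*not* pooled across strands by default; :func:`merge_symmetric_cpgs` is
provided for pipelines that want the pooled convention.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

import gffutils
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical per-site schema. ``pos`` is 0-based. ``pvalue``/``qvalue`` are
#: NaN and ``is_mcg`` is pandas NA until mcg_calling has run.
SITE_COLUMNS = [
    "chrom", "pos", "strand", "context",
    "meth_reads", "total_reads", "level",
    "pvalue", "qvalue", "is_mcg",
]

#: The five-way transposable-element class vocabulary.
TE_CLASSES = ("Gypsy", "Copia", "LTR-other", "LINE", "DNA")

#: Genomic feature categories used for site assignment.
FEATURE_KINDS = ("gene", "exon", "intron", "promoter", "downstream1kb", "intergenic", "TE")


class ParseError(ValueError):
    """Raised when an input file has a malformed line (message carries the line number)."""


@dataclass
class FeatureInterval:
    """One genomic feature in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    kind: str = "gene"
    id: str = ""
    te_class: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty/negative interval {self.chrom}:{self.start}-{self.end}")
        if (self.te_class is not None) != (self.kind == "TE"):
            raise ValueError("te_class must be set iff kind='TE'")
        if self.te_class is not None and self.te_class not in TE_CLASSES:
            raise ValueError(f"unknown TE class {self.te_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """Genes (with exons), TEs and chromosome lengths for one genome.

    Interval tables are plain DataFrames with at least
    ``chrom, start, end, strand, id`` (TEs add ``te_class``).  Derived
    feature tables (promoters, introns, ...) are attached by
    :mod:`methdev.feature_annotation`.
    """

    chrom_lengths: dict[str, int]
    genes: pd.DataFrame
    exons: pd.DataFrame
    tes: pd.DataFrame
    derived: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.genes["id"].duplicated().any():
            dupes = self.genes.loc[self.genes["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate gene IDs: {dupes[:5]}")
        bad = set(self.tes["te_class"]) - set(TE_CLASSES)
        if bad:
            raise ValueError(f"TE classes outside the 5-way vocabulary: {sorted(bad)}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_tes(self) -> int:
        return len(self.tes)


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# per-cytosine reports
# ---------------------------------------------------------------------------

def make_sites_frame(
    chrom: Iterable[str],
    pos: Iterable[int],
    strand: Iterable[str],
    meth_reads: Iterable[int],
    total_reads: Iterable[int],
    context: str | Iterable[str] = "CG",
) -> pd.DataFrame:
    """Assemble a canonical site table from column vectors (pos 0-based)."""
    n = len(np.asarray(list(pos) if not hasattr(pos, "__len__") else pos))
    df = pd.DataFrame({
        "chrom": pd.Series(chrom, dtype="object"),
        "pos": pd.Series(pos, dtype="int64"),
        "strand": pd.Series(strand, dtype="object"),
        "context": context if isinstance(context, str) else pd.Series(context, dtype="object"),
        "meth_reads": pd.Series(meth_reads, dtype="int64"),
        "total_reads": pd.Series(total_reads, dtype="int64"),
    })
    if (df["meth_reads"] > df["total_reads"]).any():
        raise ValueError("meth_reads exceeds total_reads")
    with np.errstate(invalid="ignore", divide="ignore"):
        df["level"] = np.where(df["total_reads"] > 0,
                               df["meth_reads"] / df["total_reads"].where(df["total_reads"] > 0, 1),
                               np.nan)
    df["pvalue"] = np.nan
    df["qvalue"] = np.nan
    df["is_mcg"] = pd.array([pd.NA] * len(df), dtype="boolean")
    return df[SITE_COLUMNS]


def read_cytosine_report(path: str | Path, stage_label: str | None = None) -> pd.DataFrame:
    """Read a Bismark-style cytosine report (TSV, 1-based positions).

    Columns: chrom, position (1-based), strand, methylated count,
    unmethylated count, context.  Only CG-context rows are returned
    (others are skipped; the skip count is logged).  Positions are
    converted to 0-based.
    """
    chroms: list[str] = []
    pos: list[int] = []
    strands: list[str] = []
    meth: list[int] = []
    unmeth: list[int] = []
    skipped = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 tab-separated fields, got {len(parts)}")
            c, p, s, m, u, ctx = parts[:6]
            if ctx != "CG":
                skipped += 1
                continue
            if s not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: bad strand {s!r}")
            try:
                p_i, m_i, u_i = int(p), int(m), int(u)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field ({exc})") from None
            if p_i < 1 or m_i < 0 or u_i < 0:
                raise ParseError(f"{path}:{lineno}: negative count or position")
            chroms.append(c)
            pos.append(p_i - 1)
            strands.append(s)
            meth.append(m_i)
            unmeth.append(u_i)
    if skipped:
        logger.info("read_cytosine_report(%s): skipped %d non-CG rows", path, skipped)
    df = make_sites_frame(chroms, pos, strands, meth,
                          np.asarray(meth, dtype="int64") + np.asarray(unmeth, dtype="int64"))
    df.attrs["stage"] = stage_label
    df.attrs["n_non_cg_skipped"] = skipped
    return df


def write_cytosine_report(sites: pd.DataFrame, path: str | Path) -> None:
    """Write sites back to the six-column 1-based report format."""
    with _open_text(path, "wt") as fh:
        for row in sites.itertuples(index=False):
            unmeth = row.total_reads - row.meth_reads
            fh.write(f"{row.chrom}\t{row.pos + 1}\t{row.strand}\t{row.meth_reads}\t{unmeth}\t{row.context}\n")


def write_sites_tsv(sites: pd.DataFrame, path: str | Path) -> None:
    """Write the full canonical site table (0-based, all statistics columns)."""
    sites.to_csv(path, sep="\t", index=False)


def read_sites_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": "object", "strand": "object", "context": "object"})
    df["is_mcg"] = df["is_mcg"].astype("boolean")
    return df[SITE_COLUMNS]


def merge_symmetric_cpgs(sites: pd.DataFrame) -> pd.DataFrame:
    """Pool the two strands of each CpG dyad (+ at p with - at p+1).

    Returns plus-strand records with summed counts.  Sites without a
    partner keep their own counts (minus-strand orphans are re-anchored
    to the dyad's plus position p = pos-1).
    """
    plus = sites[sites["strand"] == "+"].copy()
    minus = sites[sites["strand"] == "-"].copy()
    minus["pos"] = minus["pos"] - 1
    pooled = (
        pd.concat([plus, minus])
        .groupby(["chrom", "pos"], as_index=False, sort=True)
        .agg(meth_reads=("meth_reads", "sum"), total_reads=("total_reads", "sum"))
    )
    return make_sites_frame(pooled["chrom"], pooled["pos"], "+",
                            pooled["meth_reads"], pooled["total_reads"])


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bp."""
    out: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
            out[parts[0]] = int(parts[1])
    return out


def read_annotation(
    gff_path: str | Path,
    te_bed_path: str | Path | None,
    chrom_lengths: Mapping[str, int],
    te_class_mapping: Mapping[str, str] | None = None,
) -> GenomeAnnotation:
    """Load genes/exons from GFF3 and TEs from BED6+1 (class in column 7).

    GFF coordinates (1-based inclusive) are converted to 0-based half-open.
    Unknown TE class labels are mapped through ``te_class_mapping`` or
    rejected.
    """
    db = gffutils.create_db(str(gff_path), ":memory:", merge_strategy="error",
                            keep_order=True)
    genes, exons = [], []
    for g in db.features_of_type("gene"):
        genes.append((g.seqid, g.start - 1, g.end, g.strand, g.id))
        for e in db.children(g.id, featuretype="exon"):
            if e.start - 1 < g.start - 1 or e.end > g.end:
                raise ValueError(f"exon {e.id} of {g.id} extends outside the gene")
            exons.append((e.seqid, e.start - 1, e.end, e.strand, g.id))
    genes_df = pd.DataFrame(genes, columns=["chrom", "start", "end", "strand", "id"])
    exons_df = pd.DataFrame(exons, columns=["chrom", "start", "end", "strand", "gene_id"])

    if te_bed_path is None:
        tes_df = pd.DataFrame(columns=["chrom", "start", "end", "strand", "id", "te_class"])
    else:
        tes_df = read_te_bed(te_bed_path, te_class_mapping)
    return GenomeAnnotation(dict(chrom_lengths), genes_df, exons_df, tes_df)


def read_te_bed(path: str | Path, te_class_mapping: Mapping[str, str] | None = None) -> pd.DataFrame:
    """BED6+1: chrom, start, end, name, score, strand, TE class."""
    rows = []
    mapping = dict(te_class_mapping or {})
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                raise ParseError(f"{path}:{lineno}: BED6+1 needs 7 columns")
            chrom, start, end, name, _score, strand, klass = parts[:7]
            klass = mapping.get(klass, klass)
            if klass not in TE_CLASSES:
                raise ValueError(f"{path}:{lineno}: TE class {klass!r} not in {TE_CLASSES} and no mapping given")
            rows.append((chrom, int(start), int(end), strand, name, klass))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "id", "te_class"])


def write_te_bed(tes: pd.DataFrame, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for row in tes.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.id}\t0\t{row.strand}\t{row.te_class}\n")


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Emit genes and exons as GFF3 (1-based inclusive)."""
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        exons_by_gene = dict(tuple(annotation.exons.groupby("gene_id", sort=False))) if len(annotation.exons) else {}
        for g in annotation.genes.itertuples(index=False):
            fh.write(f"{g.chrom}\tmethdev\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.id}\n")
            for i, e in enumerate(exons_by_gene.get(g.id, pd.DataFrame()).itertuples(index=False), start=1):
                fh.write(f"{e.chrom}\tmethdev\texon\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t"
                         f"ID={g.id}.e{i};Parent={g.id}\n")


def write_chrom_sizes(chrom_lengths: Mapping[str, int], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for chrom, length in chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")


# ---------------------------------------------------------------------------
# region tables / BED
# ---------------------------------------------------------------------------

def _chrom_sort_key(frame: pd.DataFrame) -> pd.DataFrame:
    try:
        return frame.sort_values(["chrom", "start"], key=lambda s: s if s.name != "chrom" else s.astype(str))
    except TypeError:  # pragma: no cover - unsortable names
        logger.warning("unsortable chromosome names; falling back to lexicographic order")
        return frame.sort_values(["chrom", "start"], key=lambda s: s.astype(str))


def write_regions_bed(regions: pd.DataFrame, path: str | Path) -> None:
    """Write regions as BED6: name = status, score = round(1000 * delta) clamped to [0, 1000].

    ``regions`` needs columns chrom/start/end/status and optionally
    ``delta`` (defaults to 0).
    """
    regions = regions.copy()
    if "delta" not in regions.columns:
        regions["delta"] = 0.0
    regions = _chrom_sort_key(regions)
    with _open_text(path, "wt") as fh:
        for row in regions.itertuples(index=False):
            score = int(np.clip(round(1000 * row.delta), 0, 1000))
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.status}\t{score}\t.\n")


def read_regions_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: BED6 needs 6 columns")
            rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3], int(parts[4]), parts[5]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "status", "score", "strand"])


# ---------------------------------------------------------------------------
# count matrices, ortholog pairs, GO maps
# ---------------------------------------------------------------------------

def read_count_matrix(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a TSV count matrix: feature_id, length, then sample columns.

    Sample columns are named ``STAGE:replicate`` (e.g. ``MY:1``) and become
    a two-level (stage, replicate) MultiIndex.  Returns (counts, lengths).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "length" not in df.columns:
        raise ParseError(f"{path}: missing 'length' column")
    lengths = df.pop("length").astype("int64")
    if (lengths <= 0).any():
        raise ValueError(f"{path}: non-positive feature length")
    cols = pd.MultiIndex.from_tuples(
        [tuple(c.split(":", 1)) for c in df.columns], names=["stage", "replicate"])
    if cols.duplicated().any():
        raise ValueError(f"{path}: duplicate sample columns")
    counts = df.astype("int64")
    counts.columns = cols
    if (counts.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative counts")
    return counts, lengths


def write_count_matrix(counts: pd.DataFrame, lengths: pd.Series, path: str | Path) -> None:
    out = counts.copy()
    out.columns = [f"{s}:{r}" for s, r in counts.columns]
    out.insert(0, "length", lengths.reindex(counts.index).astype("int64"))
    out.to_csv(path, sep="\t", index_label="feature_id")


def read_ortholog_pairs(path: str | Path) -> pd.DataFrame:
    """TSV with columns gene_a, gene_b, consensus_fraction, consensus_length_bp."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_a", "gene_b", "consensus_fraction", "consensus_length_bp"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_go_map(path: str | Path) -> pd.DataFrame:
    """Two-column TSV gene -> GO term (optional third column: term name)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3] if df.shape[1] >= 3 else df.iloc[:, :2]
    df.columns = ["gene", "term", "name"][: df.shape[1]]
    return df
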
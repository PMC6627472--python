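"""Feature geography: derivation, site assignment, MP/MGB, profiles, distances."""

import numpy as np
import pandas as pd
import pytest

from methdev import feature_annotation as fa
from methdev.io_formats import GenomeAnnotation
from methdev.mcg_calling import call_mcgs, depth_filter

from conftest import sites_from_counts


def toy_annotation(genes, exons=None, tes=None, length=20_000):
    genes_df = pd.DataFrame(genes, columns=["chrom", "start", "end", "strand", "id"])
    exons_df = pd.DataFrame(exons or [], columns=["chrom", "start", "end", "strand", "gene_id"])
    tes_df = pd.DataFrame(tes or [], columns=["chrom", "start", "end", "strand", "id", "te_class"])
    return GenomeAnnotation({"chr1": length}, genes_df, exons_df, tes_df)


class TestDeriveFeatures:
    def test_plus_strand_promoter_and_downstream(self):
        ann = fa.derive_features(toy_annotation([("chr1", 5000, 8000, "+", "g1")]))
        p = ann.derived["promoter"].iloc[0]
        d = ann.derived["downstream1kb"].iloc[0]
        assert (p["start"], p["end"]) == (4000, 5000)
        assert (d["start"], d["end"]) == (8000, 9000)

    def test_minus_strand_promoter_is_downstream_of_end(self):
        ann = fa.derive_features(toy_annotation([("chr1", 5000, 8000, "-", "g1")]))
        p = ann.derived["promoter"].iloc[0]
        assert (p["start"], p["end"]) == (8000, 9000)

    def test_promoter_truncated_at_chromosome_start(self):
        ann = fa.derive_features(toy_annotation([("chr1", 300, 1300, "+", "g1")]))
        p = ann.derived["promoter"].iloc[0]
        assert (p["start"], p["end"]) == (0, 300)

    def test_introns_are_gene_minus_exons(self):
        ann = fa.derive_features(toy_annotation(
            [("chr1", 1000, 2000, "+", "g1")],
            exons=[("chr1", 1000, 1200, "+", "g1"), ("chr1", 1500, 2000, "+", "g1")]))
        i = ann.derived["intron"].iloc[0]
        assert (i["start"], i["end"]) == (1200, 1500)


class TestSiteAssignment:
    @pytest.fixture
    def ann(self):
        return fa.derive_features(toy_annotation(
            [("chr1", 5000, 8000, "+", "g1")],
            exons=[("chr1", 5000, 6000, "+", "g1"), ("chr1", 7000, 8000, "+", "g1")],
            tes=[("chr1", 12000, 13000, ".", "te1", "Gypsy")]))

    @pytest.mark.parametrize("pos,expected", [
        (5500, "exon"),
        (6500, "intron"),
        (4500, "promoter"),
        (8500, "downstream1kb"),
        (12500, "TE"),
        (15000, "intergenic"),
    ])
    def test_single_category_by_precedence(self, ann, pos, expected):
        sites = sites_from_counts([pos], [1], [10])
        assert fa.assign_sites_to_features(sites, ann).iloc[0] == expected

    def test_promoter_beats_te_when_overlapping(self):
        # TE inside the promoter interval: gene-centric precedence wins
        ann = fa.derive_features(toy_annotation(
            [("chr1", 5000, 8000, "+", "g1")],
            tes=[("chr1", 4200, 4800, ".", "te1", "DNA")]))
        sites = sites_from_counts([4500], [1], [10])
        assert fa.assign_sites_to_features(sites, ann).iloc[0] == "promoter"

    def test_categories_partition_all_sites(self, small_dataset):
        ann = fa.derive_features(small_dataset.annotations["Pt"])
        sites = small_dataset.methylomes["Pt"].stage_sites["MY"]
        cats = fa.assign_sites_to_features(sites, ann)
        assert cats.notna().all()
        assert cats.value_counts().sum() == len(sites)


class TestMpMgb:
    def stage_sites(self, n_mcg_per_stage):
        out = {}
        for stage, n_mcg in n_mcg_per_stage.items():
            pos = np.arange(20) * 50  # 20 sites in a 1 kb promoter
            meth = np.where(np.arange(20) < n_mcg, 9, 0)
            sites = sites_from_counts(pos, meth, np.full(20, 10))
            sites["is_mcg"] = pd.array(np.arange(20) < n_mcg, dtype="boolean")
            out[stage] = sites
        return out

    @pytest.fixture
    def ann(self):
        # promoter [0,1000) of a gene at [1000,3000)
        return fa.derive_features(toy_annotation([("chr1", 1000, 3000, "+", "g1")]))

    def test_ten_mcg_in_one_stage_qualifies(self, ann):
        table = fa.identify_mp_mgb(self.stage_sites({"MY": 10, "PR": 0}), ann,
                                   10.0, "promoter")
        assert bool(table.iloc[0]["qualifies"])

    def test_nine_mcg_everywhere_does_not_qualify(self, ann):
        table = fa.identify_mp_mgb(self.stage_sites({"MY": 9, "PR": 9}), ann,
                                   10.0, "promoter")
        assert not bool(table.iloc[0]["qualifies"])

    def test_density_is_per_kb(self, ann):
        # 15 mCG over the 2 kb gene body -> 7.5/kb -> no MGB
        sites = {}
        pos = 1000 + np.arange(30) * 66
        meth = np.where(np.arange(30) < 15, 9, 0)
        s = sites_from_counts(pos, meth, np.full(30, 10))
        s["is_mcg"] = pd.array(np.arange(30) < 15, dtype="boolean")
        sites["MY"] = s
        table = fa.identify_mp_mgb(sites, ann, 10.0, "gene_body")
        assert table.iloc[0]["density_MY"] == pytest.approx(7.5)
        assert not bool(table.iloc[0]["qualifies"])

    def test_adding_mcgs_never_disqualifies(self, ann):
        base = fa.identify_mp_mgb(self.stage_sites({"MY": 10}), ann, 10.0, "promoter")
        more = fa.identify_mp_mgb(self.stage_sites({"MY": 14}), ann, 10.0, "promoter")
        assert bool(base.iloc[0]["qualifies"]) and bool(more.iloc[0]["qualifies"])


class TestMetaprofile:
    def test_uniform_level_gives_flat_profile(self):
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [2000], "end": [4000],
                                "strand": ["+"]})
        pos = np.arange(1000, 5000, 40)
        sites = sites_from_counts(pos, np.full(len(pos), 5), np.full(len(pos), 10))
        prof = fa.metaprofile(regions, {"MY": sites})
        assert np.nanmax(np.abs(prof["MY"].to_numpy() - 0.5)) < 1e-12

    def test_minus_strand_region_reverses_bins(self):
        pos = np.arange(1000, 5000, 40)
        level_grad = (pos - 1000) / 4000  # increasing along the chromosome
        sites = sites_from_counts(pos, (level_grad * 100).astype(int),
                                  np.full(len(pos), 100))
        plus = pd.DataFrame({"chrom": ["chr1"], "start": [2000], "end": [4000],
                             "strand": ["+"]})
        minus = plus.assign(strand="-")
        p_prof = fa.metaprofile(plus, {"MY": sites})["MY"].to_numpy()
        m_prof = fa.metaprofile(minus, {"MY": sites})["MY"].to_numpy()
        assert np.allclose(p_prof, m_prof[::-1], equal_nan=True)

    def test_uncovered_flank_bins_are_nan(self):
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000],
                                "strand": ["+"]})
        pos = np.arange(0, 1000, 50)
        sites = sites_from_counts(pos, np.full(len(pos), 2), np.full(len(pos), 10))
        prof = fa.metaprofile(regions, {"MY": sites})
        assert prof["MY"].iloc[:10].isna().all()  # nothing upstream of position 0

    def test_te_plateau_exceeds_flanks_on_synthetic_data(self, small_dataset):
        ann = small_dataset.annotations["Pt"]
        sites = small_dataset.methylomes["Pt"].stage_sites["MY"]
        prof = fa.metaprofile(ann.tes.assign(strand="+"), {"MY": sites})
        body = prof["MY"].iloc[10:30].mean()
        flanks = pd.concat([prof["MY"].iloc[:5], prof["MY"].iloc[-5:]]).mean()
        assert body > flanks

    def test_empty_region_set_rejected(self):
        with pytest.raises(ValueError):
            fa.metaprofile(pd.DataFrame(columns=["chrom", "start", "end"]), {})


class TestTeDistance:
    def test_gap_and_overlap_arithmetic(self):
        tes = pd.DataFrame({"chrom": ["chr1"], "start": [6000], "end": [7000]})
        regions = pd.DataFrame({"chrom": ["chr1", "chr1", "chr1"],
                                "start": [4000, 6500, 8000],
                                "end": [5000, 6600, 9000]})
        d = fa.nearest_te_distance(regions, tes)
        assert d.tolist() == [1000.0, 0.0, 1000.0]

    def test_no_te_on_chromosome_gives_nan(self):
        tes = pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [100]})
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        assert np.isnan(fa.nearest_te_distance(regions, tes).iloc[0])


class TestExpressionClasses:
    def test_tied_tpm_split_deterministically_into_equal_classes(self):
        meth = pd.Series(0.5, index=[f"g{i}" for i in range(9)])
        tpm = pd.Series(10.0, index=meth.index)
        out = fa.methylation_by_expression_class(meth, tpm)
        sizes = out["expr_class"].value_counts()
        assert sorted(sizes) == [3, 3, 3]
        again = fa.methylation_by_expression_class(meth, tpm)
        assert (out["expr_class"] == again["expr_class"]).all()

    def test_fewer_than_three_genes_rejected(self):
        meth = pd.Series([0.1, 0.2], index=["a", "b"])
        with pytest.raises(ValueError):
            fa.methylation_by_expression_class(meth, pd.Series([1.0, 2.0], index=["a", "b"]))


def test_promoter_classes_cover_none_plus_tertiles(small_dataset):
    ann = fa.derive_features(small_dataset.annotations["Pt"])
    called = {s: call_mcgs(depth_filter(df))
              for s, df in small_dataset.methylomes["Pt"].stage_sites.items()}
    mp = fa.identify_mp_mgb(called, ann, 10.0, "promoter")
    cls = fa.classify_promoters_by_methylation(mp)
    assert set(cls.unique()) <= {"none", "low", "medium", "high"}
    n_mp = int(mp["qualifies"].sum())
    assert (cls != "none").sum() == n_mp
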
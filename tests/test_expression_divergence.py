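"""TPM, NB Wald DE test, ortholog filtering and divergence classification."""

import numpy as np
import pandas as pd
import pytest

from methdev import expression_divergence as ed
from methdev import synthetic_data as sd


def counts_frame(arrays_by_stage, n_reps=3, index=None):
    cols = pd.MultiIndex.from_tuples(
        [(s, str(r + 1)) for s in arrays_by_stage for r in range(n_reps)],
        names=["stage", "replicate"])
    mat = np.column_stack([col for s in arrays_by_stage for col in
                           np.atleast_2d(np.asarray(arrays_by_stage[s])).T[:n_reps]])
    # arrays_by_stage[s] has shape (n_features, n_reps)
    mat = np.hstack([np.asarray(arrays_by_stage[s]) for s in arrays_by_stage])
    return pd.DataFrame(mat, columns=cols, index=index)


class TestTpm:
    def test_single_gene_gets_the_full_million(self):
        counts = counts_frame({"MY": np.array([[7, 3, 11]])}, index=["g1"])
        tpm = ed.compute_tpm(counts, pd.Series([500], index=["g1"]))
        assert np.allclose(tpm.to_numpy(), 1e6)

    def test_rate_normalisation_by_hand(self):
        counts = counts_frame({"MY": np.array([[100], [100]])}, n_reps=1,
                              index=["g1", "g2"])
        tpm = ed.compute_tpm(counts, pd.Series([1000, 2000], index=["g1", "g2"]))
        assert tpm.iloc[0, 0] == pytest.approx(2e6 / 3)
        assert tpm.iloc[1, 0] == pytest.approx(1e6 / 3)

    def test_columns_sum_to_one_million(self, small_dataset):
        expr = small_dataset.expression
        tpm = ed.compute_tpm(expr.gene_counts["Pt"], expr.gene_lengths["Pt"])
        assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-9)

    def test_all_zero_column_becomes_nan(self):
        counts = counts_frame({"MY": np.array([[0], [0]])}, n_reps=1, index=["g1", "g2"])
        tpm = ed.compute_tpm(counts, pd.Series([100, 100], index=["g1", "g2"]))
        assert tpm.iloc[:, 0].isna().all()

    def test_zero_length_rejected(self):
        counts = counts_frame({"MY": np.array([[1]])}, n_reps=1, index=["g1"])
        with pytest.raises(ValueError):
            ed.compute_tpm(counts, pd.Series([0], index=["g1"]))


class TestExpressedMask:
    @pytest.mark.parametrize("stage_means,expected", [
        ((0.5, 0.9, 0.99), False),  # never above 1
        ((0.0, 0.0, 1.01), True),   # strict > in one stage
    ])
    def test_threshold_is_strict_over_stage_means(self, stage_means, expected):
        cols = pd.MultiIndex.from_tuples(
            [(s, "1") for s in ("MY", "PR", "FB")], names=["stage", "replicate"])
        tpm = pd.DataFrame([stage_means], columns=cols, index=["g1"])
        assert ed.expressed_mask(tpm).iloc[0] == expected

    def test_empty_matrix_gives_empty_mask(self):
        assert len(ed.expressed_mask(pd.DataFrame())) == 0


class TestDeTest:
    def make_counts(self, rng, n=300, mean=150, disp=0.1, lfc_last=None):
        mu = rng.lognormal(np.log(mean), 0.7, n)
        mu_b = mu.copy()
        if lfc_last is not None:
            mu_b[-50:] = mu[-50:] * 2.0**lfc_last
        a = np.column_stack([sd._nb_draw(rng, mu, disp) for _ in range(3)])
        b = np.column_stack([sd._nb_draw(rng, mu_b, disp) for _ in range(3)])
        return counts_frame({"MY": a, "PR": b}, index=[f"f{i}" for i in range(n)])

    def test_identical_replicates_give_zero_lfc_and_none(self):
        counts = counts_frame({"MY": np.full((5, 3), 40), "PR": np.full((5, 3), 40)})
        res = ed.de_test(counts, "MY", "PR")
        assert np.allclose(res["log2fc"], 0)
        assert (res["status"] == "none").all()

    def test_label_symmetry_negates_lfc_and_preserves_q(self):
        rng = np.random.default_rng(0)
        counts = self.make_counts(rng, lfc_last=2.0)
        fwd = ed.de_test(counts, "MY", "PR")
        rev = ed.de_test(counts, "PR", "MY")
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["qvalue"].fillna(-1), rev["qvalue"].fillna(-1))

    def test_all_zero_feature_untested(self):
        counts = counts_frame({"MY": np.zeros((1, 3)), "PR": np.zeros((1, 3))})
        res = ed.de_test(counts, "MY", "PR")
        assert res.iloc[0]["status"] == "none" and np.isnan(res.iloc[0]["qvalue"])

    def test_planted_eightfold_changes_detected(self):
        rng = np.random.default_rng(1)
        counts = self.make_counts(rng, mean=200, disp=0.05, lfc_last=3.0)
        res = ed.de_test(counts, "MY", "PR")
        assert (res["status"].iloc[-50:] == "up").mean() >= 0.95

    def test_null_well_calibrated(self):
        rng = np.random.default_rng(2)
        counts = self.make_counts(rng, n=2000)
        res = ed.de_test(counts, "MY", "PR")
        assert (res["qvalue"] < 0.01).mean() <= 0.02

    def test_direction_agrees_with_pydeseq2_on_planted_data(self):
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(3)
        counts = self.make_counts(rng, n=200, lfc_last=2.5)
        res = ed.de_test(counts, "MY", "PR")
        meta = pd.DataFrame({"condition": ["A"] * 3 + ["B"] * 3},
                            index=[f"s{i}" for i in range(6)])
        mat = counts.T.reset_index(drop=True).set_index(meta.index)
        dds = DeseqDataSet(counts=mat.astype(int), metadata=meta,
                           design="~condition", quiet=True)
        dds.deseq2()
        stat = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
        stat.summary()
        ref = stat.results_df
        called_ref = set(ref.index[(ref["padj"] < 0.01)
                                   & (ref["log2FoldChange"].abs() > 1)])
        called_own = set(res.index[res["status"] != "none"])
        # same direction wherever both call, and large overlap of calls
        both = called_ref & called_own
        assert len(both) >= 0.8 * max(len(called_ref), 1)
        sign_ref = np.sign(ref.loc[sorted(both), "log2FoldChange"])
        sign_own = np.sign(res.loc[sorted(both), "log2fc"])
        assert (sign_ref.to_numpy() == sign_own.to_numpy()).all()


class TestOrthologFilter:
    @pytest.mark.parametrize("frac,length,kept", [
        (0.80, 400, True),
        (0.60, 400, False),
        (0.80, 250, False),
        (0.70, 400, False),   # strict inequality
        (0.80, 300, False),   # strict inequality
    ])
    def test_coverage_thresholds(self, frac, length, kept):
        pairs = pd.DataFrame({"gene_a": ["x"], "gene_b": ["y"],
                              "consensus_fraction": [frac],
                              "consensus_length_bp": [length]})
        assert ed.filter_orthologs(pairs)["kept"].iloc[0] == kept


class TestClassifyDivergence:
    @pytest.mark.parametrize("a,b,expected", [
        ("none", "none", "DE0"),
        ("up", "none", "DE1-Pt"),
        ("down", "none", "DE1-Pt"),
        ("none", "up", "DE1-Pe"),
        ("none", "down", "DE1-Pe"),
        ("up", "up", "DE2-identical"),
        ("down", "down", "DE2-identical"),
        ("up", "down", "DE2-opposite"),
        ("down", "up", "DE2-opposite"),
    ])
    def test_all_nine_status_pairs(self, a, b, expected):
        assert ed.classify_divergence(a, b) == expected

    def test_unknown_status_rejected(self):
        with pytest.raises(ValueError):
            ed.classify_divergence("sideways", "none")

    def test_classes_partition_pairs(self, small_dataset):
        expr = small_dataset.expression
        pairs = ed.filter_orthologs(expr.ortholog_pairs)
        de_a = ed.de_test(expr.gene_counts["Pt"], "MY", "PR")
        de_b = ed.de_test(expr.gene_counts["Pe"], "MY", "PR")
        cl = ed.classify_pairs(pairs, de_a, de_b, "phase1")
        counts = cl["divergence_class"].value_counts()
        assert counts.sum() == int(pairs["kept"].sum())
        assert set(counts.index) <= set(ed.DIVERGENCE_CLASSES)


class TestCorrelations:
    def frame(self, lfc_a, lfc_b):
        return pd.DataFrame({"log2fc_a": lfc_a, "log2fc_b": lfc_b,
                             "divergence_class": "DE0"})

    def test_identical_vectors_r_one(self):
        x = np.linspace(-2, 2, 20)
        r, p, n = ed.foldchange_correlation(self.frame(x, x))
        assert r == pytest.approx(1.0)

    def test_negated_vector_r_minus_one(self):
        x = np.linspace(-2, 2, 20)
        r, _, _ = ed.foldchange_correlation(self.frame(x, -x))
        assert r == pytest.approx(-1.0)

    def test_independent_effects_give_near_zero_r(self):
        rng = np.random.default_rng(4)
        r, _, n = ed.foldchange_correlation(
            self.frame(rng.normal(size=2000), rng.normal(size=2000)))
        assert abs(r) < 0.1 and n == 2000

    def test_constant_methylation_gives_nan(self):
        r, p, n = ed.methylation_expression_correlation(
            pd.Series([0.5, 0.5, 0.5, 0.5]), pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert np.isnan(r)

    def test_shuffled_methylation_loses_the_association(self, default_dataset):
        from methdev.pipeline import _region_pooled_levels
        from methdev.mcg_calling import call_mcgs, depth_filter

        ds = default_dataset
        sp = "Pt"
        called = pd.concat([call_mcgs(depth_filter(df))
                            for df in ds.methylomes[sp].stage_sites.values()],
                           ignore_index=True)
        te_meth = _region_pooled_levels(ds.annotations[sp].tes, called)
        te_tpm = ed.compute_tpm(ds.expression.te_counts[sp], ds.expression.te_lengths[sp])
        mean_tpm = ed.stage_mean_tpm(te_tpm).mean(axis=1)
        r_real, p_real, _ = ed.methylation_expression_correlation(te_meth, mean_tpm)
        rng = np.random.default_rng(0)
        shuffled = pd.Series(rng.permutation(te_meth.to_numpy()), index=te_meth.index)
        r_shuf, p_shuf, _ = ed.methylation_expression_correlation(shuffled, mean_tpm)
        assert r_real < 0 and p_real < 0.05
        assert abs(r_shuf) < abs(r_real)


class TestTeExpressionSummary:
    def test_counting_by_hand(self):
        tes = pd.DataFrame({"id": [f"te{i}" for i in range(100)],
                            "te_class": ["Gypsy"] * 100})
        cols = pd.MultiIndex.from_tuples([("FB", "1")], names=["stage", "replicate"])
        tpm = pd.DataFrame(np.zeros((100, 1)), index=tes["id"], columns=cols)
        tpm.iloc[:2, 0] = 5.0
        out = ed.te_expression_summary(tes, tpm)
        fb = out[(out["te_class"] == "Gypsy") & (out["stage"] == "FB")].iloc[0]
        assert fb["n_total"] == 100 and fb["n_expressed"] == 2
        assert fb["proportion"] == pytest.approx(0.02)

    def test_absent_class_omitted(self):
        tes = pd.DataFrame({"id": ["te1"], "te_class": ["LINE"]})
        cols = pd.MultiIndex.from_tuples([("MY", "1")], names=["stage", "replicate"])
        tpm = pd.DataFrame([[0.0]], index=["te1"], columns=cols)
        out = ed.te_expression_summary(tes, tpm)
        assert set(out["te_class"]) == {"LINE"}
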
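"""Sliding-window DMR machinery: tiling, eligibility, Fisher, merging."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methdev.dmr_detection import (
    DmrParams,
    _fisher_batch,
    call_differential_regions,
    call_dmrs,
    evaluate_dmr_calls,
    fisher_exact_2x2,
    make_windows,
    merge_windows,
    window_eligibility,
)
from methdev.mcg_calling import call_mcgs, depth_filter

from conftest import sites_from_counts


def brute_fisher(a, b, c, d):
    """Two-sided Fisher by full enumeration over fixed margins."""
    N, row1, col1 = a + b + c + d, a + b, a + c
    if N == 0 or row1 == 0 or row1 == N or col1 == 0 or col1 == N:
        return 1.0
    def pmf(k):
        return comb(row1, k) * comb(N - row1, col1 - k) / comb(N, col1)
    obs = pmf(a)
    return sum(pmf(k) for k in range(max(0, col1 - (N - row1)), min(row1, col1) + 1)
               if pmf(k) <= obs * (1 + 1e-12))


class TestMakeWindows:
    def test_tiling_rule_enumeration(self):
        w = make_windows({"chr1": 1400}, size=1000, step=200)
        assert w["start"].tolist() == [0, 200, 400, 600, 800, 1000, 1200]
        assert w["end"].tolist() == [1000, 1200, 1400, 1400, 1400, 1400, 1400]

    def test_short_chromosome_single_truncated_window(self):
        w = make_windows({"chr1": 500}, size=1000, step=200)
        assert (w.iloc[0]["start"], w.iloc[0]["end"]) == (0, 500)

    def test_step_equal_size_gives_disjoint_tiling(self):
        w = make_windows({"chr1": 3000}, size=1000, step=1000)
        assert (w["start"].to_numpy()[1:] == w["end"].to_numpy()[:-1]).all()


class TestEligibility:
    @pytest.mark.parametrize("na,nb,expected", [
        (10, 0, True),   # >= 10 in at least one stage
        (9, 9, False),   # boundary
        (0, 0, False),   # empty window
    ])
    def test_ten_mcg_in_at_least_one_stage(self, na, nb, expected):
        assert window_eligibility(np.array([na]), np.array([nb]))[0] == expected


class TestFisher:
    @pytest.mark.parametrize("table,expected", [
        ((5, 5, 5, 5), 1.0),
        ((10, 0, 0, 10), 2 / comb(20, 10)),
        ((3, 7, 3, 7), 1.0),
    ])
    def test_known_tables(self, table, expected):
        assert fisher_exact_2x2(*table) == pytest.approx(expected, rel=1e-9)

    def test_degenerate_margin_is_one(self):
        assert fisher_exact_2x2(0, 0, 3, 7) == 1.0

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_enumeration(self, a, b, c, d):
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            brute_fisher(a, b, c, d), rel=1e-9, abs=1e-12)

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    @settings(max_examples=200, deadline=None)
    def test_batch_path_agrees_with_scalar(self, a, b, c, d):
        batch = _fisher_batch([a], [a + b], [c], [c + d])[0]
        assert batch == pytest.approx(fisher_exact_2x2(a, b, c, d), rel=1e-9, abs=1e-12)


def two_stage_fixture(rng, n_sites=400, p_a=0.1, p_b=0.1, depth=30):
    pos = np.arange(n_sites) * 25
    total_a = rng.poisson(depth, n_sites) + 1
    total_b = rng.poisson(depth, n_sites) + 1
    a = sites_from_counts(pos, rng.binomial(total_a, p_a), total_a)
    b = sites_from_counts(pos, rng.binomial(total_b, p_b), total_b)
    return call_mcgs(depth_filter(a)), call_mcgs(depth_filter(b))


class TestCallDmrs:
    def test_pooled_count_example_and_delta(self):
        # one 1kb block: stage A pooled 30/100, stage B pooled 5/100
        pos = np.arange(10) * 100
        a = sites_from_counts(pos, [3] * 10, [10] * 10)
        b = sites_from_counts(pos, [1, 1, 1, 1, 1, 0, 0, 0, 0, 0], [10] * 10)
        a["is_mcg"] = pd.array([True] * 10, dtype="boolean")
        b["is_mcg"] = pd.array([True] * 10, dtype="boolean")
        tests, _ = call_dmrs(a, b, {"chr1": 1000}, DmrParams())
        row = tests.iloc[0]
        assert (row["meth_a"], row["total_a"], row["meth_b"], row["total_b"]) == (30, 100, 5, 100)
        assert row["delta"] == pytest.approx(-0.25)
        # enumeration-verified exact two-sided p for this table
        assert row["pvalue"] == pytest.approx(3.5476954553e-06, rel=1e-6)
        assert row["pvalue"] == pytest.approx(brute_fisher(30, 70, 5, 95), rel=1e-9)

    def test_delta_below_threshold_is_not_a_dmr(self):
        rng = np.random.default_rng(0)
        # strong significance but |delta| = 0.10 < 0.15
        pos = np.arange(40) * 25
        a = sites_from_counts(pos, np.full(40, 10), np.full(40, 100))
        b = sites_from_counts(pos, np.full(40, 20), np.full(40, 100))
        for df in (a, b):
            df["is_mcg"] = pd.array([True] * 40, dtype="boolean")
        tests, dmrs = call_dmrs(a, b, {"chr1": 1000}, DmrParams())
        assert (tests["qvalue"] < 0.01).all()
        assert (tests["status"] == "none").all() and len(dmrs) == 0

    def test_swapping_stages_maps_hyper_to_hypo(self, small_dataset):
        m = small_dataset.methylomes["Pt"]
        called = {s: call_mcgs(depth_filter(df)) for s, df in m.stage_sites.items()}
        lengths = small_dataset.annotations["Pt"].chrom_lengths
        fwd, dmr_fwd = call_dmrs(called["MY"], called["PR"], lengths)
        rev, dmr_rev = call_dmrs(called["PR"], called["MY"], lengths)
        assert np.allclose(fwd["pvalue"], rev["pvalue"])
        assert np.allclose(fwd["delta"], -rev["delta"])
        flip = {"hyper": "hypo", "hypo": "hyper", "none": "none"}
        assert (fwd["status"].map(flip) == rev["status"]).all()
        assert len(dmr_fwd) == len(dmr_rev)

    def test_null_methylome_produces_no_dmrs(self):
        rng = np.random.default_rng(2)
        a, b = two_stage_fixture(rng, p_a=0.5, p_b=0.5)
        _, dmrs = call_dmrs(a, b, {"chr1": 10_000})
        assert len(dmrs) == 0

    def test_planted_dmrs_recovered(self, small_dataset):
        m = small_dataset.methylomes["Pt"]
        called = {s: call_mcgs(depth_filter(df)) for s, df in m.stage_sites.items()}
        _, dmrs = call_dmrs(called["MY"], called["PR"],
                            small_dataset.annotations["Pt"].chrom_lengths)
        truth = m.truth_dmrs[m.truth_dmrs["transition"] == "MY->PR"]
        perf = evaluate_dmr_calls(dmrs, truth)
        assert perf["sensitivity"] >= 0.75 and perf["precision"] >= 0.75


class TestMergeWindows:
    def base(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "status",
                                           "delta", "qvalue"])

    def test_overlapping_same_status_merge(self):
        w = self.base([("chr1", 0, 1000, "hyper", 0.2, 1e-5),
                       ("chr1", 200, 1200, "hyper", 0.3, 1e-6)])
        m = merge_windows(w)
        assert len(m) == 1
        r = m.iloc[0]
        assert (r["start"], r["end"], r["n_windows"]) == (0, 1200, 2)
        assert r["max_abs_delta"] == pytest.approx(0.3)
        assert r["min_qvalue"] == pytest.approx(1e-6)

    def test_opposite_status_does_not_merge(self):
        w = self.base([("chr1", 0, 1000, "hyper", 0.2, 1e-5),
                       ("chr1", 200, 1200, "hypo", -0.3, 1e-6)])
        assert len(merge_windows(w)) == 2

    def test_bookended_windows_stay_separate(self):
        w = self.base([("chr1", 0, 1000, "hyper", 0.2, 1e-5),
                       ("chr1", 1000, 2000, "hyper", 0.2, 1e-5)])
        assert len(merge_windows(w)) == 2

    def test_single_window_single_dmr(self):
        m = merge_windows(self.base([("chr1", 0, 1000, "hypo", -0.2, 1e-4)]))
        assert len(m) == 1 and m.iloc[0]["n_windows"] == 1

    def test_same_status_dmrs_never_overlap(self, small_dataset):
        m = small_dataset.methylomes["Pe"]
        called = {s: call_mcgs(depth_filter(df)) for s, df in m.stage_sites.items()}
        _, dmrs = call_dmrs(called["PR"], called["FB"],
                            small_dataset.annotations["Pe"].chrom_lengths)
        for _, grp in dmrs.groupby(["chrom", "status"]):
            g = grp.sort_values("start")
            assert (g["start"].to_numpy()[1:] >= g["end"].to_numpy()[:-1]).all()


class TestDifferentialRegions:
    def test_identical_counts_give_p_one_status_none(self):
        pos = np.arange(20) * 50
        a = sites_from_counts(pos, np.full(20, 10), np.full(20, 20))
        b = a.copy()
        for df in (a, b):
            df["is_mcg"] = pd.array([True] * 20, dtype="boolean")
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        res = call_differential_regions(regions, a, b)
        assert res.iloc[0]["pvalue"] == 1.0 and res.iloc[0]["status"] == "none"

    def test_density_eligibility_boundary(self):
        # 9 mCG per kb in both stages -> not tested
        pos = np.arange(9) * 100
        a = sites_from_counts(pos, np.full(9, 9), np.full(9, 10))
        b = sites_from_counts(pos, np.full(9, 1), np.full(9, 10))
        for df in (a, b):
            df["is_mcg"] = pd.array([True] * 9, dtype="boolean")
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        res = call_differential_regions(regions, a, b)
        assert len(res) == 0

    def test_promoter_scale_example_hyper(self):
        # 20/200 vs 60/200 pooled -> delta +0.20, strongly significant
        pos = np.arange(20) * 50
        a = sites_from_counts(pos, np.full(20, 1), np.full(20, 10))
        b = sites_from_counts(pos, np.full(20, 3), np.full(20, 10))
        for df in (a, b):
            df["is_mcg"] = pd.array([True] * 20, dtype="boolean")
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        res = call_differential_regions(regions, a, b)
        row = res.iloc[0]
        assert row["delta"] == pytest.approx(0.20)
        assert row["pvalue"] == pytest.approx(brute_fisher(20, 180, 60, 140), rel=1e-9)
        assert row["status"] == "hyper"
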
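"""Strand merging, coverage filters, region statistics, thinning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from xcimeth.methylome import (
    CpGSiteTable,
    DuplicateSiteError,
    downsample_counts,
    merge_symmetric_cpgs,
    region_methylation,
    regions_methylation_frame,
    site_fractional_methylation,
)


def records(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos0", "strand", "m", "u"])


class TestMerge:
    def test_symmetric_pair_is_summed_at_plus_position(self):
        out = merge_symmetric_cpgs(records([
            ("c1", 100, "+", 3, 2), ("c1", 101, "-", 1, 4),
        ]))
        assert len(out) == 1
        assert out.iloc[0].tolist() == ["c1", 100, 4, 6]

    def test_unpaired_minus_mapped_to_plus_coordinate(self):
        out = merge_symmetric_cpgs(records([("c1", 55, "-", 2, 0)]))
        assert out.iloc[0].tolist() == ["c1", 54, 2, 0]

    def test_duplicate_same_strand_position_rejected(self):
        with pytest.raises(DuplicateSiteError):
            merge_symmetric_cpgs(records([
                ("c1", 10, "+", 1, 0), ("c1", 10, "+", 0, 1),
            ]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_merge_conserves_total_counts(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        pos = rng.choice(np.arange(5000), size=n, replace=False)
        strand = np.where(rng.random(n) < 0.5, "+", "-")
        df = records(list(zip(
            rng.choice(["c1", "c2"], n), pos, strand,
            rng.integers(0, 30, n), rng.integers(0, 30, n),
        )))
        out = merge_symmetric_cpgs(df)
        assert out["m"].sum() == df["m"].sum()
        assert out["u"].sum() == df["u"].sum()
        # positions strictly increasing within each chromosome
        for _, sub in out.groupby("chrom"):
            assert (np.diff(sub["pos0"]) > 0).all()


class TestSiteFractions:
    def table(self, cells):
        frames = {
            s: pd.DataFrame({
                "chrom": "c1",
                "pos0": range(len(rows)),
                "m": [r[0] for r in rows],
                "u": [r[1] for r in rows],
            })
            for s, rows in cells.items()
        }
        return CpGSiteTable.from_sample_frames(frames)

    def test_fraction_and_cutoff(self):
        t = self.table({"s1": [(4, 6), (1, 3)]})
        res = site_fractional_methylation(t, min_coverage=5)
        assert res.fractions[("s1")].iloc[0] == pytest.approx(0.4)
        assert np.isnan(res.fractions[("s1")].iloc[1])  # coverage 4 < 5
        assert res.qualifying_proportion["s1"] == pytest.approx(0.5)

    def test_higher_cutoff_is_stricter_but_unbiased(self):
        rng = np.random.default_rng(7)
        n = 2000
        cov = rng.poisson(30, n)
        m = rng.binomial(cov, 0.7)
        t = self.table({"s1": list(zip(m, cov - m))})
        r5 = site_fractional_methylation(t, min_coverage=5)
        r10 = site_fractional_methylation(t, min_coverage=10)
        assert r10.fractions["s1"].notna().sum() <= r5.fractions["s1"].notna().sum()
        # key summary (mean methylation) robust to the cutoff choice
        assert abs(r5.fractions["s1"].mean() - r10.fractions["s1"].mean()) < 0.01


class TestRegionMethylation:
    def test_hand_computed_weighted_and_mean(self):
        frames = {"s1": pd.DataFrame(
            {"chrom": "c1", "pos0": [10, 20], "m": [9, 1], "u": [1, 1]})}
        t = CpGSiteTable.from_sample_frames(frames)
        (s,) = region_methylation(t, "c1", 0, 100, min_coverage=1, min_sites=1)
        assert s.weighted == pytest.approx(10 / 12)
        assert s.mean == pytest.approx(0.7)

    def test_fully_methylated_region(self):
        frames = {"s1": pd.DataFrame(
            {"chrom": "c1", "pos0": [1, 2, 3, 4, 5], "m": [5] * 5, "u": [0] * 5})}
        t = CpGSiteTable.from_sample_frames(frames)
        (s,) = region_methylation(t, "c1", 0, 10)
        assert s.weighted == 1.0 and s.mean == 1.0

    def test_min_sites_is_strict_greater_than(self):
        frames = {"s1": pd.DataFrame(
            {"chrom": "c1", "pos0": [1, 2, 3], "m": [5] * 3, "u": [0] * 3})}
        t = CpGSiteTable.from_sample_frames(frames)
        (s,) = region_methylation(t, "c1", 0, 10, min_sites=3)
        assert np.isnan(s.mean)  # 3 qualifying sites is not "> 3"
        assert s.n_sites_qualifying == 3

    def test_empty_region_reports_reason(self):
        frames = {"s1": pd.DataFrame({"chrom": "c1", "pos0": [1], "m": [1], "u": [1]})}
        t = CpGSiteTable.from_sample_frames(frames)
        (s,) = region_methylation(t, "c1", 500, 600)
        assert np.isnan(s.weighted) and s.reason == "no covered sites"

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        n = 300
        pos = np.sort(rng.choice(np.arange(5000), n, replace=False))
        m = rng.integers(0, 20, n)
        u = rng.integers(0, 20, n)
        t = CpGSiteTable.from_sample_frames(
            {"s1": pd.DataFrame({"chrom": "c1", "pos0": pos, "m": m, "u": u})})
        for _ in range(200):
            a, b = sorted(rng.choice(5000, 2, replace=False))
            (s,) = region_methylation(t, "c1", a, b + 1, min_coverage=5, min_sites=3)
            sel = (pos >= a) & (pos < b + 1)
            mm, uu = m[sel], u[sel]
            cov = mm + uu
            exp_w = mm.sum() / cov.sum() if cov.sum() else np.nan
            qual = cov >= 5
            exp_mean = (mm[qual] / cov[qual]).mean() if qual.sum() > 3 else np.nan
            np.testing.assert_equal(np.isnan(s.weighted), np.isnan(exp_w))
            if not np.isnan(exp_w):
                assert s.weighted == pytest.approx(exp_w)
            np.testing.assert_equal(np.isnan(s.mean), np.isnan(exp_mean))
            if not np.isnan(exp_mean):
                assert s.mean == pytest.approx(exp_mean)

    def test_split_and_pool_invariance_of_weighted(self):
        rng = np.random.default_rng(3)
        pos = np.arange(0, 1000, 7)
        m = rng.integers(0, 30, len(pos))
        u = rng.integers(0, 30, len(pos))
        t = CpGSiteTable.from_sample_frames(
            {"s1": pd.DataFrame({"chrom": "c1", "pos0": pos, "m": m, "u": u})})
        (whole,) = region_methylation(t, "c1", 0, 1000, min_coverage=1)
        (left,) = region_methylation(t, "c1", 0, 500, min_coverage=1)
        (right,) = region_methylation(t, "c1", 500, 1000, min_coverage=1)
        sel_l = pos < 500
        w_l = (m[sel_l] + u[sel_l]).sum()
        w_r = (m[~sel_l] + u[~sel_l]).sum()
        pooled = (left.weighted * w_l + right.weighted * w_r) / (w_l + w_r)
        assert whole.weighted == pytest.approx(pooled)

    def test_sex_pooling_pools_counts_for_weighted(self):
        frames = {
            "f1": pd.DataFrame({"chrom": "c1", "pos0": [1], "m": [9], "u": [1]}),
            "f2": pd.DataFrame({"chrom": "c1", "pos0": [1], "m": [0], "u": [10]}),
        }
        t = CpGSiteTable.from_sample_frames(frames)
        (s,) = region_methylation(
            t, "c1", 0, 10, min_coverage=1, min_sites=0,
            sex_of={"f1": "female", "f2": "female"})
        assert s.group == "female"
        assert s.weighted == pytest.approx(9 / 20)

    def test_frame_variant_agrees_with_scalar(self):
        rng = np.random.default_rng(5)
        pos = np.sort(rng.choice(2000, 100, replace=False))
        t = CpGSiteTable.from_sample_frames(
            {"s1": pd.DataFrame({"chrom": "c1", "pos0": pos,
                                 "m": rng.integers(0, 9, 100),
                                 "u": rng.integers(0, 9, 100)})})
        regions = [(f"r{i}", "c1", i * 100, i * 100 + 400) for i in range(10)]
        frame = regions_methylation_frame(t, regions)
        for rid, chrom, a, b in regions:
            (s,) = region_methylation(t, chrom, a, b, region_id=rid)
            row = frame[frame["region_id"] == rid].iloc[0]
            np.testing.assert_equal(row["weighted"], s.weighted)
            np.testing.assert_equal(row["mean"], s.mean)


class TestDownsampling:
    def table_single(self, m, u, n=1):
        return CpGSiteTable.from_sample_frames(
            {"s1": pd.DataFrame({"chrom": "c1", "pos0": range(n),
                                 "m": [m] * n, "u": [u] * n})})

    def test_keep_all_is_identity(self):
        t = self.table_single(7, 3, n=10)
        out = downsample_counts(t, 1.0, seed=0)
        pd.testing.assert_frame_equal(out.counts, t.counts)

    def test_half_thinning_within_binomial_bounds(self):
        t = self.table_single(1000, 1000)
        out = downsample_counts(t, 0.5, seed=1)
        cov = out.coverage()["s1"].iloc[0]
        assert 900 <= cov <= 1100  # +-3.2 sd of Binomial(2000, .5)

    def test_thinning_preserves_fractions_at_high_coverage(self):
        rng = np.random.default_rng(2)
        n = 1000
        m = rng.binomial(200, 0.6, n)
        t = CpGSiteTable.from_sample_frames(
            {"s1": pd.DataFrame({"chrom": "c1", "pos0": range(n),
                                 "m": m, "u": 200 - m})})
        out = downsample_counts(t, 0.5, seed=3)
        f_before = t.m()["s1"] / t.coverage()["s1"]
        f_after = out.m()["s1"] / out.coverage()["s1"]
        delta = f_after - f_before
        # independent oracle: direct binomial thinning of the same counts
        mo = rng.binomial(m, 0.5)
        uo = rng.binomial(200 - m, 0.5)
        oracle_delta = mo / (mo + uo) - m / 200
        assert abs(delta.abs().mean() - np.abs(oracle_delta).mean()) < 0.005
        assert abs(delta.mean()) < 0.005  # thinning is unbiased

    def test_deterministic_under_seed(self):
        t = self.table_single(50, 50, n=20)
        a = downsample_counts(t, 0.3, seed=9)
        b = downsample_counts(t, 0.3, seed=9)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            downsample_counts(self.table_single(1, 1), 0.0, seed=0)
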
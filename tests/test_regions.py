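import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sweepx import regions as reg
from sweepx.types import SelectionRegion
from tests.conftest import make_snp_map


def outlier_df(positions, values, col="ihs"):
    return pd.DataFrame(
        {
            "pos": positions,
            "snp_id": [f"s{i}" for i in range(len(positions))],
            col: values,
        }
    )


class TestIhsOutliers:
    def test_strict_threshold_excludes_boundary_and_na(self):
        track = outlier_df(
            [10, 20, 30, 40, 50], [-2.5, 1.9, 2.0, 3.1, np.nan]
        )
        out = reg.ihs_outliers(track)
        assert out["pos"].tolist() == [10, 40]

    def test_empty_track(self):
        assert len(reg.ihs_outliers(outlier_df([], []))) == 0


class TestBoxplot:
    def test_worked_example(self):
        vals = np.array(list(range(1, 12)) + [100], dtype=float)
        thr, mask = reg.boxplot_outliers(vals)
        assert thr.f_l == pytest.approx(3.75)
        assert thr.f_u == pytest.approx(9.25)
        assert thr.q == pytest.approx(5.5)
        assert thr.ul == pytest.approx(17.5)
        assert thr.ll == pytest.approx(-4.5)
        assert np.flatnonzero(mask).tolist() == [11]

    def test_constant_values_have_no_outliers(self):
        thr, mask = reg.boxplot_outliers(np.full(10, 0.3))
        assert thr.ul == thr.ll == pytest.approx(0.3)
        assert not mask.any()

    def test_symmetric_fences(self):
        vals = np.array([-4, -2, -1, 0, 1, 2, 4], dtype=float)
        thr, _ = reg.boxplot_outliers(vals)
        assert thr.ul - thr.f_u == pytest.approx(thr.f_l - thr.ll)

    def test_too_few_values_error(self):
        with pytest.raises(ValueError, match=">= 4"):
            reg.boxplot_outliers(np.array([1.0, 2.0, 3.0]))

    @given(st.integers(0, 100_000))
    @settings(max_examples=100, deadline=None)
    def test_matches_sort_interpolate_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 1000))
        vals = rng.gamma(2.0, 0.05, size=n)
        thr, mask = reg.boxplot_outliers(vals)
        s = np.sort(vals)
        rank_l, rank_u = 0.25 * (n - 1), 0.75 * (n - 1)

        def interp(r):
            lo = int(np.floor(r))
            frac = r - lo
            hi = min(lo + 1, n - 1)
            return s[lo] * (1 - frac) + s[hi] * frac

        f_l, f_u = interp(rank_l), interp(rank_u)
        assert thr.f_l == pytest.approx(f_l, abs=1e-12)
        assert thr.f_u == pytest.approx(f_u, abs=1e-12)
        q = f_u - f_l
        expect = (vals > f_u + 1.5 * q) | (vals < f_l - 1.5 * q)
        assert (mask == expect).all()


class TestBhFdr:
    def test_step_up_hand_example(self):
        q = reg.bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert reg.bh_fdr(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_all_ones(self):
        assert (reg.bh_fdr(np.ones(5)) == 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            reg.bh_fdr(np.array([0.5, 1.5]))

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(int(rng.integers(1, 50)))
        q = reg.bh_fdr(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()
        perm = rng.permutation(len(p))
        assert np.allclose(reg.bh_fdr(p[perm]), q[perm])

    def test_empirical_upper_tail_ranks(self):
        p = reg.empirical_upper_tail_p(np.array([0.1, 0.5, 0.3]))
        # #{>= 0.5}=1, #{>= 0.3}=2, #{>= 0.1}=3; n=3
        assert np.allclose(p, [(1 + 3) / 4, (1 + 1) / 4, (1 + 2) / 4])


class TestBuildRegions:
    def test_single_outlier_window(self):
        m = make_snp_map([122_360_000])
        out = outlier_df([122_360_000], [5.85])
        regs = reg.build_regions(out, m, "ihs", "ihs", "GM")
        assert regs[0].start_bp == 122_160_000
        assert regs[0].end_bp == 122_560_000
        assert regs[0].length_mb == pytest.approx(0.40)

    def test_nearby_outliers_merge(self):
        m = make_snp_map([1_000_000, 1_300_000])
        out = outlier_df([1_000_000, 1_300_000], [2.5, -3.0])
        regs = reg.build_regions(out, m, "ihs", "ihs")
        assert len(regs) == 1
        assert regs[0].length_mb == pytest.approx(0.7)
        assert regs[0].peak_value == -3.0  # larger |value|

    def test_empty_in_empty_out(self):
        m = make_snp_map([100])
        assert reg.build_regions(outlier_df([], []), m, "ihs", "ihs") == []

    def test_clamped_to_chromosome(self):
        m = make_snp_map([50_000])
        out = outlier_df([50_000], [3.0])
        regs = reg.build_regions(out, m, "ihs", "ihs",
                                 chrom_length=120_000)
        assert regs[0].start_bp == 1
        assert regs[0].end_bp == 120_000

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_merge_idempotent_and_order_free(self, seed):
        rng = np.random.default_rng(seed)
        regs = [
            SelectionRegion(
                "X", int(s), int(s) + int(rng.integers(1, 500_000)),
                f"s{i}", float(rng.normal()), "ihs", "L",
            )
            for i, s in enumerate(
                rng.integers(1, 5_000_000, size=rng.integers(1, 15))
            )
        ]
        merged = reg.merge_regions(regs)
        assert reg.merge_regions(merged) == merged
        shuffled = [regs[i] for i in rng.permutation(len(regs))]
        merged2 = reg.merge_regions(shuffled)
        assert [(r.start_bp, r.end_bp) for r in merged] == [
            (r.start_bp, r.end_bp) for r in merged2
        ]
        for a, b in zip(merged, merged[1:]):
            assert b.start_bp > a.end_bp


class TestCombine:
    def _region(self, start, end, method="ihs", peak=3.0):
        return SelectionRegion("X", start, end, "s", peak, method, "L")

    def _track(self, positions, col, values):
        return pd.DataFrame(
            {
                "pos": positions,
                "snp_id": [f"s{i}" for i in range(len(positions))],
                col: values,
            }
        )

    def test_threshold_mode_is_merged_union(self):
        a = [self._region(100, 500)]
        b = [self._region(400, 900, "fst")]
        out = reg.combine_candidates(a, b, mode="threshold")
        assert len(out) == 1
        assert (out[0].start_bp, out[0].end_bp) == (100, 900)
        assert out[0].method == "combined"

    def test_fdr_single_method_rule(self):
        # iHS q at the region's peak ~ 0.03 -> candidate via one-method
        # rule even with no F_ST signal
        ihs_track = self._track([200], "ihs", [3.5])
        fst_track = self._track([200], "fst", [0.01])
        region = [self._region(100, 500)]
        out = reg.combine_candidates(
            region, [], mode="fdr",
            ihs_track=ihs_track, fst_track=fst_track,
        )
        assert len(out) == 1

    def test_fdr_both_methods_rule_and_rejection(self):
        # many SNPs so BH does not collapse; the region's best iHS
        # |z|=1.0 has q ~ 0.6 -> rejected
        rng = np.random.default_rng(0)
        pos = np.arange(100) * 1000 + 500
        z = rng.normal(0, 0.3, 100)
        z[50] = 1.0
        ihs_track = self._track(pos.tolist(), "ihs", z.tolist())
        fstv = rng.uniform(0, 0.05, 100)
        fst_track = self._track(pos.tolist(), "fst", fstv.tolist())
        region = [self._region(50_000, 51_000)]
        out = reg.combine_candidates(
            region, [], mode="fdr",
            ihs_track=ihs_track, fst_track=fst_track,
        )
        assert out == []

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="mode"):
            reg.combine_candidates([], [], mode="bogus")


class TestSummaryAndOverlap:
    def test_table1_style_arithmetic(self):
        regs = [
            SelectionRegion("X", 0, 400_000, "a", 3.0, "ihs", "GM"),
            SelectionRegion("X", 1_000_000, 1_400_000, "b", 2.5, "ihs", "GM"),
            SelectionRegion("X", 2_000_000, 2_500_000, "c", 4.0, "ihs", "GM"),
        ]
        df = reg.summarize_regions({("ihs", "GM"): regs})
        row = df.iloc[0]
        assert row["n_regions"] == 3
        assert row["avg_length_mb"] == pytest.approx(0.43)
        assert row["total_length_mb"] == pytest.approx(1.3)

    def test_overlap_partial(self):
        a = [
            SelectionRegion("X", 0, 400_000, "a", 1.0, "ihs", "A"),
            SelectionRegion("X", 1_000_000, 1_400_000, "b", 1.0, "ihs", "A"),
        ]
        b = [SelectionRegion("X", 200_000, 600_000, "c", 1.0, "fst", "B")]
        assert reg.overlap_length_mb(a, b) == pytest.approx(0.2)
        assert reg.overlap_length_mb(b, a) == pytest.approx(0.2)

    def test_overlap_identity_and_bound(self):
        a = [
            SelectionRegion("X", 0, 300_000, "a", 1.0, "ihs", "A"),
            SelectionRegion("X", 500_000, 900_000, "b", 1.0, "ihs", "A"),
        ]
        total = sum(r.length_mb for r in a)
        assert reg.overlap_length_mb(a, a) == pytest.approx(total)
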
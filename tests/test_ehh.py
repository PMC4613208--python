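import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sweepx import ehh
from sweepx.ehh import EHHCurve
from sweepx.types import HaplotypeMatrix, PopulationMap
from tests.conftest import make_snp_map


def ehh_pair_oracle(D, positions, core, allele, side):
    """Brute force: at each flanking SNP, count haplotype pairs
    identical at every SNP between core and flank inclusive."""
    carriers = [i for i in range(D.shape[0]) if D[i, core] == allele]
    n = len(carriers)
    pairs = n * (n - 1) // 2
    idx = (
        range(core - 1, -1, -1) if side == "left"
        else range(core + 1, D.shape[1])
    )
    out = [(0, 1.0)]
    for s in idx:
        lo, hi = min(core, s), max(core, s)
        ident = 0
        for a in range(n):
            for b in range(a + 1, n):
                if np.array_equal(
                    D[carriers[a], lo:hi + 1], D[carriers[b], lo:hi + 1]
                ):
                    ident += 1
        out.append((int(positions[s] - positions[core]), ident / pairs))
    return out


class TestEhhCurve:
    def test_identical_carriers_stay_at_one(self):
        D = np.zeros((6, 5), dtype=np.int8)
        pos = np.array([10, 20, 30, 40, 50])
        c = ehh.ehh_side(D, pos, 2, 0, "right")
        assert c.ehh.tolist() == [1.0, 1.0, 1.0]

    def test_group_split_3_2_1(self):
        # 6 carriers split into groups {3,2,1} at the first flank:
        # identical pairs = C(3,2)+C(2,2) = 4 of C(6,2)=15
        D = np.zeros((6, 3), dtype=np.int8)
        D[:, 1] = [0, 0, 0, 1, 1, 1]
        D[:, 2] = [0, 0, 0, 0, 0, 1]
        pos = np.array([100, 200, 300])
        c = ehh.ehh_side(D, pos, 0, 0, "right")
        # at SNP1: groups {3,3} -> (3+3)/15; at SNP2: {3,2,1} -> 4/15
        assert c.ehh[1] == pytest.approx(6 / 15)
        assert c.ehh[2] == pytest.approx(4 / 15)

    def test_all_distinct_gives_zero(self):
        D2 = np.zeros((4, 3), dtype=np.int8)
        D2[:, 1] = [0, 0, 1, 1]
        D2[:, 2] = [0, 1, 0, 1]
        pos = np.array([10, 20, 30])
        c = ehh.ehh_side(D2, pos, 0, 0, "right")
        assert c.ehh[2] == 0.0

    def test_fewer_than_two_carriers_unavailable(self):
        D = np.zeros((4, 3), dtype=np.int8)
        D[0, 1] = 1
        pos = np.array([10, 20, 30])
        c = ehh.ehh_side(D, pos, 1, 1, "right")
        assert not c.available

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_h = rng.integers(2, 13)
        n_s = rng.integers(2, 21)
        D = (rng.random((n_h, n_s)) < rng.uniform(0.2, 0.8)).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 10_000), n_s, replace=False))
        core = int(rng.integers(0, n_s))
        allele = int(rng.integers(0, 2))
        side = "left" if rng.random() < 0.5 else "right"
        if (D[:, core] == allele).sum() < 2:
            return
        curve = ehh.ehh_side(D, pos, core, allele, side)
        oracle = ehh_pair_oracle(D, pos, core, allele, side)
        # the implementation may stop once EHH hits 0; beyond that the
        # oracle must be 0 too
        for k, (d, e) in enumerate(oracle):
            if k < len(curve.ehh):
                assert curve.distances[k] == d
                assert curve.ehh[k] == pytest.approx(e, abs=1e-12)
            else:
                assert e == 0.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_monotone_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        D = (rng.random((10, 15)) < 0.5).astype(np.int8)
        pos = np.arange(1, 16) * 100
        for side in ("left", "right"):
            c = ehh.ehh_side(D, pos, 7, 0, side)
            if c.available:
                assert (np.diff(c.ehh) <= 1e-15).all()


class TestIntegrateEhh:
    def test_three_point_trapezoid(self):
        curve = EHHCurve(0, "", [0, 10_000, 20_000], [1.0, 0.5, 0.05])
        total, flags = ehh.integrate_ehh(curve, ehh_cutoff=0.04)
        assert total == pytest.approx(10_250.0)
        assert flags == set()

    def test_constant_one_rectangle(self):
        curve = EHHCurve(0, "", [0, 40_000, 100_000], [1.0, 1.0, 1.0])
        total, _ = ehh.integrate_ehh(curve)
        assert total == pytest.approx(100_000.0)

    def test_cutoff_excludes_first_low_point(self):
        curve = EHHCurve(0, "", [0, 10_000], [1.0, 0.02])
        total, _ = ehh.integrate_ehh(curve, ehh_cutoff=0.05)
        assert total == 0.0

    def test_gap_truncation_flagged(self):
        curve = EHHCurve(
            0, "", [0, 100_000, 700_000], [1.0, 0.9, 0.8]
        )
        total, flags = ehh.integrate_ehh(curve, max_gap_bp=500_000)
        assert "truncated_by_gap" in flags
        assert total == pytest.approx(100_000 * 1.9 / 2)

    def test_left_side_uses_absolute_distance(self):
        right = EHHCurve(0, "", [0, 10_000], [1.0, 0.5])
        left = EHHCurve(0, "", [0, -10_000], [1.0, 0.5])
        assert ehh.integrate_ehh(right)[0] == ehh.integrate_ehh(left)[0]


class TestRawIhs:
    def test_equal_integrals_give_zero(self):
        assert ehh.raw_ihs(12_345.0, 12_345.0) == 0.0

    def test_ln_two(self):
        assert ehh.raw_ihs(2.0, 1.0) == pytest.approx(math.log(2))

    def test_zero_integral_is_na(self):
        assert math.isnan(ehh.raw_ihs(1.0, 0.0))
        assert math.isnan(ehh.raw_ihs(0.0, 1.0))


class TestStandardize:
    def test_bins_have_mean_zero_sd_one(self):
        rng = np.random.default_rng(11)
        freq = rng.uniform(0.05, 0.95, 500)
        raw = rng.normal(freq, 0.5)  # frequency-dependent raw scores
        z, _ = ehh.standardize_ihs(raw, freq)
        bins = ehh._bin_index(freq, 0.05)
        for b in np.unique(bins):
            sel = (bins == b) & np.isfinite(z)
            if sel.sum() >= 2:
                assert abs(z[sel].mean()) < 1e-6
                assert abs(z[sel].std(ddof=1) - 1) < 1e-6

    def test_p_ihs_is_two_sided_gaussian_tail(self):
        from scipy.stats import norm

        rng = np.random.default_rng(9)
        raw = rng.normal(size=50)
        z, p = ehh.standardize_ihs(raw, np.full(50, 0.5), bin_width=1.0)
        assert np.allclose(p, -np.log10(2 * norm.sf(np.abs(z))), atol=1e-12)
        # a score standardized to exactly 1.96 maps to ~ -log10(0.05)
        assert -np.log10(2 * norm.sf(1.96)) == pytest.approx(1.301, abs=5e-3)
        # and a zero score maps to p_ihs = 0 (p = 1)
        assert -np.log10(2 * norm.sf(0.0)) == 0.0

    def test_small_bin_gives_na_with_warning(self):
        with pytest.warns(UserWarning, match="cannot standardize"):
            z, _ = ehh.standardize_ihs(
                np.array([0.3]), np.array([0.5])
            )
        assert math.isnan(z[0])

    def test_single_bin_recovers_global_standardization(self):
        rng = np.random.default_rng(2)
        raw = rng.normal(size=200)
        freq = rng.uniform(0.05, 0.95, 200)
        z, _ = ehh.standardize_ihs(raw, freq, bin_width=1.0)
        expect = (raw - raw.mean()) / raw.std(ddof=1)
        assert np.allclose(z, expect, atol=1e-12)


class TestScanProperties:
    def _panel(self, seed=0, n_samples=30, n_snps=60):
        rng = np.random.default_rng(seed)
        n_h = 2 * n_samples
        founders = (rng.random((8, n_snps)) < rng.uniform(0.2, 0.8, n_snps))
        choice = rng.integers(0, 8, size=(n_h, 4))
        blocks = np.array_split(np.arange(n_snps), 4)
        values = np.zeros((n_h, n_snps), dtype=np.int8)
        for h in range(n_h):
            for b, blk in enumerate(blocks):
                values[h, blk] = founders[choice[h, b], blk]
        samples = [f"s{i}" for i in range(n_samples)]
        H = HaplotypeMatrix(samples, values)
        pops = PopulationMap({s: "P" for s in samples})
        snp_map = make_snp_map(
            (np.arange(n_snps) * 50_000 + 1).tolist(),
            ancestral=["ref"] * n_snps,
        )
        return H, snp_map, pops

    def test_allele_swap_negates_raw(self):
        H, snp_map, pops = self._panel(seed=4)
        track = ehh.ihs_scan(H, snp_map, pops, "P")
        flipped = snp_map.table.copy()
        flipped["ancestral"] = "alt"
        from sweepx.types import SNPMap

        track2 = ehh.ihs_scan(H, SNPMap(flipped), pops, "P")
        a, b = track["raw_ihs"].to_numpy(), track2["raw_ihs"].to_numpy()
        both = np.isfinite(a) & np.isfinite(b)
        assert both.any()
        assert np.allclose(a[both], -b[both], atol=1e-12)

    def test_translation_invariance_of_ihh(self):
        H, snp_map, pops = self._panel(seed=5)
        track = ehh.ihs_scan(H, snp_map, pops, "P")
        shifted = snp_map.table.copy()
        shifted["pos"] = shifted["pos"] + 7_777
        from sweepx.types import SNPMap

        track2 = ehh.ihs_scan(H, SNPMap(shifted), pops, "P")
        for col in ("ihh_a", "ihh_d"):
            a = track[col].to_numpy()
            b = track2[col].to_numpy()
            both = np.isfinite(a) & np.isfinite(b)
            assert np.allclose(a[both], b[both], atol=1e-9)

    def test_unknown_ancestral_is_skipped(self):
        H, snp_map, pops = self._panel(seed=6)
        t = snp_map.table.copy()
        t.loc[0, "ancestral"] = "unknown"
        from sweepx.types import SNPMap

        track = ehh.ihs_scan(H, SNPMap(t), pops, "P")
        assert track["flags"].iloc[0] == "no_ancestral"
        assert math.isnan(track["ihs"].iloc[0])

    def test_single_sample_population_errors(self):
        H, snp_map, pops = self._panel(n_samples=1)
        with pytest.raises(ValueError, match="no eligible"):
            ehh.ihs_scan(H, snp_map, pops, "P")
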
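import numpy as np
import pytest

from polyadapt import (
    DegenerateInputError,
    LdScoreRegression,
    UndefinedStatisticError,
    bivariate_ldsc,
    frequency_contrast,
    genetic_correlation_from_arrays,
    moment_vs_ldscore,
    normalize_by_maf_bins,
    univariate_ldsc,
)
from polyadapt.ldsc import bed_mask, default_exclusion_regions

from conftest import toy_frequency_matrix


@pytest.fixture(scope="module")
def sim_l2():
    rng = np.random.default_rng(0)
    return 1.0 + rng.gamma(2.0, 50.0, size=8000)


class TestNormalizeByMafBins:
    def test_bins_zero_mean_unit_sd(self):
        rng = np.random.default_rng(1)
        maf = rng.uniform(0.0, 0.5, 500)
        out = normalize_by_maf_bins(rng.normal(size=500), maf, bin_width=0.05)
        idx = np.minimum(np.floor(maf / 0.05).astype(int), 9)
        for k in np.unique(idx):
            assert abs(out[idx == k].mean()) < 1e-10
            assert out[idx == k].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_matches_hand_z_scores(self):
        maf = np.array([0.005, 0.007, 0.008, 0.009, 0.032, 0.034, 0.036, 0.039])
        vals = np.array([1.0, 2.0, 4.0, 5.0, -1.0, 0.0, 2.0, 3.0])
        out = normalize_by_maf_bins(vals, maf)
        a, b = vals[:4], vals[4:]
        expected = np.concatenate(
            [(a - a.mean()) / a.std(ddof=1), (b - b.mean()) / b.std(ddof=1)]
        )
        assert np.allclose(out, expected)

    def test_idempotent_when_single_bin_normalized(self):
        rng = np.random.default_rng(2)
        maf = np.full(100, 0.25)
        once = normalize_by_maf_bins(rng.normal(size=100), maf)
        twice = normalize_by_maf_bins(once, maf)
        assert np.allclose(once, twice, atol=1e-12)

    def test_zero_variance_bin_names_bin(self):
        with pytest.raises(DegenerateInputError, match=r"\[0\.20, 0\.21\)"):
            normalize_by_maf_bins(np.ones(4), np.full(4, 0.205))


class TestFrequencyContrast:
    def test_identical_populations_degenerate_zeros(self):
        fm = toy_frequency_matrix([[0.2, 0.3, 0.4], [0.2, 0.3, 0.4]])
        values, degenerate = frequency_contrast(fm, "P0", "P1")
        assert degenerate
        assert np.allclose(values, 0.0)

    def test_matches_hand_computation(self):
        pa = np.array([0.30, 0.31, 0.33, 0.35, 0.38, 0.40])
        pb = np.array([0.28, 0.35, 0.30, 0.33, 0.42, 0.35])
        fm = toy_frequency_matrix(np.vstack([pa, pb]))
        mean_maf = np.minimum((pa + pb) / 2, 1 - (pa + pb) / 2)
        values, degenerate = frequency_contrast(fm, "P0", "P1", bin_width=0.5)
        raw = pa - pb
        expected = (raw - raw.mean()) / raw.std(ddof=1)
        assert not degenerate
        assert np.allclose(values, expected)

    def test_swapping_populations_negates(self):
        rng = np.random.default_rng(3)
        fm = toy_frequency_matrix(rng.uniform(0.2, 0.8, size=(2, 50)))
        v1, _ = frequency_contrast(fm, "P0", "P1", bin_width=0.5)
        v2, _ = frequency_contrast(fm, "P1", "P0", bin_width=0.5)
        assert np.allclose(v1, -v2)


class TestUnivariateLdsc:
    def test_null_statistic_gives_unit_intercept_zero_slope(self, sim_l2):
        fit = univariate_ldsc(np.ones_like(sim_l2), sim_l2)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)

    def test_single_step_fit_matches_statsmodels_wls(self, sim_l2):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        y = 1 + 0.004 * sim_l2 + rng.normal(0, 1, size=sim_l2.size)
        fit = LdScoreRegression(y, sim_l2, chi2_cutoff=None, n_blocks=50).fit()
        w = 1.0 / np.maximum(sim_l2, 1.0)
        ref = sm.WLS(y, sm.add_constant(sim_l2), weights=w).fit()
        assert fit.intercept == pytest.approx(ref.params[0], rel=1e-9)
        assert fit.slope == pytest.approx(ref.params[1], rel=1e-9)

    def test_recovers_planted_slope(self, sim_l2):
        rng = np.random.default_rng(5)
        c = 0.005
        cover = 0
        for _ in range(50):
            z = rng.normal(0, np.sqrt(1 + c * sim_l2))
            fit = univariate_ldsc(z**2, sim_l2)
            cover += abs(fit.slope - c) < 1.96 * fit.slope_se
        assert cover >= 42

    def test_uniform_inflation_moves_intercept_not_slope(self, sim_l2):
        rng = np.random.default_rng(6)
        z = rng.normal(0, np.sqrt(1 + 0.005 * sim_l2))
        f0 = univariate_ldsc(z**2, sim_l2)
        f1 = univariate_ldsc(z**2 + 0.3, sim_l2)
        assert f1.intercept - f0.intercept == pytest.approx(0.3, rel=0.1)
        assert abs(f1.slope - f0.slope) < 0.1 * 0.005

    def test_too_few_snps_for_blocks(self):
        from polyadapt.exceptions import ParameterError

        with pytest.raises(ParameterError):
            univariate_ldsc(np.ones(10), np.ones(10), n_blocks=20)


class TestBivariateLdsc:
    def test_independent_inputs_give_null_fit(self, sim_l2):
        rng = np.random.default_rng(7)
        fit = bivariate_ldsc(rng.normal(size=8000) * rng.normal(size=8000), sim_l2)
        assert abs(fit.slope) < 3 * fit.slope_se
        assert abs(fit.intercept) < 3 * fit.intercept_se

    def test_shared_structure_hits_intercept_not_slope(self, sim_l2):
        rng = np.random.default_rng(8)
        g = rng.normal(size=8000)
        s = np.sqrt(0.3)
        z1 = s * g + rng.normal(size=8000)
        z2 = s * g + rng.normal(size=8000)
        fit = bivariate_ldsc(z1 * z2, sim_l2)
        assert fit.intercept > 3 * fit.intercept_se  # structure signature
        assert abs(fit.slope) < 3 * fit.slope_se

    def test_structure_plus_ld_inflation_creates_slope(self, sim_l2):
        rng = np.random.default_rng(9)
        g = rng.normal(size=8000)
        v = np.sqrt(1 + 0.005 * sim_l2)
        z1 = v * (np.sqrt(0.3) * g + np.sqrt(0.7) * rng.normal(size=8000))
        z2 = v * (np.sqrt(0.3) * g + np.sqrt(0.7) * rng.normal(size=8000))
        fit = bivariate_ldsc(z1 * z2, sim_l2)
        assert fit.slope > 0
        assert fit.p_slope < 0.05

    def test_self_product_equals_univariate_without_cutoff(self, sim_l2):
        rng = np.random.default_rng(10)
        z = rng.normal(0, np.sqrt(1 + 0.004 * sim_l2))
        biv = bivariate_ldsc(z * z, sim_l2)
        uni = univariate_ldsc(z**2, sim_l2, chi2_cutoff=None)
        assert biv.slope == pytest.approx(uni.slope, rel=1e-12)
        assert biv.intercept == pytest.approx(uni.intercept, rel=1e-12)


class TestGeneticCorrelation:
    def test_self_correlation_is_exactly_one(self, sim_l2):
        rng = np.random.default_rng(11)
        z = np.sqrt(0.005 * sim_l2) * rng.normal(size=8000) + rng.normal(size=8000)
        res = genetic_correlation_from_arrays(z, z, sim_l2)
        assert res.rg == pytest.approx(1.0, abs=1e-6)

    def test_independent_traits_near_zero(self, sim_l2):
        rng = np.random.default_rng(12)
        z1 = np.sqrt(0.005 * sim_l2) * rng.normal(size=8000) + rng.normal(size=8000)
        z2 = np.sqrt(0.005 * sim_l2) * rng.normal(size=8000) + rng.normal(size=8000)
        res = genetic_correlation_from_arrays(z1, z2, sim_l2)
        assert abs(res.rg) < 2 * res.se + 0.05

    def test_recovers_planted_rg(self, sim_l2):
        rng = np.random.default_rng(13)
        rg_true = 0.8
        cover = 0
        for _ in range(30):
            g = rng.normal(size=8000)
            u1 = np.sqrt(rg_true) * g + np.sqrt(1 - rg_true) * rng.normal(size=8000)
            u2 = np.sqrt(rg_true) * g + np.sqrt(1 - rg_true) * rng.normal(size=8000)
            z1 = np.sqrt(0.005 * sim_l2) * u1 + rng.normal(size=8000)
            z2 = np.sqrt(0.005 * sim_l2) * u2 + rng.normal(size=8000)
            res = genetic_correlation_from_arrays(z1, z2, sim_l2)
            cover += abs(res.rg - rg_true) < 1.96 * res.se
        assert cover >= 24

    def test_nonpositive_heritability_slope_raises(self, sim_l2):
        rng = np.random.default_rng(14)
        z_null = rng.normal(size=8000) * 0.01  # essentially no LD-dependent signal
        y = 0.0001 - 0.00001 * sim_l2  # decreasing: negative slope
        with pytest.raises(UndefinedStatisticError):
            genetic_correlation_from_arrays(np.sqrt(np.maximum(y, 0)) + z_null, z_null + 1.0, sim_l2)


class TestMomentVsLdscore:
    def test_homoskedastic_input_has_no_slope(self, sim_l2):
        rng = np.random.default_rng(15)
        fit, bins = moment_vs_ldscore(rng.normal(size=8000) ** 2, sim_l2)
        assert abs(fit.slope) < 3 * fit.slope_se

    def test_recovers_variance_slope(self, sim_l2):
        rng = np.random.default_rng(16)
        c = 0.01
        y = rng.normal(0, np.sqrt(1 + c * sim_l2)) ** 2
        fit, _ = moment_vs_ldscore(y, sim_l2)
        assert fit.slope == pytest.approx(c, abs=3 * fit.slope_se)

    def test_bin_means_match_direct_recomputation(self, sim_l2):
        rng = np.random.default_rng(17)
        y = rng.normal(size=8000) ** 2
        _, bins = moment_vs_ldscore(y, sim_l2, n_bins=10)
        order = np.argsort(sim_l2, kind="mergesort")
        assert bins["n"].sum() == 8000
        start = 0
        for _, row in bins.iterrows():
            sel = order[start : start + int(row["n"])]
            assert row["mean_y"] == pytest.approx(y[sel].mean())
            start += int(row["n"])


class TestJackknifeScaling:
    def test_se_shrinks_with_sample_size(self):
        rng = np.random.default_rng(18)

        def fit_se(n):
            l2 = 1.0 + rng.gamma(2.0, 50.0, size=n)
            z = rng.normal(0, np.sqrt(1 + 0.005 * l2))
            return univariate_ldsc(z**2, l2, n_blocks=100).slope_se

        small = np.mean([fit_se(2000) for _ in range(10)])
        large = np.mean([fit_se(32000) for _ in range(10)])
        ratio = small / large
        assert ratio == pytest.approx(4.0, rel=0.45)  # 1/sqrt(n) scaling


class TestRegionMask:
    def test_default_regions_masked(self):
        regions = default_exclusion_regions()
        chrom = np.array(["6", "6", "2", "8", "1"])
        pos = np.array([30_000_000, 40_000_000, 135_000_000, 9_000_000, 1_000])
        keep = bed_mask(chrom, pos, regions)
        assert keep.tolist() == [False, True, False, False, True]
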
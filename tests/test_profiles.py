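"""Iso-gravitational profiles and profile statistics."""

import numpy as np
import pytest
import statsmodels.api as sm

from strainpet.profiles import (
    GravProfile,
    compare_regressions_F,
    fit_central_quartiles,
    group_profile,
    layer_profile,
    slope_z_test,
    suvr_vs_nongaseous_regression,
    wilcoxon_compare,
)


def _profile_from_means(means):
    means = np.asarray(means, dtype=float)
    return GravProfile(
        layer_mean=means,
        layer_se=np.zeros_like(means),
        layer_n=np.ones(means.size, dtype=int),
    )


class TestLayerProfile:
    def test_constant_map(self):
        vals = np.full((4, 200, 4), 3.3)
        mask = np.ones_like(vals, bool)
        prof = layer_profile(vals, mask, gravity_axis=1)
        assert prof.n_layers == 100
        np.testing.assert_allclose(prof.layer_mean, 3.3)
        np.testing.assert_allclose(prof.layer_se, 0.0, atol=1e-7)

    def test_linear_ramp_brute_force(self):
        """Layer means of a depth ramp equal brute-force bin averages."""
        n_g = 200
        vals = np.broadcast_to(
            np.arange(n_g, dtype=float).reshape(1, n_g, 1), (3, n_g, 2)
        ).copy()
        mask = np.ones_like(vals, bool)
        prof = layer_profile(vals, mask, gravity_axis=1, n_layers=100)
        # brute force: full extent, each layer holds planes [2i, 2i+1]
        expected = np.array([(2 * i + 2 * i + 1) / 2 for i in range(100)])
        np.testing.assert_allclose(prof.layer_mean, expected)
        # means are exactly linear in layer index
        diffs = np.diff(prof.layer_mean)
        np.testing.assert_allclose(diffs, diffs[0])

    def test_single_layer_is_whole_mask_mean(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(5, 30, 4))
        mask = rng.random(vals.shape) < 0.6
        prof = layer_profile(vals, mask, gravity_axis=1, n_layers=1)
        assert prof.layer_mean[0] == pytest.approx(vals[mask].mean())

    def test_bin_conservation(self):
        """Voxel-count-weighted mean of layer means = whole-mask mean."""
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(6, 77, 5))
        mask = rng.random(vals.shape) < 0.5
        prof = layer_profile(vals, mask, gravity_axis=1, n_layers=40)
        weighted = np.nansum(prof.layer_mean * prof.layer_n) / prof.layer_n.sum()
        assert weighted == pytest.approx(vals[mask].mean(), rel=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            layer_profile(np.zeros((3, 3, 3)), np.zeros((3, 3, 3), bool), 1)

    def test_empty_layers_flagged(self):
        vals = np.ones((1, 50, 1))
        mask = np.zeros_like(vals, bool)
        mask[0, :10, 0] = True
        mask[0, 40:, 0] = True  # gap in the middle of the extent
        with pytest.warns(UserWarning, match="empty"):
            prof = layer_profile(vals, mask, gravity_axis=1, n_layers=50)
        assert prof.empty_layers.size > 0
        assert np.isnan(prof.layer_mean[prof.empty_layers - 1]).all()

    def test_works_on_2d_slices(self):
        vals = np.tile(np.arange(100.0).reshape(100, 1), (1, 3))
        mask = np.ones_like(vals, bool)
        prof = layer_profile(vals, mask, gravity_axis=0, n_layers=100)
        np.testing.assert_allclose(prof.layer_mean, np.arange(100.0))


class TestGroupProfile:
    def test_identical_profiles_zero_se(self):
        p = _profile_from_means(np.linspace(0, 1, 100))
        g = group_profile([p, p, p])
        np.testing.assert_allclose(g.layer_se, 0.0, atol=1e-12)
        np.testing.assert_allclose(g.layer_mean, p.layer_mean)

    def test_two_profiles_hand_arithmetic(self):
        a = _profile_from_means(np.zeros(100))
        b = _profile_from_means(np.full(100, 2.0))
        g = group_profile([a, b])
        np.testing.assert_allclose(g.layer_mean, 1.0)
        np.testing.assert_allclose(g.layer_se, 1.0)  # SD sqrt(2) / sqrt(2)

    def test_single_profile_flagged(self):
        p = _profile_from_means(np.arange(100.0))
        with pytest.warns(UserWarning, match="single"):
            g = group_profile([p])
        np.testing.assert_allclose(g.layer_se, 0.0)

    def test_mismatched_layers_rejected(self):
        with pytest.raises(ValueError):
            group_profile([_profile_from_means(np.zeros(100)), _profile_from_means(np.zeros(50))])


class TestCentralQuartileFit:
    def test_exact_line(self):
        prof = _profile_from_means(2.0 * np.arange(1, 101) + 1.0)
        fit = fit_central_quartiles(prof)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.n == 51

    def test_constant_profile_convention(self):
        fit = fit_central_quartiles(_profile_from_means(np.full(100, 5.0)))
        assert fit.slope == 0.0
        assert fit.r_squared == 0.0

    def test_matches_statsmodels(self):
        """Closed-form OLS agrees with statsmodels to 1e-10."""
        rng = np.random.default_rng(2)
        means = 0.3 * np.arange(1, 101) + rng.normal(0, 2, 100)
        fit = fit_central_quartiles(_profile_from_means(means))
        x = np.arange(25, 76, dtype=float)
        res = sm.OLS(means[24:75], sm.add_constant(x)).fit()
        assert fit.slope == pytest.approx(res.params[1], rel=1e-10)
        assert fit.intercept == pytest.approx(res.params[0], rel=1e-10)
        assert fit.slope_se == pytest.approx(res.bse[1], rel=1e-10)
        assert fit.r_squared == pytest.approx(res.rsquared, rel=1e-10)

    def test_noisy_slope_recovery(self):
        rng = np.random.default_rng(3)
        beta = 0.7
        means = beta * np.arange(1, 101) + rng.normal(0, 0.5, 100)
        fit = fit_central_quartiles(_profile_from_means(means))
        assert abs(fit.slope - beta) < 3 * fit.slope_se


class TestCompareRegressionsF:
    def test_identical_groups(self):
        rng = np.random.default_rng(4)
        x = np.arange(25, 76, dtype=float)
        y = 2 * x + rng.normal(0, 1, x.size)
        res = compare_regressions_F(x, y, x, y)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0, abs=1e-10)
        assert res.df == (2, 2 * x.size - 4)

    def test_grossly_different_slopes(self):
        rng = np.random.default_rng(5)
        x = np.arange(25, 76, dtype=float)
        res = compare_regressions_F(
            x, 5 * x + rng.normal(0, 0.01, x.size), x, -5 * x + rng.normal(0, 0.01, x.size)
        )
        assert res.p_value < 1e-6

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            compare_regressions_F([1, 2], [1, 2], [1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            compare_regressions_F([1, 1, 1], [1, 2, 3], [1, 2, 3], [1, 2, 3])


class TestSlopeZ:
    def test_equal_slopes(self):
        res = slope_z_test(1.5, 0.2, 1.5, 0.3)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        """(2.0 - 1.5)/sqrt(0.01 + 0.01) = 3.5355."""
        res = slope_z_test(2.0, 0.1, 1.5, 0.1)
        assert res.statistic == pytest.approx(0.5 / 0.1414213562, rel=1e-6)
        assert res.p_value < 0.001

    def test_antisymmetry(self):
        a = slope_z_test(2.0, 0.1, 1.5, 0.1)
        b = slope_z_test(1.5, 0.1, 2.0, 0.1)
        assert a.statistic == -b.statistic
        assert a.p_value == b.p_value

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            slope_z_test(1.0, 0.0, 1.0, 0.1)


class TestSUVRvsNongaseous:
    def test_exact_proportionality(self):
        nongas = _profile_from_means(np.linspace(0.5, 3.5, 100))
        suvr = _profile_from_means(2.0 * nongas.layer_mean)
        fit = suvr_vs_nongaseous_regression(suvr, nongas)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope_through_origin == pytest.approx(2.0, abs=1e-12)

    def test_mismatched_layers_rejected(self):
        with pytest.raises(ValueError):
            suvr_vs_nongaseous_regression(
                _profile_from_means(np.zeros(100)), _profile_from_means(np.zeros(60))
            )


class TestWilcoxon:
    def test_identical_groups_unpaired(self):
        res = wilcoxon_compare([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert res.method == "rank-sum"
        assert res.p_value > 0.9

    def test_clearly_shifted_groups(self):
        """Complete separation at n=10 per group: exact rank-sum p is
        2/C(20,10) < 0.01."""
        a = list(range(1, 11))
        b = list(range(101, 111))
        res = wilcoxon_compare(a, b)
        assert res.p_value < 0.01
        # exact enumeration oracle: both one-sided extremes
        from math import comb

        assert res.p_value == pytest.approx(2.0 / comb(20, 10), rel=1e-9)

    def test_paired_all_zero_differences(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = wilcoxon_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
        assert res.degenerate
        assert res.p_value == 1.0

    def test_paired_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_compare([1, 2, 3], [1, 2], paired=True)

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_compare([1.0], [1.0, 2.0])
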
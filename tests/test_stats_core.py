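"""Circular tests, Mann-Whitney U, truncated-t noise and the reflected KDE."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from hydrataxis import (
    JumpDistanceKDE,
    NoiseDistribution,
    circ_cm_test,
    circ_median,
    fit_kde,
    fit_truncated_tls,
    mann_whitney_u,
    sample_kde,
    sample_noise,
)
from hydrataxis._angles import wrap_deg
from hydrataxis.exceptions import DegenerateDataError, FitError
from hydrataxis.stats_core import common_median_statistic, silverman_bandwidth


def grid_circ_median(angles, step=0.1):
    """Brute-force minimiser of the mean absolute circular deviation."""
    grid = np.arange(0.0, 360.0, step)
    diffs = np.abs(wrap_deg(np.subtract.outer(grid, np.asarray(angles, dtype=float))))
    return grid[np.argmin(diffs.mean(axis=1))]


class TestCircMedian:
    def test_symmetric_sample(self):
        assert circ_median([10, 20, 30]) == pytest.approx(20.0)

    def test_wrap_around(self):
        assert circ_median([350, 0, 10]) == pytest.approx(0.0)

    def test_matches_grid_search_on_von_mises(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            sample = np.degrees(rng.vonmises(math.radians(45.0), 2.0, size=7))
            ours = circ_median(sample)
            oracle = grid_circ_median(sample)
            assert abs(wrap_deg(ours - oracle)) <= 0.1 + 1e-9

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            circ_median([])

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(5)
        sample = rng.uniform(0, 360, 15)
        base = circ_median(sample)
        for rot in (13.0, 110.0, 250.0):
            assert abs(wrap_deg(circ_median(sample + rot) - (base + rot))) < 1e-6


class TestCommonMedianTest:
    def test_identical_symmetric_groups_give_zero_statistic(self):
        group = [-30.0, -20.0, -10.0, 10.0, 20.0, 30.0]
        res = circ_cm_test([group, group])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_hand_evaluated_counts(self):
        # m = (3, 7), n = (10, 10): statistic 3.2 by the closed form
        assert common_median_statistic([3, 7], [10, 10]) == pytest.approx(3.2)
        g1 = [-10.0] * 3 + [10.0] * 7
        g2 = [-10.0] * 7 + [10.0] * 3
        res = circ_cm_test([g1, g2])
        assert res.m == (3, 7)
        assert res.statistic == pytest.approx(3.2)
        assert res.pvalue == pytest.approx(stats.chi2.sf(3.2, 1))
        assert res.pvalue == pytest.approx(0.0736, abs=5e-4)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(6)
        groups = [rng.uniform(0, 360, 30), rng.vonmises(0.5, 1.0, 30) * 180 / np.pi]
        base = circ_cm_test(groups)
        rotated = circ_cm_test([g + 77.0 for g in groups])
        assert rotated.statistic == pytest.approx(base.statistic, abs=1e-9)

    def test_degenerate_one_sided_data(self):
        with pytest.raises(DegenerateDataError):
            common_median_statistic([0, 0], [10, 10])

    def test_small_groups_warn(self):
        with pytest.warns(UserWarning, match="fewer than 5"):
            circ_cm_test([[1.0, 2.0, 3.0, 50.0], [10.0, 20.0, 30.0, 40.0, 50.0]])


class TestMannWhitney:
    def test_disjoint_pairs(self):
        res = mann_whitney_u([1, 2], [3, 4], mode="exact")
        assert res.statistic == 0
        assert res.pvalue == pytest.approx(1 / 3)

    def test_disjoint_fives(self):
        res = mann_whitney_u([1, 2, 3, 4, 5], [6, 7, 8, 9, 10], mode="exact")
        assert res.statistic == 0
        assert res.pvalue == pytest.approx(2 / 252)

    def test_identical_samples_not_significant(self):
        x = list(range(20))
        res = mann_whitney_u(x, x, mode="normal")
        assert res.pvalue >= 0.99

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1, 9)
        base = mann_whitney_u(x, y)
        transformed = mann_whitney_u(np.exp(x), np.exp(y))
        assert transformed.statistic == base.statistic
        assert transformed.pvalue == pytest.approx(base.pvalue)


class TestTruncatedTls:
    def test_parameter_recovery(self):
        dist = NoiseDistribution(mu=0.0, sigma=10.0, nu=3.0)
        sample = sample_noise(dist, 5000, 9)
        fit = fit_truncated_tls(sample)
        assert fit.mu == pytest.approx(0.0, abs=1.0)
        assert fit.sigma == pytest.approx(10.0, rel=0.10)

    def test_degenerate_sample_is_fit_error(self):
        with pytest.raises(FitError):
            fit_truncated_tls(np.zeros(100))

    def test_normal_limit_total_variation(self):
        """Fitting t to truncated-normal data stays within TV 0.05 of truth."""
        rng = np.random.default_rng(10)
        raw = rng.normal(0.0, 10.0, 8000)
        sample = raw[np.abs(raw) <= 180.0]
        fit = fit_truncated_tls(sample)
        a, b = -180.0, 180.0
        z = stats.norm.cdf(b, 0, 10) - stats.norm.cdf(a, 0, 10)
        tv = 0.5 * integrate.quad(
            lambda x: abs(fit.pdf(np.array([x]))[0] - stats.norm.pdf(x, 0, 10) / z),
            a, b, limit=200,
        )[0]
        assert tv < 0.05

    def test_samples_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            fit_truncated_tls(np.linspace(-200, 0, 50))


class TestSampleNoise:
    def test_ks_against_analytic_cdf(self):
        dist = NoiseDistribution(mu=5.0, sigma=25.0, nu=4.0)
        draws = sample_noise(dist, 100_000, 11)
        assert draws.min() >= dist.lower and draws.max() <= dist.upper
        ks = stats.kstest(draws, lambda x: dist.cdf(x)).statistic
        assert ks < 0.01

    def test_tiny_scale_collapses_to_location(self):
        dist = NoiseDistribution(mu=42.0, sigma=1e-9, nu=5.0)
        draws = sample_noise(dist, 100, 12)
        np.testing.assert_allclose(draws, 42.0, atol=1e-6)

    def test_seed_determinism(self):
        dist = NoiseDistribution(mu=0.0, sigma=30.0, nu=5.0)
        np.testing.assert_array_equal(sample_noise(dist, 1000, 13), sample_noise(dist, 1000, 13))


class TestKde:
    def test_reflected_pdf_closed_form(self):
        kde = JumpDistanceKDE(data=np.array([1.0]), bandwidth=0.5)
        direct = stats.norm.pdf(0.0) / 0.5  # ~0.7979
        assert kde.pdf(np.array([1.0]))[0] == pytest.approx(direct * (1 + np.exp(-8.0)))

    def test_pdf_integrates_to_one(self):
        kde = fit_kde(np.array([1.0, 2.0, 3.5, 4.0, 8.0]))
        total, _ = integrate.quad(lambda x: kde.pdf(np.array([x]))[0], 0, 60, limit=300)
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_silverman_matches_textbook_formula(self):
        rng = np.random.default_rng(14)
        data = np.abs(rng.normal(0, 1, 100)) + 0.1
        sd = np.std(data, ddof=1)
        iqr = np.subtract(*np.percentile(data, [75, 25]))
        expected = 0.9 * min(sd, iqr / 1.34) * 100 ** (-0.2)
        assert silverman_bandwidth(data) == pytest.approx(expected)
        assert fit_kde(data).bandwidth == pytest.approx(expected)

    def test_nonpositive_datum_rejected(self):
        with pytest.raises(ValueError):
            fit_kde(np.array([1.0, 0.0, 2.0]))

    def test_sampler_ks_against_analytic_cdf(self):
        kde = fit_kde(np.array([2.0, 3.0, 4.5, 5.0, 6.5, 8.0]))
        draws = sample_kde(kde, 100_000, 15)
        assert draws.min() > 0
        ks = stats.kstest(draws, lambda x: kde.cdf(x)).statistic
        assert ks < 0.01

    def test_zero_bandwidth_limit_bootstraps_data(self):
        kde = JumpDistanceKDE(data=np.array([2.0, 5.0, 9.0]), bandwidth=1e-12)
        draws = sample_kde(kde, 500, 16)
        assert set(np.round(draws, 6)) <= {2.0, 5.0, 9.0}

    def test_point_mass_mean(self):
        kde = JumpDistanceKDE(data=np.full(4, 5.0), bandwidth=0.1)
        draws = sample_kde(kde, 100_000, 17)
        assert draws.mean() == pytest.approx(5.0, abs=0.01)
        assert kde.mean() == pytest.approx(5.0, abs=1e-6)

    def test_seed_determinism(self):
        kde = fit_kde(np.array([2.0, 3.0, 4.0]))
        np.testing.assert_array_equal(sample_kde(kde, 100, 18), sample_kde(kde, 100, 18))
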
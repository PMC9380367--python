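"""Error-rate estimators, intervals, the clustered GEE, and the trend fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mraqc.errors import (
    BoundaryEstimateWarning,
    DegenerateIntervalWarning,
    EstimationError,
    ValidationError,
)
from mraqc.stats import (
    ClusteredOutcomes,
    error_rate,
    errors_per_10k,
    gee_adjusted_rate,
    proportion_ci,
    rate_difference_test,
    trend_fit,
)


class TestErrorRate:
    @pytest.mark.parametrize(
        "k, n, percent_2dp",
        [
            (573, 18_843, 3.04),  # study total, populated-field
            (273, 10_425, 2.62),  # pharmacologic
            (300, 8_418, 3.56),   # non-pharmacologic
            (0, 100, 0.0),
        ],
    )
    def test_populated_field_rates(self, k, n, percent_2dp):
        assert round(100 * error_rate(k, n), 2) == percent_2dp

    def test_per_10k_scaling(self):
        assert round(errors_per_10k(573, 18_843)) == 304
        assert round(errors_per_10k(573, 48_880)) == 117
        assert errors_per_10k(500, 10_000) == 500  # the threshold phrasing
        assert errors_per_10k(0, 50) == 0

    def test_domain_errors(self):
        with pytest.raises(EstimationError):
            error_rate(1, 0)
        with pytest.raises(ValidationError):
            error_rate(5, 3)

    def test_same_numerator_smaller_denominator_larger_rate(self):
        assert error_rate(573, 18_843) > error_rate(573, 48_880)


class TestProportionCI:
    def test_wald_matches_closed_form(self):
        """Independent evaluation of p +/- z*sqrt(p(1-p)/n)."""
        k, n = 573, 18_843
        p = k / n
        z = sps.norm.ppf(0.975)
        half = z * np.sqrt(p * (1 - p) / n)
        lo, hi = proportion_ci(k, n, method="wald")
        assert lo == pytest.approx(p - half, abs=1e-12)
        assert hi == pytest.approx(p + half, abs=1e-12)
        assert (round(100 * lo, 2), round(100 * hi, 2)) == (2.80, 3.29)

    def test_wilson_matches_score_test_inversion(self):
        """Bisection on the score statistic reproduces the Wilson bounds."""
        k, n = 573, 18_843
        p_hat = k / n
        z = sps.norm.ppf(0.975)

        def score(p0):
            return (p_hat - p0) / np.sqrt(p0 * (1 - p0) / n)

        def invert(lo, hi, target):
            for _ in range(200):
                mid = (lo + hi) / 2
                if score(mid) > target:
                    lo = mid
                else:
                    hi = mid
            return (lo + hi) / 2

        lower = invert(1e-9, p_hat, z)
        upper = invert(p_hat, 0.5, -z)
        w_lo, w_hi = proportion_ci(k, n, method="wilson")
        assert w_lo == pytest.approx(lower, abs=1e-9)
        assert w_hi == pytest.approx(upper, abs=1e-9)

    def test_wilson_reproduces_published_populated_interval(self):
        lo, hi = proportion_ci(573, 18_843, method="wilson")
        assert (round(100 * lo, 2), round(100 * hi, 2)) == (2.81, 3.30)

    def test_degenerate_wald_warns(self):
        with pytest.warns(DegenerateIntervalWarning):
            lo, hi = proportion_ci(0, 100, method="wald")
        assert (lo, hi) == (0.0, 0.0)
        # wilson stays informative at the boundary
        lo, hi = proportion_ci(0, 100, method="wilson")
        assert 0.0 <= lo < hi < 1.0

    @settings(max_examples=40, deadline=None)
    @given(k=st.integers(1, 99), n=st.integers(100, 5000))
    def test_wilson_inside_unit_interval_and_brackets_estimate(self, k, n):
        lo, hi = proportion_ci(k, n, method="wilson")
        assert 0.0 <= lo <= k / n <= hi <= 1.0

    def test_width_shrinks_like_inverse_sqrt_n(self):
        widths = []
        for n in (100, 400, 1600):
            lo, hi = proportion_ci(int(0.2 * n), n, method="wald")
            widths.append(hi - lo)
        assert widths[0] / widths[1] == pytest.approx(2.0, rel=0.05)
        assert widths[1] / widths[2] == pytest.approx(2.0, rel=0.05)


class TestGEE:
    def test_singleton_clusters_reduce_to_crude_rate(self):
        """With one observation per cluster the GEE estimate is exactly k/n."""
        clusters = [(f"c{i}", int(i < 30), 1) for i in range(1000)]
        est = gee_adjusted_rate(ClusteredOutcomes(clusters))
        assert est.rate == pytest.approx(30 / 1000, abs=1e-10)
        assert est.ci_low < est.rate < est.ci_high
        assert est.method == "gee_adjusted"

    def test_matches_statsmodels_gee_on_bernoulli_rows(self):
        """Independent fit: statsmodels GEE over the expanded 0/1 outcomes."""
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        sizes = [40, 55, 70, 35, 60, 45]
        ks = [int(rng.binomial(n, rng.uniform(0.02, 0.10))) for n in sizes]
        est = gee_adjusted_rate(
            ClusteredOutcomes([(f"s{i}", k, n) for i, (k, n) in enumerate(zip(ks, sizes))])
        )
        y = np.concatenate([[1] * k + [0] * (n - k) for k, n in zip(ks, sizes)])
        groups = np.concatenate([[i] * n for i, n in enumerate(sizes)])
        model = sm.GEE(y, np.ones((len(y), 1)), groups=groups,
                       family=sm.families.Binomial(),
                       cov_struct=sm.cov_struct.Exchangeable())
        res = model.fit()
        mu_sm = float(1 / (1 + np.exp(-res.params[0])))
        # the two fits use slightly different moment conventions for the
        # working-correlation parameter, which perturbs the cluster weights
        assert est.rate == pytest.approx(mu_sm, rel=0.02)
        # robust standard error on the logit scale
        se_logit = float(np.log(est.ci_high / (1 - est.ci_high))
                         - np.log(est.rate / (1 - est.rate))) / sps.norm.ppf(0.975)
        assert se_logit == pytest.approx(float(res.bse[0]), rel=0.15)

    def test_no_clustering_converges_to_binomial(self):
        """Equal clusters, common rate: estimate ~ crude, robust SE ~ binomial SE."""
        rng = np.random.default_rng(11)
        m, size, p = 200, 50, 0.03
        ks = rng.binomial(size, p, m)
        est = gee_adjusted_rate(
            ClusteredOutcomes([(f"s{i}", int(k), size) for i, k in enumerate(ks)])
        )
        crude = ks.sum() / (m * size)
        assert est.rate == pytest.approx(crude, abs=1e-9)
        binom_half = sps.norm.ppf(0.975) * np.sqrt(crude * (1 - crude) / (m * size))
        assert (est.ci_high - est.ci_low) / 2 == pytest.approx(binom_half, rel=0.15)

    def test_interval_asymmetric_on_proportion_scale(self):
        rng = np.random.default_rng(3)
        ks = rng.binomial(300, rng.beta(3, 97, 20))
        est = gee_adjusted_rate(
            ClusteredOutcomes([(f"s{i}", int(k), 300) for i, k in enumerate(ks)])
        )
        assert (est.ci_high - est.rate) > (est.rate - est.ci_low)

    def test_boundary_outcomes_warn_with_fallback_interval(self):
        with pytest.warns(BoundaryEstimateWarning):
            est = gee_adjusted_rate(
                ClusteredOutcomes([(f"s{i}", 0, 50) for i in range(5)])
            )
        assert est.rate == 0.0
        assert 0.0 < est.ci_high < 1.0

    def test_invalid_clusters_rejected(self):
        with pytest.raises(ValidationError):
            ClusteredOutcomes([])
        with pytest.raises(ValidationError):
            ClusteredOutcomes([("a", 5, 3)])


class TestRateDifference:
    def test_case_type_contrast(self):
        """NP minus P populated-field difference: 0.95 pp, strongly significant."""
        d = rate_difference_test(300, 8_418, 273, 10_425)
        assert d.delta == pytest.approx(0.95, abs=0.005)
        assert d.p == pytest.approx(0.0002, abs=5e-5)

    def test_all_field_contrast(self):
        d = rate_difference_test(300, 22_360, 273, 26_520)
        assert d.delta == pytest.approx(0.31, abs=0.005)
        assert d.p < 0.05

    def test_identical_groups(self):
        d = rate_difference_test(10, 100, 10, 100)
        assert d.delta == 0.0 and d.p == 1.0

    @pytest.mark.parametrize("k1, n1, k2, n2", [(8, 60, 3, 55), (12, 90, 5, 80)])
    def test_agrees_with_exact_enumeration(self, k1, n1, k2, n2):
        """Small-count z test sits near the Fisher exact-enumeration p-value."""
        d = rate_difference_test(k1, n1, k2, n2)
        _, p_exact = sps.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]])
        assert abs(d.p - p_exact) < 0.08  # within normal-approximation error

    def test_degenerate_denominator(self):
        with pytest.raises(Exception):
            rate_difference_test(1, 0, 1, 10)


class TestTrendFit:
    def test_exact_linear_recovery(self):
        fit = trend_fit([(1, 5.0), (2, 4.5), (3, 4.0)])
        assert fit.slope == pytest.approx(-0.5, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_rates(self):
        fit = trend_fit([(1, 3.0), (2, 3.0), (3, 3.0), (4, 3.0)])
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == 0.0

    def test_shift_invariance_and_scaling(self):
        pts = [(1, 5.2), (2, 4.1), (3, 4.4), (4, 3.0), (5, 2.9)]
        base = trend_fit(pts)
        shifted = trend_fit([(e, r + 7.0) for e, r in pts])
        scaled = trend_fit([(e, 3.0 * r) for e, r in pts])
        assert shifted.slope == pytest.approx(base.slope, abs=1e-10)
        assert scaled.slope == pytest.approx(3.0 * base.slope, rel=1e-10)

    def test_ci_brackets_slope_and_matches_scipy(self):
        pts = [(e, r) for e, r in zip(range(1, 8), (5.5, 4.9, 4.2, 4.4, 3.1, 3.3, 2.4))]
        fit = trend_fit(pts)
        lr = sps.linregress([e for e, _ in pts], [r for _, r in pts])
        assert fit.slope == pytest.approx(lr.slope)
        assert fit.p == pytest.approx(lr.pvalue)
        assert fit.slope_ci_low < fit.slope < fit.slope_ci_high

    def test_insufficient_or_singular_input(self):
        with pytest.raises(EstimationError):
            trend_fit([(1, 5.0), (2, 4.0)])
        with pytest.raises(EstimationError):
            trend_fit([(1, 5.0), (1, 4.0), (1, 3.0)])
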
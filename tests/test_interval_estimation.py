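"""Interval constructions vs quantile arithmetic; resampling-engine contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from helpers import quantile_linear
from predinc import (
    BinaryDesign,
    BootstrapDistribution,
    MeasureEstimate,
    MeasureSpec,
    ModelSpec,
    UnusableDistributionError,
    asymptotic_ci,
    bc_ci,
    bca_ci,
    bootstrap_resample,
    bootstrap_t_ci,
    generate_binary_cohort,
    hybrid_ci,
    percentile_ci,
)


def make_dist(estimates, point, point_se=None, inner_ses=None, b=None):
    estimates = np.asarray(estimates, dtype=float)
    return BootstrapDistribution(
        measure="toy",
        point_estimate=point,
        estimates=estimates,
        point_se=point_se,
        inner_ses=None if inner_ses is None else np.asarray(inner_ses, dtype=float),
        b_requested=len(estimates) if b is None else b,
    )


class TestAsymptotic:
    def test_standard_normal_quantile(self):
        iv = asymptotic_ci(MeasureEstimate("idi", 0.0, se=1.0), alpha=0.025)
        assert iv.lower == pytest.approx(-1.959964, abs=1e-5)
        assert iv.upper == pytest.approx(1.959964, abs=1e-5)

    def test_zero_se_gives_point_interval(self):
        iv = asymptotic_ci(MeasureEstimate("idi", 0.4, se=0.0), alpha=0.025)
        assert iv.lower == iv.upper == 0.4 and iv.width == 0.0

    def test_missing_se_rejected(self):
        with pytest.raises(ValueError):
            asymptotic_ci(MeasureEstimate("delta_c", 0.1, se=None))

    def test_known_variance_normal_mean_coverage(self):
        # harness self-test: exact 95% coverage for the N(0,1) mean with
        # known variance, 10^4 Monte-Carlo repeats
        rng = np.random.default_rng(77)
        reps, n = 10_000, 50
        means = rng.standard_normal((reps, n)).mean(axis=1)
        half = norm.ppf(0.975) / np.sqrt(n)
        cover = np.mean(np.abs(means) <= half)
        assert abs(cover - 0.95) < 3 * np.sqrt(0.95 * 0.05 / reps)


class TestPercentile:
    def test_frozen_quantile_values(self):
        # replicates 1..1000; type-7 positions 1 + 0.025*999 = 25.975 and
        # 1 + 0.975*999 = 975.025, so the interpolated endpoints equal them
        iv = percentile_ci(make_dist(np.arange(1.0, 1001.0), 500.0), alpha=0.025)
        assert iv.lower == pytest.approx(25.975, abs=1e-9)
        assert iv.upper == pytest.approx(975.025, abs=1e-9)

    def test_matches_independent_quantile_arithmetic(self, rng):
        est = rng.standard_normal(400)
        iv = percentile_ci(make_dist(est, 0.0), alpha=0.05)
        assert iv.lower == pytest.approx(quantile_linear(est, 0.05), abs=1e-12)
        assert iv.upper == pytest.approx(quantile_linear(est, 0.95), abs=1e-12)

    def test_constant_replicates_zero_width(self):
        iv = percentile_ci(make_dist(np.full(200, 1.5), 1.5))
        assert iv.width == 0.0

    def test_monotone_transform_equivariance(self, rng):
        est = rng.random(500) + 0.5
        a = percentile_ci(make_dist(est, 1.0))
        b = percentile_ci(make_dist(np.log(est), 0.0))
        assert np.exp(b.lower) == pytest.approx(a.lower, rel=1e-3)
        assert np.exp(b.upper) == pytest.approx(a.upper, rel=1e-3)

    def test_unusable_distribution_rejected(self):
        with pytest.raises(UnusableDistributionError):
            percentile_ci(make_dist(np.arange(50.0), 25.0))  # < 100 valid
        with pytest.raises(UnusableDistributionError):
            percentile_ci(make_dist(np.arange(180.0), 90.0, b=200))  # 90% valid


class TestBC:
    def test_reduces_to_percentile_at_zero_median_bias(self, rng):
        est = rng.standard_normal(1000)
        point = float(np.median(est))  # exactly half the replicates below
        a = bc_ci(make_dist(est, point))
        b = percentile_ci(make_dist(est, point))
        assert a.lower == pytest.approx(b.lower, abs=1e-12)
        assert a.upper == pytest.approx(b.upper, abs=1e-12)

    def test_skewed_distribution_matches_hand_adjustment(self, rng):
        est = np.sort(rng.gamma(2.0, 1.0, 500))
        point = float(np.quantile(est, 0.4))  # ~40% of replicates below
        iv = bc_ci(make_dist(est, point), alpha=0.025)
        frac = np.mean(est < point)
        z0 = norm.ppf(frac)
        lv = norm.cdf(2 * z0 + norm.ppf([0.025, 0.975]))
        assert iv.lower == pytest.approx(quantile_linear(est, lv[0]), abs=1e-12)
        assert iv.upper == pytest.approx(quantile_linear(est, lv[1]), abs=1e-12)

    def test_one_sided_distribution_rejected(self):
        with pytest.raises(UnusableDistributionError):
            bc_ci(make_dist(np.arange(1.0, 201.0), 0.0))  # all replicates above


class TestBCa:
    def test_reduces_to_percentile_when_uncorrected(self, rng):
        est = rng.standard_normal(1000)
        point = float(np.median(est))
        jack = np.r_[np.linspace(-1, 1, 50)]  # symmetric: acceleration a = 0
        a = bca_ci(make_dist(est, point), jack)
        b = percentile_ci(make_dist(est, point))
        assert a.lower == pytest.approx(b.lower, abs=1e-12)
        assert a.upper == pytest.approx(b.upper, abs=1e-12)

    def test_endpoints_match_hand_arithmetic(self, rng):
        est = np.sort(rng.gamma(2.0, 1.0, 400))
        point = float(np.quantile(est, 0.45))
        jack = rng.gamma(2.0, 0.1, 60)
        iv = bca_ci(make_dist(est, point), jack, alpha=0.025)
        z0 = norm.ppf(np.mean(est < point))
        dev = jack.mean() - jack
        a = np.sum(dev**3) / (6.0 * np.sum(dev**2) ** 1.5)
        z = norm.ppf([0.025, 0.975])
        lv = norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))
        assert iv.lower == pytest.approx(quantile_linear(est, lv[0]), abs=1e-12)
        assert iv.upper == pytest.approx(quantile_linear(est, lv[1]), abs=1e-12)

    def test_degenerate_jackknife_rejected(self, rng):
        est = rng.standard_normal(300)
        with pytest.raises(UnusableDistributionError):
            bca_ci(make_dist(est, float(np.median(est))), np.full(20, 0.3))


class TestBootstrapT:
    def test_symmetric_pivots_give_symmetric_interval(self):
        piv = np.r_[np.linspace(-2, 2, 201)]
        est = 0.5 + piv * 0.1
        iv = bootstrap_t_ci(make_dist(est, 0.5, point_se=0.1, inner_ses=np.full(201, 0.1)))
        assert iv.upper - 0.5 == pytest.approx(0.5 - iv.lower, abs=1e-12)

    def test_matches_hand_pivot_arithmetic(self, rng):
        b = 250
        est = rng.gamma(3.0, 0.1, b)
        ses = rng.uniform(0.05, 0.15, b)
        point, point_se = 0.3, 0.09
        iv = bootstrap_t_ci(make_dist(est, point, point_se=point_se, inner_ses=ses),
                            alpha=0.025)
        t = (est - point) / ses
        assert iv.lower == pytest.approx(point - quantile_linear(t, 0.975) * point_se,
                                         abs=1e-12)
        assert iv.upper == pytest.approx(point - quantile_linear(t, 0.025) * point_se,
                                         abs=1e-12)

    def test_zero_inner_ses_skipped_and_policed(self, rng):
        b = 200
        est = rng.standard_normal(b)
        ses = np.full(b, 0.1)
        ses[:20] = 0.0  # 10% unusable -> below the 95% validity floor
        with pytest.raises(UnusableDistributionError):
            bootstrap_t_ci(make_dist(est, 0.0, point_se=0.1, inner_ses=ses))

    def test_studentized_gaussian_mean_benchmark(self):
        # textbook case: bootstrap-t for the mean of n=50 gaussians is close
        # to nominal; checked via the exact pivot distribution analogue
        rng = np.random.default_rng(5)
        reps, n, b = 400, 50, 199
        cover = 0
        for _ in range(reps):
            x = rng.standard_normal(n)
            idx = rng.integers(0, n, (b, n))
            bs = x[idx]
            est = bs.mean(axis=1)
            ses = bs.std(axis=1, ddof=1) / np.sqrt(n)
            d = make_dist(est, float(x.mean()),
                          point_se=float(x.std(ddof=1) / np.sqrt(n)), inner_ses=ses)
            iv = bootstrap_t_ci(d)
            cover += iv.lower <= 0.0 <= iv.upper
        assert abs(cover / reps - 0.95) < 0.04


class TestHybrid:
    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_reflection_identity_holds_exactly(self, seed):
        rng = np.random.default_rng(seed)
        est = rng.gamma(2.0, 1.0, 300)
        point = float(rng.random() * 3)
        h = hybrid_ci(make_dist(est, point))
        p = percentile_ci(make_dist(est, point))
        assert h.lower == pytest.approx(2 * point - p.upper, abs=1e-12)
        assert h.upper == pytest.approx(2 * point - p.lower, abs=1e-12)
        assert h.lower <= h.upper

    def test_symmetric_distribution_matches_percentile(self, rng):
        est = np.r_[np.linspace(-1, 1, 501)] + 0.3
        h = hybrid_ci(make_dist(est, 0.3))
        p = percentile_ci(make_dist(est, 0.3))
        assert h.lower == pytest.approx(p.lower, abs=1e-9)
        assert h.upper == pytest.approx(p.upper, abs=1e-9)

    def test_right_skew_shifts_interval_left(self, rng):
        est = rng.gamma(1.5, 1.0, 1000)
        point = float(np.median(est))
        h = hybrid_ci(make_dist(est, point))
        p = percentile_ci(make_dist(est, point))
        assert h.lower < p.lower and h.upper < p.upper


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_all_methods_produce_ordered_endpoints(seed):
    rng = np.random.default_rng(seed)
    est = rng.gamma(2.0, 1.0, 300)
    point = float(np.quantile(est, rng.uniform(0.2, 0.8)))
    jack = rng.gamma(2.0, 0.2, 40)
    dists = make_dist(est, point, point_se=0.2, inner_ses=rng.uniform(0.1, 0.3, 300))
    for fn in (percentile_ci, bc_ci, hybrid_ci, bootstrap_t_ci,
               lambda d, alpha=0.025: bca_ci(d, jack, alpha)):
        iv = fn(dists)
        assert iv.lower <= iv.upper


@pytest.fixture(scope="module")
def cohort():
    return generate_binary_cohort(BinaryDesign(event_rate=0.3, n=250), seed=19)


class TestResamplingEngine:
    def test_deterministic_given_seed(self, cohort):
        ms = ModelSpec("binary", (0,), (0, 4))
        a = bootstrap_resample(cohort, ms, MeasureSpec("idi"), B=120, seed=5)
        b = bootstrap_resample(cohort, ms, MeasureSpec("idi"), B=120, seed=5)
        assert np.array_equal(a.estimates, b.estimates)
        c = bootstrap_resample(cohort, ms, MeasureSpec("idi"), B=120, seed=6)
        assert not np.array_equal(a.estimates, c.estimates)

    def test_degenerate_measure_constant_replicates(self, cohort):
        ms = ModelSpec("binary", (0,), (0,))  # expanded == standard
        d = bootstrap_resample(cohort, ms, MeasureSpec("idi"), B=120, seed=5)
        assert np.all(d.estimates == 0.0)

    def test_replicate_mean_near_point_estimate(self, cohort):
        ms = ModelSpec("binary", (0,), (0, 4))
        d = bootstrap_resample(cohort, ms, MeasureSpec("idi"), B=400, seed=7)
        boot_se = d.estimates.std(ddof=1)
        assert abs(d.estimates.mean() - d.point_estimate) < 3 * boot_se

    def test_rare_events_make_distribution_unusable(self):
        # 2 events among 40: many resamples lose all events and are skipped
        rng = np.random.default_rng(3)
        from predinc import CohortData

        y = np.zeros(40, dtype=np.int8)
        y[:2] = 1
        c = CohortData(y=y, x=rng.standard_normal((40, 5)))
        d = bootstrap_resample(c, ModelSpec("binary", (0,), (0, 1)),
                               MeasureSpec("idi"), B=150, seed=2)
        assert d.b_valid < d.b_requested
        assert d.failure_log
        if not d.usable:
            with pytest.raises(UnusableDistributionError):
                percentile_ci(d)

    def test_stratified_resampling_preserves_class_sizes(self, cohort):
        ms = ModelSpec("binary", (0,), (0, 4))
        d = bootstrap_resample(cohort, ms, MeasureSpec("idi"), B=120, seed=5,
                               stratified=True)
        # no single-class failures possible under stratification
        assert d.b_valid == d.b_requested

    def test_multi_measure_shares_resamples(self, cohort):
        ms = ModelSpec("binary", (0,), (0, 4))
        both = bootstrap_resample(
            cohort, ms, [MeasureSpec("idi"), MeasureSpec("delta_auc")], B=120, seed=5
        )
        solo = bootstrap_resample(cohort, ms, MeasureSpec("idi"), B=120, seed=5)
        assert np.array_equal(both["idi"].estimates, solo.estimates)

    def test_small_b_rejected(self, cohort):
        with pytest.raises(ValueError):
            bootstrap_resample(cohort, ModelSpec("binary", (0,), (0, 4)),
                               MeasureSpec("idi"), B=50, seed=1)
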
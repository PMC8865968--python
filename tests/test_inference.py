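import math

import numpy as np
import pytest
from scipy import stats

from powerhazard import (
    CensoringScheme,
    GammaPrior,
    PHFDParams,
    ProgCensSample,
    TestSpec,
    assess,
    bayes_alpha,
    bayes_c,
    build_scheme,
    c_index,
    gamma_constants,
    log_likelihood,
    lower_bound_bayes,
    lower_bound_bayes_exact,
    lower_bound_ml,
    mle_alpha,
    mle_c,
    posterior_params,
    sample_progressive,
    suff_stats,
)

BETA = 0.332


class TestGammaPrior:
    def test_positive_required(self):
        with pytest.raises(ValueError):
            GammaPrior(0.0, 1.0)
        with pytest.raises(ValueError):
            GammaPrior(1.0, -1.0)

    def test_improper_limit_allowed(self):
        p = GammaPrior(0.0, 0.0, improper=True)
        assert p.a == 0.0 and p.b == 0.0


class TestSuffStats:
    def test_bearing_statistics(self, bearings):
        s = suff_stats(bearings, BETA)
        assert s.w == pytest.approx(20.2589747909, abs=1e-8)
        assert s.m == 18
        assert s.w_prime == pytest.approx(s.w / (BETA + 1), rel=1e-14)

    def test_complete_sample_beta_zero(self):
        scheme = CensoringScheme(n=4, removals=(0,) * 4)
        sample = ProgCensSample(scheme=scheme, times=(0.5, 1.0, 1.5, 3.0))
        assert suff_stats(sample, 0.0).w == pytest.approx(6.0)

    def test_prior_shifts_w_prime(self, bearings):
        s0 = suff_stats(bearings, BETA)
        s1 = suff_stats(bearings, BETA, GammaPrior(0.5, 0.001))
        assert s1.w_prime == pytest.approx(s0.w_prime + 0.001, rel=1e-12)


class TestLogLikelihood:
    def test_stationary_at_mle(self, bearings):
        a_hat = mle_alpha(bearings, BETA)
        h = 1e-6
        deriv = (
            log_likelihood(a_hat + h, BETA, bearings)
            - log_likelihood(a_hat - h, BETA, bearings)
        ) / (2 * h)
        assert deriv == pytest.approx(0.0, abs=1e-6)
        # strictly below the maximum away from it
        assert log_likelihood(a_hat, BETA, bearings) > log_likelihood(
            2 * a_hat, BETA, bearings
        )

    def test_concavity(self, bearings):
        a_hat = mle_alpha(bearings, BETA)
        h = 1e-4
        second = (
            log_likelihood(a_hat + h, BETA, bearings)
            - 2 * log_likelihood(a_hat, BETA, bearings)
            + log_likelihood(a_hat - h, BETA, bearings)
        ) / h**2
        assert second == pytest.approx(-bearings.m / a_hat**2, rel=1e-4)

    def test_exponential_closed_form(self):
        scheme = CensoringScheme(n=3, removals=(0, 0, 0))
        sample = ProgCensSample(scheme=scheme, times=(0.4, 1.2, 2.0))
        alpha = 1.7
        expected = 3 * math.log(alpha) - alpha * 3.6
        assert log_likelihood(alpha, 0.0, sample) == pytest.approx(expected, rel=1e-12)

    def test_ordering_constant(self):
        # n=4, m=2, R=(1,1): factors 4 and 4-1-1=2
        scheme = CensoringScheme(n=4, removals=(1, 1))
        sample = ProgCensSample(scheme=scheme, times=(0.5, 1.0))
        gap = log_likelihood(1.0, 0.0, sample, include_constant=True) - log_likelihood(
            1.0, 0.0, sample
        )
        assert gap == pytest.approx(math.log(8), rel=1e-12)

    def test_rejects_nonpositive_alpha(self, bearings):
        with pytest.raises(ValueError):
            log_likelihood(0.0, BETA, bearings)


class TestMLE:
    def test_bearing_alpha(self, bearings):
        assert round(mle_alpha(bearings, BETA), 4) == 1.1835

    def test_exponential_complete_sample(self):
        scheme = CensoringScheme(n=4, removals=(0,) * 4)
        sample = ProgCensSample(scheme=scheme, times=(0.5, 1.0, 1.5, 3.0))
        assert mle_alpha(sample, 0.0) == pytest.approx(4 / 6.0, rel=1e-14)

    def test_consistency_large_sample(self):
        true = PHFDParams(1.092, 0.332)
        scheme = CensoringScheme(n=20_000, removals=(0,) * 20_000)
        sample = sample_progressive(scheme, true, 3)
        assert mle_alpha(sample, true.beta) == pytest.approx(true.alpha, rel=0.02)

    def test_c_invariance(self, bearings):
        # index MLE = index at plugged-in scale MLE
        for l_x in (0.1, 0.4411, 0.9):
            plug = c_index(PHFDParams(mle_alpha(bearings, BETA), BETA), l_x)
            assert mle_c(bearings, BETA, l_x) == pytest.approx(plug, rel=1e-13)

    def test_c_at_zero_limit(self, bearings):
        mc = gamma_constants(BETA)
        assert mle_c(bearings, BETA, 0.0) == pytest.approx(mc.ratio, rel=1e-13)

    def test_c_reference_value(self, bearings):
        # oracle: (gamma1 - (18/20.2589747909)**(1/1.332) * 0.4411) / gamma2
        assert mle_c(bearings, BETA, 0.4411) == pytest.approx(0.7397792889, abs=1e-8)


class TestPosterior:
    def test_grid_oracle_total_variation(self, toy_sample):
        prior = GammaPrior(1.5, 0.8)
        post = posterior_params(toy_sample, BETA, prior)
        s = suff_stats(toy_sample, BETA)
        grid = np.linspace(1e-9, post.mean + 14 / math.sqrt(post.rate), 40_001)
        log_unnorm = (
            (toy_sample.m + prior.a - 1) * np.log(grid)
            - grid * (prior.b + s.w / (BETA + 1))
        )
        dens = np.exp(log_unnorm - log_unnorm.max())
        dens /= np.trapezoid(dens, grid)
        gamma_pdf = stats.gamma.pdf(grid, post.shape, scale=1 / post.rate)
        tv = 0.5 * np.trapezoid(np.abs(dens - gamma_pdf), grid)
        assert tv < 1e-4

    def test_improper_limit(self, toy_sample):
        post = posterior_params(toy_sample, BETA, GammaPrior(0, 0, improper=True))
        s = suff_stats(toy_sample, BETA)
        assert post.shape == toy_sample.m
        assert post.rate == pytest.approx(s.w / (BETA + 1), rel=1e-14)

    def test_pivot_is_chi_square_posterior(self, toy_sample):
        # 2*alpha*W' under the posterior is chi2(2(m+a))
        prior = GammaPrior(1.0, 2.0)
        post = posterior_params(toy_sample, BETA, prior)
        rng = np.random.default_rng(4)
        draws = rng.gamma(post.shape, 1 / post.rate, size=50_000)
        assert stats.kstest(
            2 * draws * post.rate, "chi2", args=(2 * (toy_sample.m + prior.a),)
        ).pvalue > 0.01


class TestBayesEstimators:
    def test_alpha_improper_limit_equals_mle(self, bearings):
        prior = GammaPrior(0, 0, improper=True)
        assert bayes_alpha(bearings, BETA, prior) == pytest.approx(
            mle_alpha(bearings, BETA), rel=1e-14
        )

    def test_alpha_weak_prior_reference(self, bearings):
        assert bayes_alpha(bearings, BETA, GammaPrior(0.001, 0.001)) == pytest.approx(
            1.1834634217, abs=1e-8
        )

    def test_alpha_matches_grid_posterior_mean(self, toy_sample):
        prior = GammaPrior(1.5, 0.8)
        post = posterior_params(toy_sample, BETA, prior)
        grid = np.linspace(1e-9, post.mean + 14 / math.sqrt(post.rate), 40_001)
        dens = stats.gamma.pdf(grid, post.shape, scale=1 / post.rate)
        grid_mean = np.trapezoid(grid * dens, grid)
        assert bayes_alpha(toy_sample, BETA, prior) == pytest.approx(
            grid_mean, abs=1e-5
        )

    def test_c_at_zero_limit(self, bearings):
        mc = gamma_constants(BETA)
        assert bayes_c(bearings, BETA, 0.0, GammaPrior(1, 2)) == pytest.approx(
            mc.ratio, rel=1e-13
        )

    def test_c_matches_posterior_sampling(self, toy_sample):
        prior = GammaPrior(1.0, 2.0)
        l_x = 0.5
        post = posterior_params(toy_sample, BETA, prior)
        rng = np.random.default_rng(12)
        draws = rng.gamma(post.shape, 1 / post.rate, size=20_000)
        vals = np.array([c_index(PHFDParams(a, BETA), l_x) for a in draws])
        se = vals.std() / math.sqrt(len(vals))
        assert abs(bayes_c(toy_sample, BETA, l_x, prior) - vals.mean()) < 3 * se

    def test_gap_to_mle_vanishes_with_m(self):
        # the Gamma(m+p)/(Gamma(m) m^p) factor -> 1 as m grows
        true = PHFDParams(1.092, 0.332)
        prior = GammaPrior(0, 0, improper=True)
        gaps = []
        for n in (10, 1000):
            scheme = CensoringScheme(n=n, removals=(0,) * n)
            sample = sample_progressive(scheme, true, 17)
            gaps.append(
                abs(
                    bayes_c(sample, BETA, 0.5, prior) - mle_c(sample, BETA, 0.5)
                )
            )
        assert gaps[1] < gaps[0] / 10


class TestLowerBoundML:
    def test_reported_reference_value(self):
        # the published rewrite; its printed reference truncates the 4th
        # decimal (formula value 0.920181)
        bound = lower_bound_ml(0.9382, 18, BETA, 0.05, convention="reported")
        assert bound == pytest.approx(0.92018136, abs=1e-7)
        assert abs(bound - 0.9201) < 1e-4

    def test_pivotal_below_reported_for_positive_beta(self):
        # the exact bound is more conservative when beta > 0
        reported = lower_bound_ml(0.9382, 18, BETA, 0.05, convention="reported")
        pivotal = lower_bound_ml(0.9382, 18, BETA, 0.05)
        assert pivotal < reported

    def test_conventions_coincide_at_beta_zero(self):
        a = lower_bound_ml(0.7, 12, 0.0, 0.05, convention="pivotal")
        b = lower_bound_ml(0.7, 12, 0.0, 0.05, convention="reported")
        assert a == pytest.approx(b, rel=1e-14)

    def test_unknown_convention(self):
        with pytest.raises(ValueError, match="convention"):
            lower_bound_ml(0.9, 18, BETA, 0.05, convention="exactish")

    def test_degenerate_gap(self):
        mc = gamma_constants(BETA)
        for convention in ("pivotal", "reported"):
            assert lower_bound_ml(
                mc.ratio, 18, BETA, 0.05, convention=convention
            ) == pytest.approx(mc.ratio, rel=1e-12)

    def test_direct_pivotal_form_agrees(self, bearings):
        c_hat = mle_c(bearings, BETA, 0.4411)
        for convention in ("pivotal", "reported"):
            lower_bound_ml(
                c_hat, 18, BETA, 0.05, sample=bearings, l_x=0.4411,
                convention=convention,
            )

    def test_bound_below_estimate(self):
        assert lower_bound_ml(0.9382, 18, BETA, 0.05) < 0.9382

    def test_coverage_is_exact(self):
        true = PHFDParams(1.092, 0.332)
        l_x = 0.022
        c_true = c_index(true, l_x)
        for kind, (n, m) in (("I", (25, 15)), ("III", (50, 30))):
            scheme = build_scheme(kind, n, m)
            reps = 2000
            hits = 0
            for r in range(reps):
                s = sample_progressive(scheme, true, (55, kind == "I", r))
                hits += lower_bound_ml(mle_c(s, BETA, l_x), m, BETA, 0.05) <= c_true
            se = math.sqrt(0.95 * 0.05 / reps)
            assert abs(hits / reps - 0.95) < 3 * se


class TestLowerBoundBayes:
    def test_reference_value(self):
        assert round(lower_bound_bayes(0.9427, 18, 1.0, BETA, 0.05), 4) == 0.9274

    def test_degenerate_gap(self):
        mc = gamma_constants(BETA)
        assert lower_bound_bayes(mc.ratio, 18, 1.0, BETA, 0.05) == pytest.approx(
            mc.ratio, rel=1e-12
        )

    def test_fractional_degrees_of_freedom(self):
        lo = lower_bound_bayes(0.9, 18, 0.5, BETA, 0.05)
        assert np.isfinite(lo) and lo < 0.9

    def test_equals_exact_bound_at_beta_zero(self):
        # at beta = 0 the gamma-ratio in the point estimate is exactly m+a
        # and the rewrite collapses onto the exact posterior quantile
        true = PHFDParams(1.5, 0.0)
        prior = GammaPrior(1.0, 2.0)
        l_x, delta = 0.1, 0.05
        scheme = CensoringScheme(n=12, removals=(0,) * 12)
        sample = sample_progressive(scheme, true, 23)
        approx = lower_bound_bayes(
            bayes_c(sample, 0.0, l_x, prior), sample.m, prior.a, 0.0, delta
        )
        exact = lower_bound_bayes_exact(sample, 0.0, l_x, prior, delta)
        assert approx == pytest.approx(exact, rel=1e-12)

    def test_sits_above_exact_bound_for_positive_beta(self, bearings):
        # the rewrite's subtracted term shrinks by ~(beta+1)^(-1/(beta+1)),
        # so its bound is systematically higher (anti-conservative)
        prior = GammaPrior(1.0, 2.0)
        l_x, delta = 0.4411, 0.05
        approx = lower_bound_bayes(
            bayes_c(bearings, BETA, l_x, prior), bearings.m, prior.a, BETA, delta
        )
        exact = lower_bound_bayes_exact(bearings, BETA, l_x, prior, delta)
        assert approx > exact


class TestLowerBoundBayesExact:
    def test_posterior_quantile_calibration(self, toy_sample):
        prior = GammaPrior(1.0, 2.0)
        l_x, delta = 0.5, 0.05
        bound = lower_bound_bayes_exact(toy_sample, BETA, l_x, prior, delta)
        post = posterior_params(toy_sample, BETA, prior)
        rng = np.random.default_rng(31)
        draws = rng.gamma(post.shape, 1 / post.rate, size=50_000)
        frac = np.mean(
            [c_index(PHFDParams(a, BETA), l_x) >= bound for a in draws]
        )
        assert abs(frac - 0.95) < 0.003

    def test_delta_to_one_limit(self, toy_sample):
        # as delta -> 1 the chi-square percentile -> 0 and the bound climbs
        # monotonically to gamma1/gamma2
        mc = gamma_constants(BETA)
        prior = GammaPrior(1, 2)
        bounds = [
            lower_bound_bayes_exact(toy_sample, BETA, 0.5, prior, d)
            for d in (0.5, 0.99, 1 - 1e-12)
        ]
        assert bounds[0] < bounds[1] < bounds[2] < mc.ratio
        assert bounds[2] == pytest.approx(mc.ratio, abs=1e-2)

    def test_improper_limit_equals_ml_bound(self, bearings):
        prior = GammaPrior(0, 0, improper=True)
        l_x, delta = 0.4411, 0.05
        exact = lower_bound_bayes_exact(bearings, BETA, l_x, prior, delta)
        ml = lower_bound_ml(mle_c(bearings, BETA, l_x), bearings.m, BETA, delta)
        assert exact == pytest.approx(ml, rel=1e-12)

    def test_prior_predictive_calibration(self):
        # draw the scale from the prior, data given the scale: the bound
        # covers the realised index in 95% of replicates
        prior = GammaPrior(2.0, 3.0)
        scheme = build_scheme("II", 20, 12)
        l_x, delta = 0.1, 0.05
        reps, hits = 2000, 0
        for r in range(reps):
            rng = np.random.default_rng((77, r))
            alpha = rng.gamma(prior.a, 1 / prior.b)
            true = PHFDParams(alpha, BETA)
            sample = sample_progressive(scheme, true, rng)
            bound = lower_bound_bayes_exact(sample, BETA, l_x, prior, delta)
            hits += c_index(true, l_x) >= bound
        se = math.sqrt(0.95 * 0.05 / reps)
        assert abs(hits / reps - 0.95) < 3 * se


class TestAssess:
    def test_reference_bayes_decision(self, bearings):
        spec = TestSpec(l_x=0.4411, c=0.90, delta=0.05)
        result = assess(
            bearings, BETA, spec, method="bayes", prior=GammaPrior(1.0, 2.0),
            c_hat=0.9427, convention="reported",
        )
        assert round(result.lower_bound, 4) == 0.9274
        assert result.reject_h0
        assert result.level == pytest.approx(0.95)

    def test_reference_ml_decision(self, bearings):
        spec = TestSpec(l_x=0.4411, c=0.90, delta=0.05)
        result = assess(
            bearings, BETA, spec, method="ml", c_hat=0.9382, convention="reported"
        )
        assert abs(result.lower_bound - 0.9201) < 1e-4
        assert result.reject_h0

    def test_no_rejection_above_bound(self, bearings):
        spec = TestSpec(l_x=0.4411, c=1.2, delta=0.05)
        assert not assess(bearings, BETA, spec, method="ml", c_hat=0.9382).reject_h0

    def test_boundary_not_rejected(self, bearings):
        bound = assess(
            bearings, BETA, TestSpec(l_x=0.4411, c=0.5, delta=0.05),
            method="ml", c_hat=0.9382,
        ).lower_bound
        at_boundary = assess(
            bearings, BETA, TestSpec(l_x=0.4411, c=bound, delta=0.05),
            method="ml", c_hat=0.9382,
        )
        assert not at_boundary.reject_h0

    def test_bayes_requires_prior(self, bearings):
        with pytest.raises(ValueError, match="prior"):
            assess(bearings, BETA, TestSpec(0.4411, 0.9, 0.05), method="bayes")

    def test_unknown_method(self, bearings):
        with pytest.raises(ValueError, match="method"):
            assess(bearings, BETA, TestSpec(0.4411, 0.9, 0.05), method="map")

    def test_type_one_error_at_boundary(self):
        # true index exactly at the required level: rejection rate <= delta
        true = PHFDParams(1.092, 0.332)
        c = 0.9
        from powerhazard import l_x_from_c

        l_x = l_x_from_c(true, c)
        scheme = build_scheme("I", 25, 15)
        spec = TestSpec(l_x=l_x, c=c, delta=0.05)
        reps, rejections = 2000, 0
        for r in range(reps):
            sample = sample_progressive(scheme, true, (91, r))
            rejections += assess(sample, BETA, spec, method="ml").reject_h0
        se = math.sqrt(0.05 * 0.95 / reps)
        assert rejections / reps <= 0.05 + 3 * se
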
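import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ebpi import (
    DataError,
    EffectPanel,
    PriorEstimate,
    compute_posterior,
    confidence_intervals,
    efficiency_gain,
    estimate_prior,
    expected_coverage_count,
    minimum_panel_size,
    prediction_intervals,
)
from ebpi.errors import DegeneratePriorWarning, SmallPanelWarning

Z95 = 1.959963984540054


class TestEstimatePrior:
    def test_worked_example(self, worked_panel):
        prior = estimate_prior(worked_panel, warn=False)
        assert prior.mu_hat == pytest.approx(1.0)
        # E[S^2] = tau2 + mean sigma^2 under independence: 1 - 0.5 = 0.5
        assert prior.tau2_hat == pytest.approx(0.5)
        assert not prior.truncated

    def test_equal_betas_truncate(self):
        panel = EffectPanel(
            labels=list("abcd"), beta=np.full(4, 0.7), se=np.full(4, 0.3)
        )
        with pytest.warns(DegeneratePriorWarning):
            prior = estimate_prior(panel)
        assert prior.tau2_hat == 0.0
        assert prior.truncated

    def test_k_below_two_errors(self):
        panel = EffectPanel(labels=["a"], beta=[0.1], se=[0.2])
        with pytest.raises(DataError):
            estimate_prior(panel)

    def test_small_panel_warning(self):
        # mean se^2 / tau2 well above 0.5 needs K >= 100
        panel = EffectPanel(
            labels=list("abc"), beta=[0.0, 2.0, 4.0], se=np.full(3, 1.0)
        )
        with pytest.warns(SmallPanelWarning):
            estimate_prior(panel)

    def test_covariance_correction_hand_computed(self):
        beta = np.array([0.0, 1.0, 2.0])
        se = np.sqrt([0.5, 0.5, 0.5])
        cov = np.full((3, 3), 0.2)
        np.fill_diagonal(cov, 0.5)
        panel = EffectPanel(labels=list("abc"), beta=beta, se=se, cov=cov)
        prior = estimate_prior(panel, warn=False)
        # S^2 = 1; correction = 2 * (3 * 0.2) / (3 * 2) = 0.2
        assert prior.tau2_hat == pytest.approx(1.0 - 0.5 + 0.2)

    def test_diagonal_cov_equals_independent(self, random_panel):
        indep = estimate_prior(random_panel, warn=False)
        with_cov = EffectPanel(
            labels=random_panel.labels,
            beta=random_panel.beta,
            se=random_panel.se,
            cov=np.diag(random_panel.var),
        )
        assert estimate_prior(with_cov, warn=False).tau2_hat == pytest.approx(
            indep.tau2_hat
        )

    def test_parameter_recovery(self, rng):
        # tau2 = 1, sigma_i^2 ~ U[0.25, 0.75], K = 1000, 500 panels
        k, reps = 1000, 500
        estimates = np.empty(reps)
        for r in range(reps):
            se2 = rng.uniform(0.25, 0.75, size=k)
            beta = rng.normal(0, 1, size=k) + rng.normal(0, np.sqrt(se2))
            panel = EffectPanel(
                labels=[str(i) for i in range(k)], beta=beta, se=np.sqrt(se2)
            )
            estimates[r] = estimate_prior(panel, warn=False).tau2_hat
        assert abs(estimates.mean() - 1.0) < 0.05

    def test_bias_shrinks_with_k(self, rng):
        biases = []
        for k in (50, 200, 1000):
            reps = 400
            vals = np.empty(reps)
            for r in range(reps):
                se2 = rng.uniform(0.25, 0.75, size=k)
                beta = rng.normal(0, 1, size=k) + rng.normal(0, np.sqrt(se2))
                panel = EffectPanel(
                    labels=[str(i) for i in range(k)], beta=beta, se=np.sqrt(se2)
                )
                vals[r] = estimate_prior(panel, warn=False).tau2_hat
            biases.append(abs(vals.mean() - 1.0))
        assert biases[-1] < 0.05  # consistent at large K


class TestComputePosterior:
    def test_equal_weight_closed_form(self, worked_panel):
        prior = PriorEstimate(mu_hat=1.0, tau2_hat=0.5, k=3)
        post = compute_posterior(worked_panel, prior)
        assert post.post_mean[2] == pytest.approx(1.5)
        assert post.post_var[2] == pytest.approx(0.25)

    def test_complete_shrinkage_limit(self, worked_panel):
        prior = PriorEstimate(mu_hat=1.0, tau2_hat=0.0, k=3)
        post = compute_posterior(worked_panel, prior)
        np.testing.assert_allclose(post.post_mean, 1.0)
        np.testing.assert_allclose(post.post_var, 0.0)

    def test_no_shrinkage_limit(self, worked_panel):
        prior = PriorEstimate(mu_hat=1.0, tau2_hat=1e12, k=3)
        post = compute_posterior(worked_panel, prior)
        np.testing.assert_allclose(post.post_mean, worked_panel.beta, atol=1e-9)
        np.testing.assert_allclose(post.post_var, worked_panel.var, rtol=1e-9)

    def test_equal_precision_midpoint(self):
        panel = EffectPanel(labels=["a", "b"], beta=[2.0, 0.0], se=[0.7, 0.7])
        prior = PriorEstimate(mu_hat=0.5, tau2_hat=0.49, k=2)
        post = compute_posterior(panel, prior)
        assert post.post_mean[0] == pytest.approx((2.0 + 0.5) / 2)

    def test_posterior_invariants(self, random_panel):
        prior = estimate_prior(random_panel, warn=False)
        post = compute_posterior(random_panel, prior)
        assert np.all(
            post.post_var <= np.minimum(prior.tau2_hat, random_panel.var) + 1e-12
        )
        lo = np.minimum(random_panel.beta, prior.mu_hat)
        hi = np.maximum(random_panel.beta, prior.mu_hat)
        assert np.all(post.post_mean >= lo - 1e-12)
        assert np.all(post.post_mean <= hi + 1e-12)

    def test_shrinkage_ordering(self, random_panel):
        prior = estimate_prior(random_panel, warn=False)
        post = compute_posterior(random_panel, prior)
        assert np.all(
            np.abs(post.post_mean - prior.mu_hat)
            <= np.abs(random_panel.beta - prior.mu_hat) + 1e-12
        )


class TestIntervals:
    def test_pi_normal_quantile_arithmetic(self):
        panel = EffectPanel(labels=["a", "b"], beta=[1.0, 2.0], se=[1.0, 1.0])
        prior = PriorEstimate(mu_hat=1.0, tau2_hat=0.5, k=2)
        post = compute_posterior(panel, prior)
        # factor b: E* = 1.5 (weights 2:1 for beta... recompute): V*=(2+1)^-1
        pis = prediction_intervals(post, 0.95)
        i = 1
        np.testing.assert_allclose(
            [pis.lower[i], pis.upper[i]],
            [
                post.post_mean[i] - Z95 * math.sqrt(post.post_var[i]),
                post.post_mean[i] + Z95 * math.sqrt(post.post_var[i]),
            ],
        )

    def test_pi_worked_numbers(self):
        post_mean, post_var = 1.5, 0.25
        panel = EffectPanel(labels=["x"] * 2, beta=[2.0, 0.0], se=np.sqrt([0.5, 0.5]))
        prior = PriorEstimate(mu_hat=1.0, tau2_hat=0.5, k=2)
        post = compute_posterior(panel, prior)
        assert post.post_mean[0] == pytest.approx(post_mean)
        pis = prediction_intervals(post, 0.95)
        assert pis.lower[0] == pytest.approx(post_mean - Z95 * 0.5, abs=1e-9)
        assert pis.upper[0] == pytest.approx(post_mean + Z95 * 0.5, abs=1e-9)
        assert pis.lower[0] == pytest.approx(0.52, abs=0.01)
        assert pis.upper[0] == pytest.approx(2.48, abs=0.01)

    def test_zero_width_at_complete_shrinkage(self, worked_panel):
        prior = PriorEstimate(mu_hat=1.0, tau2_hat=0.0, k=3)
        pis = prediction_intervals(compute_posterior(worked_panel, prior))
        np.testing.assert_allclose(pis.lower, 1.0)
        np.testing.assert_allclose(pis.upper, 1.0)

    def test_level_nesting(self, random_panel):
        prior = estimate_prior(random_panel, warn=False)
        post = compute_posterior(random_panel, prior)
        p95 = prediction_intervals(post, 0.95)
        p99 = prediction_intervals(post, 0.99)
        assert np.all(p99.lower < p95.lower)
        assert np.all(p99.upper > p95.upper)

    def test_ci_trivial(self):
        panel = EffectPanel(labels=["a"], beta=[0.0], se=[1.0])
        cis = confidence_intervals(panel, 0.95)
        assert cis.lower[0] == pytest.approx(-1.96, abs=1e-3)
        assert cis.upper[0] == pytest.approx(1.96, abs=1e-3)

    def test_ci_from_2x2_example(self):
        panel = EffectPanel(labels=["a"], beta=[1.3863], se=[0.5477])
        cis = confidence_intervals(panel, 0.95)
        assert cis.lower[0] == pytest.approx(0.313, abs=1e-3)
        assert cis.upper[0] == pytest.approx(2.460, abs=1e-3)

    def test_pi_never_longer_than_ci(self, random_panel):
        prior = estimate_prior(random_panel, warn=False)
        post = compute_posterior(random_panel, prior)
        pis = prediction_intervals(post, 0.95)
        cis = confidence_intervals(random_panel, 0.95)
        assert np.all(pis.length <= cis.length + 1e-12)

    def test_significance_flags(self):
        panel = EffectPanel(
            labels=list("abc"), beta=[3.0, 0.0, -3.0], se=[0.1, 0.1, 0.1]
        )
        cis = confidence_intervals(panel, 0.95)
        np.testing.assert_array_equal(cis.significant, [True, False, True])

    def test_bad_level(self, random_panel):
        with pytest.raises(DataError):
            confidence_intervals(random_panel, 1.0)


class TestEfficiencyGain:
    @pytest.mark.parametrize(
        "sigma2_mean,tau2,expected_pct",
        [(0.5, 0.25, 200.0), (0.5, 0.5, 100.0), (0.25, 0.5, 50.0),
         (0.25, 1.0, 25.0), (0.125, 1.0, 12.5)],
    )
    def test_diagonal_values(self, sigma2_mean, tau2, expected_pct):
        k = 100
        se2 = np.linspace(0.5 * sigma2_mean, 1.5 * sigma2_mean, k)  # mean exact
        panel = EffectPanel(
            labels=[str(i) for i in range(k)],
            beta=np.zeros(k),
            se=np.sqrt(se2),
        )
        prior = PriorEstimate(mu_hat=0.0, tau2_hat=tau2, k=k)
        _, avg = efficiency_gain(panel, prior)
        assert avg * 100 == pytest.approx(expected_pct)

    def test_consistency_with_posterior(self, random_panel):
        prior = estimate_prior(random_panel, warn=False)
        post = compute_posterior(random_panel, prior)
        gains, _ = efficiency_gain(random_panel, prior)
        np.testing.assert_allclose(random_panel.var / post.post_var, 1.0 + gains)

    def test_vanishing_se(self):
        panel = EffectPanel(labels=["a", "b"], beta=[0.0, 1.0], se=[1e-6, 1e-6])
        prior = PriorEstimate(mu_hat=0.5, tau2_hat=1.0, k=2)
        gains, avg = efficiency_gain(panel, prior)
        assert avg < 1e-11

    def test_degenerate_prior_warns_infinite(self, worked_panel):
        prior = PriorEstimate(mu_hat=1.0, tau2_hat=0.0, k=3)
        with pytest.warns(DegeneratePriorWarning):
            gains, avg = efficiency_gain(worked_panel, prior)
        assert math.isinf(avg)


class TestExpectedCoverageCount:
    def _pis(self, k, level=0.95):
        panel = EffectPanel(
            labels=[str(i) for i in range(k)],
            beta=np.full(k, 5.0),
            se=np.full(k, 0.1),
        )
        prior = PriorEstimate(mu_hat=5.0, tau2_hat=1.0, k=k)
        return prediction_intervals(compute_posterior(panel, prior), level)

    def test_ten_significant(self):
        pis = self._pis(10)
        assert pis.significant.all()
        assert expected_coverage_count(pis, pis.significant) == pytest.approx(9.5)

    def test_level_one_limit(self):
        pis = self._pis(7, level=0.999999)
        assert expected_coverage_count(pis) == pytest.approx(7.0, abs=1e-4)

    def test_66_at_95(self):
        assert expected_coverage_count(self._pis(66)) == pytest.approx(62.7)

    def test_rejects_cis(self):
        panel = EffectPanel(labels=["a", "b"], beta=[0.0, 1.0], se=[1.0, 1.0])
        with pytest.raises(DataError):
            expected_coverage_count(confidence_intervals(panel))


class TestMinimumPanelSize:
    @pytest.mark.parametrize(
        "ratio,expected",
        [(0.1, 20), (0.125, 20), (0.2, 30), (0.25, 30), (0.4, 50), (0.5, 50),
         (0.6, 100), (2.0, 100)],
    )
    def test_buckets(self, ratio, expected):
        assert minimum_panel_size(ratio) == expected

    def test_nonpositive_ratio(self):
        with pytest.raises(DataError):
            minimum_panel_size(0.0)


@given(shift=st.floats(min_value=-10, max_value=10, allow_nan=False))
@settings(max_examples=25, deadline=None)
def test_location_shift_equivariance(shift):
    rng = np.random.default_rng(7)
    k = 30
    se = np.sqrt(rng.uniform(0.25, 0.75, size=k))
    beta = rng.normal(0, 1, size=k)
    labels = [str(i) for i in range(k)]
    base = EffectPanel(labels=labels, beta=beta, se=se)
    moved = EffectPanel(labels=labels, beta=beta + shift, se=se)
    p0 = estimate_prior(base, warn=False)
    p1 = estimate_prior(moved, warn=False)
    assert p1.mu_hat == pytest.approx(p0.mu_hat + shift, abs=1e-9)
    assert p1.tau2_hat == pytest.approx(p0.tau2_hat, abs=1e-9)
    post0 = compute_posterior(base, p0)
    post1 = compute_posterior(moved, p1)
    np.testing.assert_allclose(post1.post_mean, post0.post_mean + shift, atol=1e-9)
    np.testing.assert_allclose(post1.post_var, post0.post_var, atol=1e-12)
    pi0 = prediction_intervals(post0)
    pi1 = prediction_intervals(post1)
    np.testing.assert_allclose(pi1.lower, pi0.lower + shift, atol=1e-9)
    np.testing.assert_allclose(pi1.upper, pi0.upper + shift, atol=1e-9)
    g0 = efficiency_gain(base, p0)[1]
    g1 = efficiency_gain(moved, p1)[1]
    assert g1 == pytest.approx(g0, abs=1e-12)
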
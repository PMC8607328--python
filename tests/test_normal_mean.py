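"""Normal-mean SSD: conjugate update, closed forms, searches, Monte Carlo path."""

import math

import numpy as np
import pytest
from scipy import stats

from bayes_ssd import (NormalDataSummary, NormalGammaPrior, PrecisionSpec,
                       n_mean_acc_closed, n_mean_criterion, n_mean_frequentist)
from bayes_ssd.normal_mean import (average_coverage_fully_bayes,
                                   average_coverage_fully_bayes_quadrature,
                                   average_length_fully_bayes,
                                   average_length_mixed, posterior_mu,
                                   worst_length_fully_bayes, worst_length_mixed)


def spec(criterion, approach, lmax=0.2, alpha=0.05, worst_level=0.8):
    return PrecisionSpec(lmax=lmax, alpha=alpha, criterion=criterion,
                         approach=approach, worst_level=worst_level)


EG_PRIOR = NormalGammaPrior(mu0=0.24, n0=0.0, a=16.0, b=11.2)   # variance 0.70, cv 0.25


class TestPosterior:
    def test_no_data_returns_prior_marginal(self):
        prior = NormalGammaPrior(mu0=-0.06, n0=38.0, a=16.0, b=6.56)
        post = posterior_mu(prior, NormalDataSummary(0, 0.0, 0.0))
        assert post.df == 2 * prior.a
        assert post.loc == prior.mu0
        assert post.scale == pytest.approx(math.sqrt(prior.b / (prior.a * prior.n0)))
        # prior predictive spread quoted for the densest-sampled district
        assert post.scale == pytest.approx(0.103, abs=1e-3)

    def test_conjugate_update_against_numeric_bayes(self):
        """Fine-grid numerical Bayes on (mu, lambda) must reproduce the scaled-t posterior."""
        prior = NormalGammaPrior(mu0=0.5, n0=3.0, a=4.0, b=2.0)
        data = NormalDataSummary(n=7, xbar=0.9, ss=3.1)
        post = posterior_mu(prior, data)
        t_post = stats.t(post.df, loc=post.loc, scale=post.scale)

        mu = np.linspace(post.loc - 6 * post.scale, post.loc + 6 * post.scale, 321)
        lam_hi = stats.gamma.ppf(1 - 1e-12, prior.a + (data.n + 1) / 2, scale=1 / prior.b) * 3
        lam = np.linspace(1e-9, lam_hi, 30001)
        k = prior.a + (data.n + 1) / 2  # gamma + normal-prior + likelihood powers of lambda
        r = (prior.b + prior.n0 * (mu[:, None] - prior.mu0) ** 2 / 2
             + data.ss / 2 + data.n * (data.xbar - mu[:, None]) ** 2 / 2)
        log_integrand = (k - 1) * np.log(lam[None, :]) - r * lam[None, :]
        log_integrand -= log_integrand.max()
        dens = np.trapezoid(np.exp(log_integrand), lam, axis=1)
        dens /= np.trapezoid(dens, mu)
        # normalise the reference on the same grid so tail truncation cancels
        ref = t_post.pdf(mu)
        ref /= np.trapezoid(ref, mu)
        assert np.max(np.abs(dens - ref)) < 1e-5 * t_post.pdf(post.loc)

    def test_undefined_posterior(self):
        prior = NormalGammaPrior(mu0=0.0, n0=0.0, a=2.0, b=1.0)
        with pytest.raises(ValueError):
            posterior_mu(prior, NormalDataSummary(0, 0.0, 0.0))


class TestACCClosedForm:
    def test_known_precision_limit_matches_frequentist(self):
        # nearly degenerate precision prior at sigma = 1: t quantile -> normal
        a = 1e6
        prior = NormalGammaPrior(mu0=0.0, n0=0.0, a=a, b=a)
        res = n_mean_acc_closed(prior, spec("acc", "fully_bayesian"))
        n_freq = n_mean_frequentist(1.0, spec("frequentist", "frequentist"))
        assert abs(res.n - n_freq) <= 1

    def test_large_prior_sample_clamps_to_zero(self):
        prior = NormalGammaPrior(mu0=0.0, n0=10_000.0, a=16.0, b=11.2)
        assert n_mean_acc_closed(prior, spec("acc", "fully_bayesian")).n == 0

    def test_prior_sample_size_shifts_requirement_exactly(self):
        base = n_mean_acc_closed(EG_PRIOR, spec("acc", "fully_bayesian")).n
        shifted = n_mean_acc_closed(
            NormalGammaPrior(mu0=0.24, n0=10.0, a=16.0, b=11.2),
            spec("acc", "fully_bayesian")).n
        assert base - shifted == 10

    def test_agrees_with_preposterior_quadrature(self):
        """The closed form and direct quadrature over the sum-of-squares
        preposterior are the same criterion: coverages match pointwise and
        the threshold n is identical."""
        sp = spec("acc", "fully_bayesian")
        n_closed = n_mean_acc_closed(EG_PRIOR, sp).n
        for n in (50, n_closed - 1, n_closed, n_closed + 25):
            exact = average_coverage_fully_bayes(n, EG_PRIOR, sp.lmax)
            quad = average_coverage_fully_bayes_quadrature(n, EG_PRIOR, sp.lmax)
            assert exact == pytest.approx(quad, abs=1e-7)
        assert average_coverage_fully_bayes_quadrature(n_closed, EG_PRIOR, sp.lmax) >= 0.95
        assert average_coverage_fully_bayes_quadrature(n_closed - 1, EG_PRIOR, sp.lmax) < 0.95


class TestCriterionSearch:
    def test_expert_precision_prior_alc(self):
        prior = NormalGammaPrior(mu0=0.24, n0=0.0, a=94.0, b=68.0)
        assert n_mean_criterion(prior, spec("alc", "fully_bayesian")).n == 281
        assert n_mean_criterion(prior, spec("alc", "mixed")).n == 283

    @pytest.mark.parametrize("a,b", [(16.0, 11.2), (94.0, 68.0), (25.0, 30.0)])
    def test_mixed_exceeds_fully_bayesian_by_at_most_two(self, a, b):
        """A flat mean prior is worth about one observation."""
        prior = NormalGammaPrior(mu0=0.0, n0=0.0, a=a, b=b)
        n_fb = n_mean_criterion(prior, spec("alc", "fully_bayesian")).n
        n_mbl = n_mean_criterion(prior, spec("alc", "mixed")).n
        assert 0 <= n_mbl - n_fb <= 2

    def test_worst_level_brackets_alc(self):
        for prior in (EG_PRIOR, NormalGammaPrior(0.0, 0.0, 94.0, 68.0)):
            n_alc = n_mean_criterion(prior, spec("alc", "fully_bayesian")).n
            n_w50 = n_mean_criterion(prior, spec("woc", "fully_bayesian", worst_level=0.5)).n
            n_w80 = n_mean_criterion(prior, spec("woc", "fully_bayesian", worst_level=0.8)).n
            assert n_w50 <= n_alc <= n_w80

    def test_minimality_all_deterministic_paths(self):
        checks = {
            ("alc", "fully_bayesian"): lambda n, sp: average_length_fully_bayes(n, EG_PRIOR, sp.alpha) <= sp.lmax,
            ("alc", "mixed"): lambda n, sp: average_length_mixed(n, EG_PRIOR, sp.alpha) <= sp.lmax,
            ("acc", "fully_bayesian"): lambda n, sp: average_coverage_fully_bayes(n, EG_PRIOR, sp.lmax) >= 1 - sp.alpha,
            ("woc", "fully_bayesian"): lambda n, sp: worst_length_fully_bayes(n, EG_PRIOR, sp.alpha, sp.worst_level) <= sp.lmax,
            ("woc", "mixed"): lambda n, sp: worst_length_mixed(n, EG_PRIOR, sp.alpha, sp.worst_level) <= sp.lmax,
        }
        for (crit, appr), satisfied in checks.items():
            sp = spec(crit, appr)
            n = n_mean_criterion(EG_PRIOR, sp).n
            assert satisfied(n, sp)
            assert not satisfied(n - 1, sp)

    def test_sharp_prior_limit_approaches_frequentist(self):
        """As the precision prior tightens (cv -> 0), ALC converges to the
        frequentist sample size."""
        sigma2 = 0.70
        n_freq = n_mean_frequentist(math.sqrt(sigma2), spec("frequentist", "frequentist"))
        gaps = []
        for cv in (0.25, 0.1, 0.02):
            a = 1.0 / cv**2
            prior = NormalGammaPrior(mu0=0.0, n0=0.0, a=a, b=a * sigma2)
            gaps.append(n_mean_criterion(prior, spec("alc", "fully_bayesian")).n - n_freq)
        assert gaps[0] > gaps[-1]
        assert gaps[-1] <= 1

    def test_diffuse_precision_prior_rejected(self):
        prior = NormalGammaPrior(mu0=0.0, n0=0.0, a=0.4, b=1.0)
        with pytest.raises(ValueError):
            n_mean_criterion(prior, spec("alc", "fully_bayesian"))


class TestMonteCarloPath:
    PRIOR = NormalGammaPrior(mu0=0.0, n0=5.0, a=16.0, b=11.2)

    def test_informative_mean_prior_reduces_n(self):
        """With n0 prior observations the ALC sample size drops by about n0."""
        res = n_mean_criterion(self.PRIOR, spec("alc", "fully_bayesian"),
                               draws=20_000, seed=3)
        n_flat = n_mean_criterion(EG_PRIOR, spec("alc", "fully_bayesian")).n
        assert res.mc_error > 0
        assert abs((res.n + 5) - n_flat) <= 2

    def test_reproducible_given_seed(self):
        r1 = n_mean_criterion(self.PRIOR, spec("alc", "fully_bayesian"),
                              draws=5_000, seed=11)
        r2 = n_mean_criterion(self.PRIOR, spec("alc", "fully_bayesian"),
                              draws=5_000, seed=11)
        assert r1 == r2

    def test_seed_required(self):
        with pytest.raises(ValueError):
            n_mean_criterion(self.PRIOR, spec("woc", "fully_bayesian"), seed=None)
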
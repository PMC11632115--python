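"""BCPNN information component and MGPS gamma-Poisson shrinkage."""

import math

import numpy as np
import pytest
from scipy import special, stats

from pvsignal.disproportionality import ContingencyTable
from pvsignal.empirical_bayes import (GammaMixturePrior, bcpnn_ic,
                                      fit_mgps_prior, mgps_score,
                                      mgps_score_from_counts,
                                      posterior_mixture_cdf,
                                      prior_log_likelihood)

NEAR_ONE = 1 - 1e-12


class TestBcpnn:
    def test_independence_limit(self):
        # observed equals expected at large counts -> IC ~ 0
        t = ContingencyTable(1000, 9000, 9000, 81000)
        r = bcpnn_ic(t)
        assert abs(r.ic) < 0.01
        assert r.ic025 == pytest.approx(r.ic - 2 * r.ic_sd)
        assert r.ic025 < r.ic

    def test_doubled_rate_gives_one_bit(self):
        # a = 2x expected at large counts -> IC -> log2(2) = 1
        a, m = 2000, 10000
        t = ContingencyTable(a, m - a, m - a, 100000 - 2 * m + a)
        assert bcpnn_ic(t).ic == pytest.approx(1.0, abs=0.02)

    def test_defined_for_zero_count(self):
        r = bcpnn_ic(ContingencyTable(0, 50, 50, 1000))
        assert math.isfinite(r.ic) and math.isfinite(r.ic025)
        assert r.ic < 0

    def test_ic_converges_to_log2_relative_rate(self):
        # IC -> log2(a/E) when a and the expected count are both large
        # (the prior correction decays like log2(1 + 1/E) + log2(1 + 1/a))
        rng = np.random.default_rng(3)
        n = 10**6
        for _ in range(20):
            m1 = int(rng.integers(50000, 200000))
            m2 = int(rng.integers(50000, 200000))
            expected = m1 * m2 / n
            a = int(max(1000, expected * rng.uniform(0.5, 3.0)))
            t = ContingencyTable(a, m1 - a, m2 - a, n - m1 - m2 + a)
            assert abs(bcpnn_ic(t).ic
                       - math.log2(t.a / t.expected)) < 0.02

    def test_matches_monte_carlo_posterior(self):
        """Beta-posterior sampling oracle for the closed-form IC.

        Draw the joint and marginal reporting probabilities from their
        posteriors and average log2 p11/(p1 p2); for a table whose cells
        are small relative to the database the closed form agrees to two
        decimals.
        """
        t = ContingencyTable(100, 900, 900, 98100)
        n = t.N
        m1, m2 = t.a + t.b, t.a + t.c
        rng = np.random.default_rng(42)
        draws = 10**6
        p11 = rng.beta(t.a + 1, n - t.a + (n + 2) * (n + 2)
                       / ((m1 + 1) * (m2 + 1)) - 1, size=draws)
        p1 = rng.beta(m1 + 1, n - m1 + 1, size=draws)
        p2 = rng.beta(m2 + 1, n - m2 + 1, size=draws)
        mc_ic = float(np.mean(np.log2(p11 / (p1 * p2))))
        assert bcpnn_ic(t).ic == pytest.approx(mc_ic, abs=0.01)


class TestMgpsScore:
    def test_degenerate_prior_digamma_closed_form(self):
        # single Ga(1,1) prior, a=3, E=1 -> posterior Ga(4,2)
        prior = GammaMixturePrior(w=NEAR_ONE, alpha1=1, beta1=1,
                                  alpha2=1, beta2=1)
        r = mgps_score_from_counts(3, 1.0, prior)
        assert r.ebgm == pytest.approx(math.exp(special.digamma(4)
                                                - math.log(2)), rel=1e-9)
        # 5th percentile of Ga(4,2) equals the chi-squared_8 5% point / 4
        assert r.ebgm05 == pytest.approx(stats.chi2.ppf(0.05, 8) / 4,
                                         rel=1e-9)
        assert r.ebgm05 < r.ebgm

    def test_data_overwhelm_the_prior(self):
        r = mgps_score_from_counts(500, 100.0, GammaMixturePrior())
        assert r.rr == 5.0
        assert r.ebgm == pytest.approx(5.0, rel=0.02)

    def test_posterior_cdf_at_ebgm05_is_five_percent(self):
        prior = GammaMixturePrior()
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = int(rng.integers(0, 200))
            e = float(rng.uniform(0.1, 150))
            r = mgps_score_from_counts(a, e, prior)
            if r.ebgm05 > 0:
                assert posterior_mixture_cdf(r.ebgm05, a, e, prior) \
                    == pytest.approx(0.05, abs=1e-8)
            assert r.ebgm05 <= r.ebgm
            # upper tail for symmetry: EBGM below the 95th percentile
            assert posterior_mixture_cdf(r.ebgm, a, e, prior) < 0.95

    def test_shrinkage_monotone_in_observed_count(self):
        prior = GammaMixturePrior()
        ebgms = [mgps_score_from_counts(a, 10.0, prior).ebgm
                 for a in range(0, 51)]
        assert all(x < y for x, y in zip(ebgms, ebgms[1:]))

    def test_table_entry_point_uses_expected_count(self, toy_table):
        r = mgps_score(toy_table, GammaMixturePrior())
        assert r.expected == pytest.approx(toy_table.expected)
        assert r.rr == pytest.approx(toy_table.a / toy_table.expected)


class TestFitPrior:
    @staticmethod
    def simulate(prior, n, seed):
        rng = np.random.default_rng(seed)
        e = rng.uniform(0.5, 50, size=n)
        comp1 = rng.random(n) < prior.w
        lam = np.where(comp1,
                       rng.gamma(prior.alpha1, 1 / prior.beta1, n),
                       rng.gamma(prior.alpha2, 1 / prior.beta2, n))
        return rng.poisson(lam * e), e

    def test_objective_never_worse_than_init(self):
        true = GammaMixturePrior(w=0.5, alpha1=2, beta1=2, alpha2=1,
                                 beta2=0.5)
        a, e = self.simulate(true, 2000, seed=11)
        init = GammaMixturePrior()
        fitted = fit_mgps_prior(a, e, init=init)
        assert prior_log_likelihood(fitted, a, e) >= prior_log_likelihood(
            init, a, e)

    def test_single_gamma_recovery(self):
        # w pinned near 1: the dominant component matches the generator
        true = GammaMixturePrior(w=NEAR_ONE, alpha1=2.0, beta1=1.0,
                                 alpha2=2.0, beta2=1.0)
        a, e = self.simulate(true, 20000, seed=13)
        init = GammaMixturePrior(w=0.5, alpha1=1.0, beta1=0.5, alpha2=4.0,
                                 beta2=2.0)
        fitted = fit_mgps_prior(a, e, init=init)
        # fitted likelihood within 0.5 of the generating parameters'
        assert prior_log_likelihood(fitted, a, e) >= prior_log_likelihood(
            true, a, e) - 0.5

    def test_restart_consistency(self):
        true = GammaMixturePrior(w=0.4, alpha1=5, beta1=5, alpha2=0.5,
                                 beta2=0.25)
        a, e = self.simulate(true, 5000, seed=17)
        baseline = fit_mgps_prior(a, e, init=GammaMixturePrior())
        base_ll = prior_log_likelihood(baseline, a, e)
        rng = np.random.default_rng(19)
        for _ in range(4):
            init = GammaMixturePrior(
                w=float(rng.uniform(0.2, 0.8)),
                alpha1=float(rng.uniform(0.1, 5)),
                beta1=float(rng.uniform(0.1, 5)),
                alpha2=float(rng.uniform(0.1, 5)),
                beta2=float(rng.uniform(0.1, 5)))
            refit = fit_mgps_prior(a, e, init=init)
            assert prior_log_likelihood(refit, a, e) == pytest.approx(
                base_ll, abs=0.5)

    def test_degenerate_all_zero_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_mgps_prior(np.zeros(200), np.ones(200))

    def test_fit_is_deterministic(self):
        true = GammaMixturePrior()
        a, e = self.simulate(true, 1000, seed=23)
        assert fit_mgps_prior(a, e) == fit_mgps_prior(a, e)
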
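"""Binomial latent-strata model: likelihood, fitting, profile CIs, tests."""

import math

import numpy as np
import pytest
from scipy import stats

from crossfx import (BinomialCounts, binomial_loglik, expected_insistors,
                     fit_binomial, lr_test, make_params, moment_estimates,
                     profile_ci)
from crossfx.binomial import pi11_from, profile_pi
from crossfx.errors import CrossfxError, DegenerateDataError

TRUTH = dict(alpha0=0.10, alpha1=0.12, omega=0.7, gamma=0.8, pi=0.25)


def expectation_counts(n: int, alpha0=0.10, alpha1=0.12, omega=0.7,
                       gamma=0.8, pi=0.25) -> BinomialCounts:
    """Counts constructed at the model's expected values (no censoring)."""
    m = 1 - pi + pi * omega
    y00 = round(n * alpha0 * m)
    y01 = round(n * gamma * alpha0 * m)
    n10, n11 = n - y00, n - y01
    n101 = round(pi * n * (1 - alpha0 * omega))
    n100 = n10 - n101
    y100 = round(n100 * alpha1)
    y101 = round(n101 * gamma * omega * alpha1)
    pi11 = pi * n * (1 - gamma * alpha0 * omega) / n11
    y11 = round(n11 * gamma * alpha1 * (1 - pi11 + pi11 * omega))
    return BinomialCounts(y00=y00, n00=n, y01=y01, n01=n, y11=y11, n11=n11,
                          y100=y100, n100=n100, y101=y101,
                          n101=n101).validate()


class TestLoglik:
    def test_no_insistor_collapse_to_independent_binomials(self):
        c = BinomialCounts(y00=30, n00=200, y01=25, n01=200, y11=20, n11=170,
                           y100=22, n100=165, y101=0, n101=0)
        p = make_params("common", alpha0=0.15, alpha1=0.12, omega=0.7,
                        gamma=0.8, pi=0.0)
        got = binomial_loglik(p, c, pi_rule=None)
        cells = [(30, 200, 0.15), (25, 200, 0.8 * 0.15),
                 (22, 165, 0.12), (20, 170, 0.8 * 0.12)]
        want = sum(stats.binom.logpmf(y, n, pr) for y, n, pr in cells)
        assert got == pytest.approx(want, abs=1e-9)

    def test_out_of_domain_returns_minus_inf_not_raise(self):
        c = expectation_counts(2000)
        p = make_params("common", alpha0=0.6, alpha1=0.6, omega=3.0,
                        gamma=2.0, pi=0.5)  # omega*gamma*alpha > 1
        assert binomial_loglik(p, c, pi_rule=None) == float("-inf")

    def test_doubling_counts_doubles_kernel_difference(self, table1):
        c2 = BinomialCounts(**{k: 2 * v for k, v in table1.__dict__.items()})
        p1 = make_params("common", alpha0=0.18, alpha1=0.18, omega=0.6,
                        gamma=0.85, pi=0.3)
        p2 = make_params("common", alpha0=0.20, alpha1=0.17, omega=0.7,
                        gamma=0.80, pi=0.3)
        d1 = binomial_loglik(p1, table1, None) - binomial_loglik(p2, table1, None)
        d2 = binomial_loglik(p1, c2, None) - binomial_loglik(p2, c2, None)
        assert d2 == pytest.approx(2 * d1, rel=1e-9)

    def test_mle_is_local_optimum_on_table1(self, table1):
        fit = fit_binomial(table1)
        rng = np.random.default_rng(0)
        p = fit.params
        base = np.log([p.alpha0, p.alpha1, p.omega0, p.gamma0])
        for _ in range(100):
            z = base + rng.normal(scale=0.02, size=4)
            pert = make_params("common", alpha0=math.exp(z[0]),
                               alpha1=math.exp(z[1]), omega=math.exp(z[2]),
                               gamma=math.exp(z[3]))
            assert binomial_loglik(pert, table1) <= fit.loglik + 1e-9


class TestExpectedInsistors:
    def test_unit_omega_no_events_no_censoring(self):
        c = BinomialCounts(y00=0, n00=100, y01=0, n01=100, y11=0, n11=100,
                           y100=0, n100=75, y101=0, n101=25)
        p = make_params("common", alpha0=1e-12, alpha1=1e-12, omega=1.0,
                        gamma=1.0, pi=0.25)
        assert expected_insistors(p, c, 0) == pytest.approx(25.0)

    def test_zero_pi_gives_zero(self, table1):
        p = make_params("common", alpha0=0.17, alpha1=0.18, omega=0.6,
                        gamma=0.85, pi=0.0)
        assert expected_insistors(p, table1, 0) == 0.0
        assert expected_insistors(p, table1, 1) == 0.0

    def test_degenerate_counts_raise(self):
        c = BinomialCounts(y00=0, n00=0, y01=0, n01=10, y11=0, n11=5,
                           y100=0, n100=0, y101=0, n101=0)
        p = make_params("common", alpha0=0.1, alpha1=0.1, omega=1.0,
                        gamma=1.0, pi=0.2)
        with pytest.raises(DegenerateDataError):
            expected_insistors(p, c, 0)

    def test_profiled_pi_reproduces_observed_count(self, table1):
        # at the fitted parameters the expected insistor count at the offer
        # must equal the observed revealed count, by construction of pi
        fit = fit_binomial(table1, "by-period")
        assert expected_insistors(fit.params, table1, 0) == \
            pytest.approx(table1.n101, abs=1.0)


class TestFit:
    def test_table1_primary_model_efficacy(self, table1):
        fit = fit_binomial(table1)
        assert round(fit.params.gamma0, 2) == 0.86
        assert 0.0 <= fit.pi11 <= 1.0
        assert np.isfinite(fit.loglik)

    def test_parameter_recovery_on_expectation_counts(self):
        c = expectation_counts(10 ** 6)
        fit = fit_binomial(c)
        p = fit.params
        assert p.alpha0 == pytest.approx(TRUTH["alpha0"], abs=1e-3)
        assert p.alpha1 == pytest.approx(TRUTH["alpha1"], abs=1e-3)
        assert p.omega0 == pytest.approx(TRUTH["omega"], abs=2e-3)
        assert p.gamma0 == pytest.approx(TRUTH["gamma"], abs=1e-3)
        assert p.pi == pytest.approx(TRUTH["pi"], abs=2e-3)

    def test_identical_arms_give_unit_efficacy(self):
        c = BinomialCounts(y00=100, n00=1000, y01=100, n01=1000,
                           y11=90, n11=880, y100=68, n100=660,
                           y101=22, n101=220)
        fit = fit_binomial(c)
        assert fit.params.gamma0 == pytest.approx(1.0, abs=5e-3)

    def test_saturated_cells_reproduced_in_free_gamma1star_variant(self, table1):
        fit = fit_binomial(table1, "free-gamma1star")
        assert fit.expected_counts["y100"] == pytest.approx(table1.y100,
                                                            abs=0.5)
        assert fit.expected_counts["y101"] == pytest.approx(table1.y101,
                                                            abs=0.5)

    def test_nested_model_likelihood_ordering(self, table1):
        for c in [table1, expectation_counts(5000),
                  expectation_counts(3000, omega=1.4, gamma=1.2)]:
            ll_c = fit_binomial(c, "common").loglik
            ll_h = fit_binomial(c, "by-period").loglik
            assert ll_h >= ll_c - 1e-6

    def test_bias_of_log_gamma_shrinks_with_n(self):
        rng = np.random.default_rng(42)
        biases = []
        for n in (2_000, 20_000, 200_000):
            vals = []
            for _ in range(8):
                c0 = expectation_counts(n)
                c = _resample(c0, rng)
                vals.append(math.log(fit_binomial(c, n_starts=1).params.gamma0))
            biases.append(abs(np.mean(vals) - math.log(TRUTH["gamma"])))
        assert biases[2] < biases[0]


def _resample(c: BinomialCounts, rng) -> BinomialCounts:
    """Binomial noise around a count table, conserving risk-set flows."""
    y00 = rng.binomial(c.n00, c.y00 / c.n00)
    y01 = rng.binomial(c.n01, c.y01 / c.n01)
    n10, n11 = c.n00 - y00, c.n01 - y01
    n101 = rng.binomial(n10, c.n101 / c.n10)
    n100 = n10 - n101
    return BinomialCounts(
        y00=y00, n00=c.n00, y01=y01, n01=c.n01,
        y11=rng.binomial(n11, c.y11 / c.n11), n11=n11,
        y100=rng.binomial(n100, c.y100 / c.n100), n100=n100,
        y101=rng.binomial(n101, c.y101 / c.n101), n101=n101).validate()


class TestProfileCI:
    def test_interval_contains_mle_and_matches_published(self, table1):
        fit = fit_binomial(table1)
        lo, hi = profile_ci(table1, "common", "gamma", fit=fit)
        assert lo < fit.params.gamma0 < hi
        assert (round(lo, 2), round(hi, 2)) == (0.77, 0.96)

    def test_width_shrinks_like_root_n(self):
        widths = []
        for n in (10_000, 1_000_000):
            c = expectation_counts(n)
            lo, hi = profile_ci(c, "common", "gamma")
            widths.append(hi - lo)
        assert widths[0] / widths[1] == pytest.approx(10.0, rel=0.15)


class TestLRTest:
    def test_published_heterogeneity_statistic(self, table1):
        stat, df, p = lr_test(table1, "common", "by-period")
        assert round(stat, 2) == 0.32 and df == 1
        assert p == pytest.approx(stats.chi2(1).sf(stat))

    def test_variant_against_itself_is_zero(self, table1):
        stat, df, p = lr_test(table1, "common", "common")
        assert stat == 0.0 and df == 0

    def test_non_nested_variants_rejected(self, table1):
        with pytest.raises(CrossfxError):
            lr_test(table1, "by-period", "common")

    def test_type_one_error_under_common_gamma_null(self):
        rng = np.random.default_rng(7)
        c0 = expectation_counts(4000)
        rejections = 0
        reps = 60
        for _ in range(reps):
            c = _resample(c0, rng)
            stat, df, p = lr_test(c, "common", "by-period", n_starts=1)
            rejections += p < 0.05
        # 99% binomial band around 0.05 at this replication
        assert rejections / reps <= 0.13


class TestMomentEstimates:
    def test_pre_offer_efficacy_ratio(self, table1):
        mom = moment_estimates(table1)
        assert round(mom["gamma0"], 2) == 0.84
        assert mom["alpha1"] == pytest.approx(table1.y100 / table1.n100)

    def test_zero_pi11_reduces_to_event_rate_ratio(self, table1):
        mom = moment_estimates(table1, pi11=0.0)
        want = (table1.y11 / table1.n11) / (table1.y100 / table1.n100)
        assert mom["gamma1"] == pytest.approx(want)

    def test_self_consistent_fixed_point_matches_published_gamma1(self, table1):
        # independent oracle: iterate pi11 <-> the insistor-subtraction
        # formula together with the moment relations for (pi, omega),
        # using only observed cell proportions
        c = table1
        a1 = c.y100 / c.n100
        gamma0 = (c.y01 / c.n01) / (c.y00 / c.n00)
        a0_m = c.y00 / c.n00               # alpha0 * mixture
        pi11 = 0.2
        for _ in range(200):
            g1 = ((c.y11 / c.n11) - pi11 * (c.y101 / c.n101)) \
                / ((1 - pi11) * a1)
            om = (c.y101 / c.n101) / (g1 * a1)
            # pi from the revealed count relation, alpha0 from the mixture
            pi = profile_pi(make_params("common", alpha0=a0_m, alpha1=a1,
                                        omega=om, gamma=g1), c)
            m = 1 - pi + pi * om
            p = make_params("common", alpha0=a0_m / m, alpha1=a1, omega=om,
                            gamma=gamma0, pi=pi)
            pi11 = pi11_from(p, c)
        assert round(g1, 2) == 0.90
        mom = moment_estimates(c, pi=pi, omega=om)
        assert mom["gamma1"] == pytest.approx(g1, abs=1e-3)
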
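"""Unit tests for the stationary law, truncated RSA, binned fit and theta."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

from neutralrsa.model import (
    BirthDeathParams,
    ParameterDomainError,
    PrecisionError,
    UnderdeterminedFitError,
    detailed_balance_pmf,
    expected_bin_counts,
    expected_rsa,
    fit_preston,
    nb_pmf,
    theta,
)
from neutralrsa.rsa import preston_bin


class TestBirthDeathParams:
    def test_ratios_and_upsilon(self):
        p = BirthDeathParams(b=0.5, d=1.0, S=0.25)
        assert p.ratio_bd == 0.5
        assert p.ratio_Sb == 0.5
        assert p.upsilon == p.ratio_Sb
        assert p.mean_abundance == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(b=-1.0, d=1.0, S=1.0),
            dict(b=0.5, d=-1.0, S=1.0),
            dict(b=0.5, d=1.0, S=0.0),
            dict(b=1.0, d=1.0, S=1.0),   # b/d = 1: no stationary law
            dict(b=2.0, d=1.0, S=1.0),   # supercritical
        ],
    )
    def test_invalid_rates_rejected(self, kwargs):
        with pytest.raises(ParameterDomainError):
            BirthDeathParams(**kwargs)


class TestNbPmf:
    def test_geometric_special_case(self):
        # at S/b = 1 the Gamma factors cancel and the law is geometric
        x = 0.7
        n = np.arange(51)
        assert nb_pmf(n, x, 1.0) == pytest.approx((1 - x) * x**n, rel=1e-12)

    def test_normalisation(self, ratio_pair):
        x, r = ratio_pair
        n_max = 200_000
        total = nb_pmf(np.arange(n_max), x, r).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_matches_scipy_negative_binomial(self, ratio_pair):
        x, r = ratio_pair
        n = np.arange(150)
        ref = stats.nbinom.pmf(n, r, 1 - x)
        assert nb_pmf(n, x, r) == pytest.approx(ref, rel=1e-10)

    def test_mean_is_deterministic_fixed_point(self):
        # the pmf mean must equal S/(d-b), the rate-equation equilibrium
        p = BirthDeathParams(b=0.9, d=1.0, S=0.45)
        n = np.arange(5000)
        mean = float((n * nb_pmf(n, p.ratio_bd, p.ratio_Sb)).sum())
        assert mean == pytest.approx(p.mean_abundance, abs=1e-8)

    @pytest.mark.parametrize("bad", [(-0.1, 0.5), (0.0, 0.5), (1.0, 0.5), (0.5, 0.0), (0.5, -1.0)])
    def test_domain_errors(self, bad):
        with pytest.raises(ParameterDomainError):
            nb_pmf(3, *bad)


class TestDetailedBalance:
    def test_matches_closed_form(self, ratio_pair):
        x, r = ratio_pair
        params = BirthDeathParams.from_ratios(x, r)
        table = detailed_balance_pmf(8000, params)
        closed = nb_pmf(np.arange(201), x, r)
        assert np.max(np.abs(table[:201] / closed - 1)) < 1e-10

    def test_sums_to_one(self):
        table = detailed_balance_pmf(2000, BirthDeathParams.from_ratios(0.9, 0.5))
        assert table.sum() == pytest.approx(1.0, abs=1e-14)

    def test_recurrence_ratio(self):
        # P_{n+1}/P_n = (b/d)(n + S/b)/(n + 1) directly from the flux balance
        x, r = 0.8, 1.7
        table = detailed_balance_pmf(2000, BirthDeathParams.from_ratios(x, r))
        n = np.arange(100)
        assert table[1:101] / table[:100] == pytest.approx(x * (n + r) / (n + 1), rel=1e-12)

    def test_insufficient_truncation_raises(self):
        with pytest.raises(PrecisionError):
            detailed_balance_pmf(10, BirthDeathParams.from_ratios(0.99, 2.0))


class TestExpectedRsa:
    def test_sums_to_observed_species(self, ratio_pair):
        x, r = ratio_pair
        n_obs = 350
        total = expected_rsa(np.arange(1, 300_000), x, r, n_obs).sum()
        assert total == pytest.approx(n_obs, abs=1e-8)

    def test_is_rescaled_truncated_pmf(self):
        x, r, n_obs = 0.9, 0.5, 120
        n = np.arange(1, 101)
        ratio = expected_rsa(n, x, r, n_obs) / n_obs
        assert ratio == pytest.approx(nb_pmf(n, x, r) / (1 - nb_pmf(0, x, r)), rel=1e-12)

    def test_log_series_limit(self):
        # as S/b -> 0 the truncated RSA collapses onto Fisher's x^n/n
        x, r = 0.9, 1e-6
        n = np.arange(1, 51)
        shape = expected_rsa(n, x, r, 1.0)
        ls = x**n / n
        ls /= (x ** np.arange(1, 100_000) / np.arange(1, 100_000)).sum()
        assert np.max(np.abs(shape / ls - 1)) < 1e-3

    def test_rejects_zero_abundance(self):
        with pytest.raises(ValueError):
            expected_rsa(0, 0.9, 0.5, 10)


class TestExpectedBinCounts:
    def test_first_octave_is_singleton_class(self):
        x, r, n_obs = 0.95, 0.3, 200
        bins = expected_bin_counts(x, r, n_obs, 5)
        assert bins[0] == pytest.approx(expected_rsa(1, x, r, n_obs), rel=1e-12)

    def test_third_octave_is_4_to_7(self):
        x, r, n_obs = 0.95, 0.3, 200
        bins = expected_bin_counts(x, r, n_obs, 5)
        direct = expected_rsa(np.array([4, 5, 6, 7]), x, r, n_obs).sum()
        assert bins[2] == pytest.approx(direct, rel=1e-12)

    def test_cumulative_difference_equals_brute_force(self, ratio_pair):
        # the sf-difference path must agree with summing every abundance in
        # the octave, up to octaves reaching 2^15
        x, r = ratio_pair
        n_obs = 500
        bins = expected_bin_counts(x, r, n_obs, 15)
        for k in range(15):
            direct = expected_rsa(np.arange(2**k, 2 ** (k + 1)), x, r, n_obs).sum()
            assert bins[k] == pytest.approx(direct, rel=1e-10, abs=1e-300)


class TestTheta:
    def test_linear_in_n_obs(self):
        assert theta(0.9, 0.5, 200) == pytest.approx(2 * theta(0.9, 0.5, 100), rel=1e-12)

    def test_two_printed_forms_agree(self, ratio_pair):
        x, r = ratio_pair
        n_obs = 100.0
        # numerator form: N_obs (1-x)^r / ([1-(1-x)^r] Gamma(r))
        p0 = math.exp(r * math.log1p(-x))
        form_a = n_obs * p0 / ((1 - p0) * math.exp(gammaln(r)))
        assert theta(x, r, n_obs) == pytest.approx(form_a, rel=1e-12)

    def test_geometric_closed_form(self):
        # at S/b = 1: theta = N_obs (1-x)/x
        x, n_obs = 0.73, 50
        assert theta(x, 1.0, n_obs) == pytest.approx(n_obs * (1 - x) / x, rel=1e-12)

    def test_survives_extreme_parameters(self):
        # log-space evaluation must not overflow Gamma at tiny S/b
        value = theta(0.999999, 1e-8, 1000)
        assert value > 0 and math.isfinite(value)


class TestFitPreston:
    def test_noiseless_recovery(self):
        true_bd, true_sb, n_obs = 0.98, 0.2, 500.0
        exact = expected_bin_counts(true_bd, true_sb, n_obs, 12)
        fit = fit_preston(exact)
        assert fit.converged
        assert fit.ratio_bd == pytest.approx(true_bd, rel=1e-4)
        assert fit.ratio_Sb == pytest.approx(true_sb, rel=1e-4)
        assert fit.r_squared > 0.9999
        assert fit.n_total >= fit.n_obs
        assert fit.theta > 0

    def test_accepts_histogram_object(self):
        from neutralrsa.synthetic import sample_truncated_nb

        params = BirthDeathParams.from_ratios(0.95, 0.5)
        hist = preston_bin(sample_truncated_nb(800, params, seed=5))
        fit = fit_preston(hist)
        assert fit.n_obs == hist.n_obs_total
        assert fit.observed.sum() == hist.n_obs_total

    def test_inconsistent_histogram_still_returns_fit(self):
        # monotonically growing octaves cannot come from this family's tail;
        # the optimiser must still return its least-squares incumbent rather
        # than fail silently or raise
        fit = fit_preston(np.arange(1, 11, dtype=float))
        assert fit.converged
        assert np.isfinite(fit.objective) and fit.objective > 0
        # the family cannot reproduce a rising tail: residuals stay visible
        assert fit.r_squared < 1 - 1e-3
        assert fit.expected[-1] < fit.observed[-1]

    def test_underdetermined_raises(self):
        with pytest.warns(UserWarning):
            with pytest.raises(UnderdeterminedFitError):
                fit_preston(np.array([5.0, 3.0, 0.0]))

    def test_invariant_to_species_order(self, rng):
        from neutralrsa.synthetic import sample_truncated_nb

        params = BirthDeathParams.from_ratios(0.95, 0.5)
        counts = sample_truncated_nb(500, params, seed=9)
        fit_a = fit_preston(preston_bin(counts))
        fit_b = fit_preston(preston_bin(rng.permutation(counts)))
        assert fit_a.ratio_bd == fit_b.ratio_bd
        assert fit_a.ratio_Sb == fit_b.ratio_Sb

    def test_mle_mode_close_to_lsq_on_model_data(self):
        from neutralrsa.synthetic import sample_truncated_nb

        params = BirthDeathParams.from_ratios(0.95, 0.5)
        hist = preston_bin(sample_truncated_nb(1000, params, seed=2))
        lsq = fit_preston(hist, mode="lsq")
        mle = fit_preston(hist, mode="mle")
        assert mle.ratio_bd == pytest.approx(lsq.ratio_bd, rel=0.2)
        assert mle.ratio_Sb == pytest.approx(lsq.ratio_Sb, rel=0.5)
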
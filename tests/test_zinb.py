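"""Unit tests for the single-taxon ZINB regression machinery."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from cramed import (
    fit_zinb, sample_zinb, wald_test, zinb_logpmf,
    AllZeroError, ZinbFit, ZinbParams,
)
from cramed.zinb import SingularCovarianceError

from conftest import make_zinb_counts


def mixture_logpmf_oracle(k, pi, lam, phi):
    """Brute-force mixture density via scipy's NB pmf (independent coding)."""
    p_nb = stats.nbinom.pmf(k, phi, phi / (phi + lam))
    prob = pi * (k == 0) + (1 - pi) * p_nb
    return np.log(prob)


class TestLogpmf:
    @pytest.mark.parametrize("k,pi,lam,phi", [
        (5, 0.3, 4.0, 1.5),
        (0, 0.3, 4.0, 1.5),
        (0, 0.0, 2.5, 0.4),
        (12, 0.8, 9.0, 6.0),
        (1, 0.5, 0.3, 10.0),
    ])
    def test_matches_mixture_oracle(self, k, pi, lam, phi):
        assert zinb_logpmf(k, pi, lam, phi) == pytest.approx(
            mixture_logpmf_oracle(k, pi, lam, phi), abs=1e-10)

    def test_all_mass_at_zero(self):
        assert zinb_logpmf(0, 1.0, 3.0, 2.0) == pytest.approx(0.0, abs=1e-12)

    def test_poisson_limit(self):
        # phi -> infinity: NB(lam, phi) -> Poisson(lam)
        expected = 3 * np.log(2) - 2 - np.log(6)
        assert zinb_logpmf(3, 0.0, 2.0, 1e7) == pytest.approx(expected, abs=1e-5)

    @pytest.mark.parametrize("pi,lam,phi", [(0.4, 5.0, 2.0), (0.0, 20.0, 0.3)])
    def test_normalizes(self, pi, lam, phi):
        k = np.arange(0, 4000)
        total = np.exp(zinb_logpmf(k, pi, lam, phi)).sum()
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_rejects_invalid_counts(self):
        with pytest.raises(ValueError):
            zinb_logpmf(-1, 0.2, 1.0, 1.0)
        with pytest.raises(ValueError):
            zinb_logpmf(1.5, 0.2, 1.0, 1.0)


class TestFit:
    def test_recovers_parameters_large_n(self, rng):
        y, T, off = make_zinb_counts(2000, rng)
        fit = fit_zinb(y, T, None, off)
        assert fit.converged
        se = np.sqrt(np.diag(fit.cov_theta))  # (alpha1, gamma1)
        assert abs(fit.params.alpha1 - (-2.0)) < 3 * se[0]
        assert abs(fit.params.gamma1 - (-2.0)) < 3 * se[1]
        assert fit.params.phi == pytest.approx(2.0, rel=0.35)

    def test_loglik_equals_pointwise_sum(self, zinb_taxon):
        y, T, off = zinb_taxon
        fit = fit_zinb(y, T, None, off)
        ll = zinb_logpmf(y, fit.fitted_pi, fit.fitted_lambda, fit.params.phi)
        assert np.sum(ll) == pytest.approx(fit.loglik, abs=1e-8)

    def test_fitted_mean_identity(self, zinb_taxon):
        y, T, off = zinb_taxon
        fit = fit_zinb(y, T, None, off)
        np.testing.assert_allclose(
            fit.fitted_mean, (1 - fit.fitted_pi) * fit.fitted_lambda)

    def test_mle_dominates_truth(self, rng):
        y, T, off = make_zinb_counts(500, rng)
        fit = fit_zinb(y, T, None, off)
        pi_true = expit(0.5 - 2.0 * T)
        lam_true = np.exp(off - 7.0 - 2.0 * T)
        ll_true = np.sum(zinb_logpmf(y, pi_true, lam_true, 2.0))
        assert fit.loglik >= ll_true - 1e-6

    def test_no_zeros_falls_back_to_nb(self, rng):
        y = rng.poisson(20.0, size=200) + 1  # strictly positive
        T = (rng.random(200) < 0.5).astype(int)
        fit = fit_zinb(y, T)
        assert fit.wald_df == 1
        assert np.all(fit.fitted_pi == 0)
        assert np.isnan(fit.params.gamma1)
        res = wald_test(fit)
        assert res.df == 1 and 0 <= res.p2 <= 1

    def test_all_zero_raises(self):
        with pytest.raises(AllZeroError):
            fit_zinb(np.zeros(50, dtype=int), np.tile([0, 1], 25))

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            fit_zinb(np.array([-1] + [1] * 20), np.tile([0, 1], 21)[:21])

    def test_bias_shrinks_with_n(self):
        biases = []
        for n in (200, 2000):
            rng = np.random.default_rng(7)
            errs = []
            for _ in range(30):
                y, T, off = make_zinb_counts(n, rng)
                fit = fit_zinb(y, T, None, off)
                errs.append(fit.params.alpha1 + 2.0)
            biases.append(abs(np.mean(errs)))
        assert biases[1] < biases[0] + 0.02


class TestSample:
    def _fit_for(self, pi, lam, phi, n=10000):
        params = ZinbParams(gamma0=0.0, gamma1=0.0, gamma_x=np.empty(0),
                            alpha0=0.0, alpha1=0.0, alpha_x=np.empty(0), phi=phi)
        pi_v = np.full(n, pi)
        lam_v = np.full(n, lam)
        return ZinbFit(params=params, fitted_pi=pi_v, fitted_lambda=lam_v,
                       fitted_mean=(1 - pi_v) * lam_v, cov_theta=np.eye(2),
                       loglik=0.0, converged=True, n_obs=n)

    def test_all_zero_when_pi_one(self, rng):
        fit = self._fit_for(1.0, 3.0, 2.0, n=500)
        assert np.all(sample_zinb(fit, rng) == 0)

    def test_poisson_like_mean(self, rng):
        fit = self._fit_for(0.0, 3.0, 1e7, n=20000)
        draw = sample_zinb(fit, rng)
        assert abs(draw.mean() - 3.0) < 3 * np.sqrt(3.0 / 20000)

    def test_zero_fraction_matches_closed_form(self, rng):
        pi, lam, phi = 0.4, 5.0, 2.0
        fit = self._fit_for(pi, lam, phi, n=10000)
        p0 = pi + (1 - pi) * (phi / (phi + lam)) ** phi
        frac = (sample_zinb(fit, rng) == 0).mean()
        assert abs(frac - p0) < 3 * np.sqrt(p0 * (1 - p0) / 10000)

    def test_reproducible_under_seed(self):
        fit = self._fit_for(0.3, 4.0, 1.0, n=100)
        a = sample_zinb(fit, np.random.default_rng(5))
        b = sample_zinb(fit, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)


class TestWald:
    def _fit_with(self, alpha1, gamma1, cov):
        params = ZinbParams(gamma0=0.0, gamma1=gamma1, gamma_x=np.empty(0),
                            alpha0=0.0, alpha1=alpha1, alpha_x=np.empty(0),
                            phi=1.0)
        z = np.zeros(10)
        return ZinbFit(params=params, fitted_pi=z, fitted_lambda=z + 1,
                       fitted_mean=z + 1, cov_theta=np.asarray(cov),
                       loglik=0.0, converged=True, n_obs=10)

    def test_zero_theta_gives_p_one(self):
        res = wald_test(self._fit_with(0.0, 0.0, np.eye(2)))
        assert res.w2 == 0.0 and res.p2 == 1.0

    def test_chi2_quantile(self):
        # W^2 at the chi2(2) 95% point must give p2 = 0.05
        w = stats.chi2.ppf(0.95, 2)
        res = wald_test(self._fit_with(np.sqrt(w), 0.0, np.eye(2)))
        assert res.w2 == pytest.approx(w, abs=1e-10)
        assert res.p2 == pytest.approx(0.05, abs=1e-10)

    def test_singular_covariance_raises(self):
        with pytest.raises(SingularCovarianceError):
            wald_test(self._fit_with(1.0, 1.0, np.zeros((2, 2))))

    def test_null_pvalues_roughly_uniform(self):
        # alpha1 = gamma1 = 0: p2 should be near-uniform at moderate n
        rng = np.random.default_rng(99)
        ps = []
        for _ in range(200):
            y, T, off = make_zinb_counts(300, rng, g1=0.0, a1=0.0)
            if not (y > 0).any():
                continue
            fit = fit_zinb(y, T, None, off)
            if fit.wald_df != 2:
                continue
            ps.append(wald_test(fit).p2)
        ps = np.asarray(ps)
        rej = (ps < 0.05).mean()
        assert abs(rej - 0.05) < 3 * np.sqrt(0.05 * 0.95 / len(ps)) + 0.01
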
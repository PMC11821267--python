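"""Tests for the synthetic-data generators and their coefficient scheme."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from cramed import (
    draw_scheme, simulate_zinb_dataset, simulate_hurdle_dataset,
    simulate_confounded_dataset, hurdle_logpmf,
)


class TestScheme:
    def test_fixed_constants(self):
        s = draw_scheme(40, np.random.default_rng(0))
        assert s.alpha0 == -7.0 and s.beta0 == 1.0
        assert s.beta1 == -2.0 and s.sigma2 == 1.0
        assert np.all(s.gamma0 >= -2) and np.all(s.gamma0 <= 2)
        assert np.all(s.phi >= 0.1) and np.all(s.phi <= 10)

    def test_class_structure(self):
        s = draw_scheme(60, np.random.default_rng(1))
        g, a, b = s.gamma1, s.alpha1, s.beta_m
        assert np.all(g[0:3] != 0) and np.all(a[0:3] != 0) and np.all(b[0:3] != 0)
        assert g[3] == 0 and a[3] != 0 and b[3] != 0
        assert g[4] != 0 and a[4] == 0 and b[4] != 0
        assert np.all(g[5:10] == 0) and np.all(a[5:10] == 0) and np.all(b[5:10] != 0)
        assert np.all(g[10:15] != 0) and np.all(a[10:15] != 0) and np.all(b[10:15] == 0)
        assert np.all(g[15:20] != 0) and np.all(a[15:20] == 0) and np.all(b[15:20] == 0)
        assert np.all(g[20:25] == 0) and np.all(a[20:25] != 0) and np.all(b[20:25] == 0)
        assert np.all(g[25:] == 0) and np.all(a[25:] == 0) and np.all(b[25:] == 0)

    def test_truth_is_first_five(self):
        s = draw_scheme(100, np.random.default_rng(2))
        np.testing.assert_array_equal(np.flatnonzero(s.truth), np.arange(5))

    def test_truth_rule_matches_null_definition(self):
        # causal iff beta_m != 0 and the treatment->mediator path is active
        s = draw_scheme(30, np.random.default_rng(3))
        expected = [(s.beta_m[j] != 0) and (s.alpha1[j] != 0 or s.gamma1[j] != 0)
                    for j in range(30)]
        np.testing.assert_array_equal(s.truth, expected)

    def test_m_below_class_table_errors(self):
        with pytest.raises(ValueError):
            draw_scheme(25, np.random.default_rng(0))

    def test_path_coefficient_mean(self):
        draws = [draw_scheme(26, np.random.default_rng(k)).gamma1[:3]
                 for k in range(300)]
        vals = np.concatenate(draws)
        assert abs(vals.mean() + 2.0) < 3 / np.sqrt(vals.size)


class TestZinbGenerator:
    @pytest.mark.parametrize("n,m", [(100, 100), (200, 100), (100, 1000),
                                     (200, 1000)])
    def test_study_dimensions_run(self, n, m):
        data = simulate_zinb_dataset(n, m, 12)
        assert data.M.shape == (n, m)
        assert set(np.unique(data.T)) <= {0, 1}
        assert np.all(data.log_depth >= 7.1) and np.all(data.log_depth <= 10.5)
        assert data.truth.sum() == 5

    def test_deterministic_under_seed(self):
        a = simulate_zinb_dataset(80, 30, 42)
        b = simulate_zinb_dataset(80, 30, 42)
        np.testing.assert_array_equal(a.M, b.M)
        np.testing.assert_array_equal(a.Y, b.Y)
        np.testing.assert_array_equal(a.T, b.T)

    def test_zero_fraction_plausible(self):
        fracs = [(simulate_zinb_dataset(100, 100, s).M == 0).mean()
                 for s in range(5)]
        assert 0.40 < np.mean(fracs) < 0.70

    def test_marginal_zero_probability_matches_closed_form(self):
        data = simulate_zinb_dataset(4000, 26, 9)
        s = data.scheme
        for j in (0, 7, 25):
            pi = expit(s.gamma0[j] + s.gamma1[j] * data.T)
            lam = np.exp(data.log_depth + s.alpha0 + s.alpha1[j] * data.T)
            p0 = pi + (1 - pi) * (s.phi[j] / (s.phi[j] + lam)) ** s.phi[j]
            expected = p0.mean()
            observed = (data.M[:, j] == 0).mean()
            se = np.sqrt(expected * (1 - expected) / 4000)
            assert abs(observed - expected) < 4 * se + 0.01

    def test_outcome_reduces_to_treatment_model_without_mediation(self):
        rng = np.random.default_rng(31)
        scheme = draw_scheme(26, rng)
        scheme.beta_m[:] = 0.0
        data = simulate_zinb_dataset(3000, 26, rng, scheme=scheme)
        x = np.column_stack([np.ones(3000), data.T])
        slope = np.linalg.lstsq(x, data.Y, rcond=None)[0][1]
        se = 1.0 / np.sqrt((data.T.var() * 3000))
        assert abs(slope + 2.0) < 3 * se


class TestHurdle:
    def hurdle_oracle(self, k, pi, lam, phi):
        # independent coding of the printed truncated pmf
        if k == 0:
            return np.log(pi)
        nb_k = stats.nbinom.pmf(k, phi, phi / (phi + lam))
        nb_0 = stats.nbinom.pmf(0, phi, phi / (phi + lam))
        return np.log((1 - pi) * nb_k / (1 - nb_0))

    @pytest.mark.parametrize("k", [0, 1, 2, 7])
    def test_logpmf_matches_oracle(self, k):
        assert hurdle_logpmf(k, 0.3, 5.0, 2.0) == pytest.approx(
            self.hurdle_oracle(k, 0.3, 5.0, 2.0), abs=1e-10)

    def test_normalizes(self):
        k = np.arange(0, 3000)
        total = np.exp(hurdle_logpmf(k, 0.3, 5.0, 2.0)).sum()
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_no_zero_mass_when_pi_zero(self):
        assert hurdle_logpmf(0, 0.0, 2.0, 1.0) == -np.inf

    def test_poisson_is_large_phi_limit(self):
        k = np.arange(0, 60)
        lp_inf = hurdle_logpmf(k, 0.2, 4.0, np.inf)
        lp_big = hurdle_logpmf(k, 0.2, 4.0, 1e8)
        np.testing.assert_allclose(lp_inf, lp_big, atol=1e-5)

    @pytest.mark.parametrize("family", ["poisson", "nb"])
    def test_dataset_runs_and_is_deterministic(self, family):
        a = simulate_hurdle_dataset(60, 26, family, 5)
        b = simulate_hurdle_dataset(60, 26, family, 5)
        np.testing.assert_array_equal(a.M, b.M)
        assert a.generator == f"hurdle_{family}"

    def test_truncation_forces_positives(self):
        rng = np.random.default_rng(13)
        scheme = draw_scheme(26, rng)
        scheme.gamma0[:] = -30.0   # pi ~ 0: the hurdle never fires
        scheme.gamma1[:] = 0.0
        data = simulate_hurdle_dataset(50, 26, "nb", rng, scheme=scheme)
        assert np.all(data.M >= 1)

    def test_zero_fraction_matches_pi(self):
        # in a hurdle model the zero fraction is exactly the hurdle probability
        data = simulate_hurdle_dataset(4000, 26, "nb", 17)
        s = data.scheme
        for j in (0, 12, 25):
            expected = expit(s.gamma0[j] + s.gamma1[j] * data.T).mean()
            observed = (data.M[:, j] == 0).mean()
            assert abs(observed - expected) < 4 * np.sqrt(expected * (1 - expected) / 4000) + 0.01


class TestConfounded:
    def test_shapes_and_confounder_moments(self):
        data = simulate_confounded_dataset(4000, 26, h=3, seed=21)
        assert data.X_u.shape == (4000, 3)
        assert abs(data.X_u.mean()) < 3 / np.sqrt(4000 * 3)
        assert data.X_u.std() == pytest.approx(1.0, abs=0.05)

    def test_centered_confounding_keeps_treatment_balanced(self):
        means = [simulate_confounded_dataset(500, 26, h=0, seed=s).T.mean()
                 for s in range(20)]
        assert abs(np.mean(means) - 0.5) < 3 * np.std(means) / np.sqrt(20) + 0.01

    def test_amplified_coefficients(self):
        vals = np.concatenate([
            simulate_confounded_dataset(20, 26, h=1, seed=s).scheme.gamma1[:3]
            for s in range(60)])
        assert abs(vals.mean() + 5.0) < 3 / np.sqrt(vals.size)

    def test_treatment_depends_on_confounders(self):
        data = simulate_confounded_dataset(3000, 26, h=9, seed=2)
        # strong confounding: T is predictable from X_u
        corr = np.corrcoef(data.X_u.sum(axis=1), data.T)[0, 1]
        assert abs(corr) > 0.2
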
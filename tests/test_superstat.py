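import numpy as np
import pytest
from scipy import integrate, stats

import superdna as sd
import superdna.superstat as ss


class TestParameterRelations:
    @pytest.mark.parametrize(
        "rho,alpha",
        [(0.07, 204.08), (0.23, 18.90), (0.12, 69.44)],
    )
    def test_alpha_from_rho(self, rho, alpha):
        m = sd.model_from_moments(mean_n=75.0, sigma_n=rho * 75.0)
        assert m.alpha == pytest.approx(alpha, rel=1e-3)

    def test_moment_relations_exact(self):
        m = sd.model_from_moments(75.0, 9.0)
        assert m.rho == pytest.approx(0.12, rel=1e-12)
        assert m.alpha == pytest.approx(1 / m.rho**2, rel=1e-12)
        assert m.lam == pytest.approx(m.alpha / m.mean_n, rel=1e-12)
        assert m.q == pytest.approx(1 + m.rho**2, rel=1e-12)
        assert m.lam == pytest.approx(0.9259, abs=1e-4)

    @pytest.mark.parametrize("q,alpha", [(1.11, 9.0909), (1.5, 2.0)])
    def test_alpha_from_q(self, q, alpha):
        assert sd.alpha_from_q(q) == pytest.approx(alpha, rel=1e-4)

    def test_alpha_q_round_trip(self):
        rho = 0.2
        assert sd.alpha_from_q(sd.q_from_rho(rho)) == pytest.approx(1 / rho**2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sd.model_from_moments(-1, 9)
        with pytest.raises(ValueError):
            sd.alpha_from_q(0.99)


class TestGammaIntensity:
    def test_moment_match(self, rng):
        m = sd.model_from_moments(75, 9)
        scale = m.mean_beta / m.alpha
        draws = rng.gamma(m.alpha, scale, size=10**6)
        assert draws.mean() == pytest.approx(m.mean_beta, rel=1e-3)
        assert draws.std() == pytest.approx(9 / 150, rel=5e-3)

    def test_integrates_to_one(self):
        m = sd.model_from_moments(75, 9)
        val, _ = integrate.quad(lambda b: ss.gamma_intensity_pdf(m, b), 0, np.inf)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_concentration_at_large_alpha(self):
        tight = sd.model_from_moments(75, 0.01)
        beta = np.linspace(0.48, 0.52, 401)
        dens = ss.gamma_intensity_pdf(tight, beta)
        assert beta[np.argmax(dens)] == pytest.approx(0.5, abs=1e-3)
        assert ss.gamma_intensity_pdf(tight, 0.45) < 1e-10


class TestMarginalIntervalLaw:
    def test_closed_form_vs_quadrature(self):
        m = sd.model_from_moments(75, 9)
        ls = np.array([0.0, 1.0, 10.0, 100.0, 1000.0])
        closed = ss.marginal_interval_pdf(m, ls)
        quad = ss.marginal_interval_pdf_quadrature(m, ls)
        np.testing.assert_allclose(closed, quad, rtol=1e-6)

    def test_monte_carlo_mixture_agreement(self):
        m = sd.model_from_moments(75, 9)
        draws = ss.sample_marginal(m, 10**6, 1234)
        res = stats.kstest(draws, lambda x: 1 - ss.marginal_interval_sf(m, x))
        assert res.statistic < 0.005

    def test_monotone_decreasing_and_normalized(self):
        m = sd.model_from_moments(40, 12)
        ls = np.linspace(0, 5000, 2001)
        dens = ss.marginal_interval_pdf(m, ls)
        assert np.all(np.diff(dens) < 0)
        val, _ = integrate.quad(lambda l: ss.marginal_interval_pdf(m, l), 0, np.inf)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_tail_exponent(self):
        m = sd.model_from_moments(75, 30)  # alpha = 6.25: visible power law
        ls = np.array([1e5, 1e6])
        dens = ss.marginal_interval_pdf(m, ls)
        slope = np.log(dens[1] / dens[0]) / np.log(10)
        assert slope == pytest.approx(-(m.alpha + 1), rel=1e-3)

    def test_large_alpha_limit_is_exponential(self):
        m = sd.model_from_moments(75, 0.075)  # rho = 1e-3
        ls = np.linspace(0, 20, 50)
        expected = m.mean_beta * np.exp(-m.mean_beta * ls)
        np.testing.assert_allclose(ss.marginal_interval_pdf(m, ls), expected, rtol=1e-3)

    def test_discrete_pmf_sums_to_one_and_matches_tail(self):
        m = sd.model_from_moments(75, 9)
        pmf = ss.marginal_interval_pmf(m, 200)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(np.diff(pmf) < 0)


class TestQExponential:
    def test_normalization_and_mean_rate(self):
        q = 1.05
        ls = np.linspace(0, 1e5, 10**6)
        dens = sd.q_exponential_pdf(q, 75.0, ls)
        assert np.trapezoid(dens, ls) == pytest.approx(1.0, abs=1e-3)

    def test_q_to_one_limit(self):
        ls = np.linspace(0, 20, 100)
        rate = 0.5
        near = sd.q_exponential_pdf(1 + 1e-9, 75.0, ls)
        expo = rate * np.exp(-rate * ls)
        np.testing.assert_allclose(near, expo, rtol=1e-6)

    def test_tail_agreement_with_mixture(self):
        m = sd.model_from_moments(75, 9)
        q = 1 + 1 / (m.alpha + 1)
        l = 10.0 / m.mean_beta
        ratio = sd.q_exponential_pdf(q, 75.0, l) / ss.marginal_interval_pdf(m, l)
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_q_out_of_range(self):
        with pytest.raises(ValueError):
            sd.q_exponential_pdf(2.3, 75.0, 1.0)
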
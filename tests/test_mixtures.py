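import math

import numpy as np
import pytest
from scipy import integrate, stats

from corefit.mixtures import (
    GammaPosterior,
    GIGPosterior,
    MixtureParams,
    draw_mixing_scales,
    expected_scale,
    log_density,
    mixing_log_density,
    sample_scale,
    scale_posterior,
    total_neg_log_likelihood,
)


def _mixing_pdf(params, s):
    return np.exp(mixing_log_density(params, s))


def quadrature_log_density(params, r):
    """Independent oracle: numerically average N(d; 0, s⁻¹ I₃) over g(s)."""

    def integrand(s):
        return (s / (2 * np.pi)) ** 1.5 * np.exp(-s * r * r / 2) * _mixing_pdf(params, s)

    val, _ = integrate.quad(integrand, 0, np.inf, limit=400, epsabs=0.0, epsrel=1e-11)
    return np.log(val)


class TestLogDensity:
    def test_gauss_matches_isotropic_normal(self):
        tau = 2.7
        params = MixtureParams("gauss", 1.0, tau)
        d = np.array([0.3, -0.5, 1.1])
        expected = stats.multivariate_normal(np.zeros(3), np.eye(3) / tau).logpdf(d)
        assert log_density(params, np.linalg.norm(d)) == pytest.approx(expected)

    def test_student_matches_quadrature_at_zero(self):
        params = MixtureParams("student", 1.0, 1.0)
        assert float(log_density(params, 0.0)) == pytest.approx(
            quadrature_log_density(params, 0.0), abs=1e-8
        )

    @pytest.mark.parametrize("model,alpha,beta", [
        ("student", 1.0, 1.0), ("student", 3.2, 0.4), ("kdist", 2.0, 1.0),
        ("kdist", 0.8, 2.5),
    ])
    def test_heavy_tails_match_quadrature_on_grid(self, model, alpha, beta):
        params = MixtureParams(model, alpha, beta)
        for r in np.linspace(0.05, 6.0, 20):
            assert float(log_density(params, r)) == pytest.approx(
                quadrature_log_density(params, r), abs=1e-7
            )

    def test_laplace_closed_form_and_k_family_membership(self):
        lam = 1.7
        params = MixtureParams("laplace", 1.0, lam)
        r = np.array([0.0, 0.5, 2.0, 7.0])
        expected = 3 * np.log(lam) - np.log(8 * np.pi) - lam * r
        np.testing.assert_allclose(log_density(params, r), expected, rtol=1e-12)
        # the Laplace density is the K-family member with α=2, β=λ²/2
        np.testing.assert_allclose(
            log_density(params.as_kdist(), r[1:]), expected[1:], rtol=1e-9
        )

    @pytest.mark.parametrize("model,alpha,beta", [
        ("gauss", 1.0, 1.3), ("student", 1.5, 0.8), ("kdist", 2.2, 1.1),
        ("laplace", 1.0, 2.0),
    ])
    def test_normalised_over_3space(self, model, alpha, beta):
        params = MixtureParams(model, alpha, beta)

        def radial(r):
            return 4 * np.pi * r * r * np.exp(float(log_density(params, r)))

        total, _ = integrate.quad(radial, 0, np.inf, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_tail_dominance_over_gauss(self):
        # matched second moments: student α=3, β=2 has E‖d‖² = 3·β/(α−1) = 3
        student = MixtureParams("student", 3.0, 2.0)
        gauss = MixtureParams("gauss", 1.0, 1.0)  # E‖d‖² = 3
        r = np.linspace(4.0, 10.0, 30)  # beyond the crossover radius
        assert np.all(log_density(student, r) > log_density(gauss, r))

    def test_student_converges_to_gauss_as_alpha_grows(self):
        tau = 1.5
        gauss = MixtureParams("gauss", 1.0, tau)
        r = np.linspace(0.0, 3.0, 7)
        prev = np.inf
        for alpha in (10.0, 100.0, 1000.0):
            student = MixtureParams("student", alpha, alpha / tau)
            gap = np.max(np.abs(log_density(student, r) - log_density(gauss, r)))
            assert gap < prev
            prev = gap
        assert prev < 0.02  # convergence is O(1/alpha)

    def test_scale_mixture_identity_random_triples(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            model = rng.choice(["student", "kdist"])
            params = MixtureParams(model, rng.uniform(0.5, 4.0), rng.uniform(0.3, 3.0))
            r = rng.uniform(0.05, 5.0)
            assert float(log_density(params, r)) == pytest.approx(
                quadrature_log_density(params, r), abs=1e-7
            )


class TestScalePosterior:
    def test_student_direct_substitution(self):
        post = scale_posterior(MixtureParams("student", 1.0, 2.0), 2.0)
        assert isinstance(post, GammaPosterior)
        assert post.shape == pytest.approx(2.5)
        assert post.rate == pytest.approx(4.0)

    def test_kdist_product_identity_by_quadrature(self):
        # the conditional ∝ N(d;0,s⁻¹)·InvGamma(s;α,β) must equal the
        # returned GIG family pointwise after renormalisation
        alpha, beta, r = 2.0, 1.0, 1.0
        post = scale_posterior(MixtureParams("kdist", alpha, beta), r)
        assert isinstance(post, GIGPosterior)
        assert post.p == pytest.approx(1.5 - alpha)
        assert post.chi == pytest.approx(2.0 * beta)
        assert post.psi == pytest.approx(r * r)

        def product(s):
            return s**1.5 * np.exp(-s * r * r / 2) * s ** (-alpha - 1) * np.exp(-beta / s)

        def gig(s):
            return s ** (post.p - 1) * np.exp(-(post.chi / s + post.psi * s) / 2)

        zp, _ = integrate.quad(product, 0, np.inf)
        zg, _ = integrate.quad(gig, 0, np.inf)
        for s in [0.2, 0.7, 1.5, 4.0]:
            assert product(s) / zp == pytest.approx(gig(s) / zg, rel=1e-9)

    def test_gauss_and_laplace_refused(self):
        for model in ("gauss", "laplace"):
            with pytest.raises(ValueError, match="scale posterior"):
                scale_posterior(MixtureParams(model, 1.0, 1.0), 1.0)


class TestExpectedScale:
    def test_gamma_mean(self):
        assert expected_scale(GammaPosterior(2.5, 4.0)) == pytest.approx(0.625)

    @pytest.mark.parametrize("p,chi,psi", [(-0.5, 1.0, 2.0), (1.2, 0.3, 4.0), (-2.0, 5.0, 0.7)])
    def test_gig_mean_matches_quadrature(self, p, chi, psi):
        def f(s):
            return s ** (p - 1) * np.exp(-(chi / s + psi * s) / 2)

        z, _ = integrate.quad(f, 0, np.inf)
        m, _ = integrate.quad(lambda s: s * f(s), 0, np.inf)
        assert expected_scale(GIGPosterior(p, chi, psi)) == pytest.approx(m / z, abs=1e-8)

    def test_gig_large_chi_asymptotics(self):
        psi = 2.0
        for chi in (1e4, 1e6):
            ratio = expected_scale(GIGPosterior(-0.5, chi, psi)) / math.sqrt(chi / psi)
            assert ratio == pytest.approx(1.0, rel=5e-3)


class TestSampleScale:
    def test_gamma_law_of_large_numbers(self):
        rng = np.random.default_rng(0)
        post = GammaPosterior(2.5, 4.0)
        draws = np.array([sample_scale(post, rng) for _ in range(100_000)])
        se = draws.std() / math.sqrt(draws.size)
        assert abs(draws.mean() - 0.625) < 3 * se

    def test_gig_mean_matches_expected_scale(self):
        rng = np.random.default_rng(1)
        post = GIGPosterior(-0.5, 1.0, 2.0)
        draws = np.array([sample_scale(post, rng) for _ in range(100_000)])
        se = draws.std() / math.sqrt(draws.size)
        assert abs(draws.mean() - expected_scale(post)) < 3 * se

    def test_seeded_reproducibility(self):
        post = GIGPosterior(-0.5, 1.0, 2.0)
        a = sample_scale(post, np.random.default_rng(7))
        b = sample_scale(post, np.random.default_rng(7))
        assert a == b


class TestMixingDensity:
    def test_gamma_examples(self):
        assert float(
            mixing_log_density(MixtureParams("student", 1.0, 1.0), 1.0)
        ) == pytest.approx(-1.0)
        # mode of Gamma(2, 1) at s = 1
        s = np.linspace(0.2, 3.0, 200)
        vals = mixing_log_density(MixtureParams("student", 2.0, 1.0), s)
        assert s[np.argmax(vals)] == pytest.approx(1.0, abs=0.02)

    def test_invgamma_normalised(self):
        params = MixtureParams("kdist", 1.8, 0.9)
        total, _ = integrate.quad(lambda s: _mixing_pdf(params, s), 0, np.inf)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_generative_draws_match_density_moments(self):
        rng = np.random.default_rng(3)
        params = MixtureParams("student", 3.0, 1.5)
        draws = draw_mixing_scales(params, 200_000, rng)
        assert draws.mean() == pytest.approx(3.0 / 1.5, rel=0.02)


class TestTotalNegLogLikelihood:
    def test_gauss_is_weighted_rmsd_objective(self):
        tau = 0.8
        params = MixtureParams("gauss", 1.0, tau)
        norms = np.array([0.5, 1.5, 2.5])
        const = -norms.size * 1.5 * np.log(tau / (2 * np.pi))
        assert total_neg_log_likelihood(params, norms) == pytest.approx(
            0.5 * tau * np.sum(norms**2) + const
        )

    def test_laplace_is_euclidean_not_squared(self):
        lam = 2.0
        params = MixtureParams("laplace", 1.0, lam)
        norms = np.array([1.0, 3.0])
        const = -norms.size * (3 * np.log(lam) - np.log(8 * np.pi))
        assert total_neg_log_likelihood(params, norms) == pytest.approx(
            lam * norms.sum() + const
        )

    def test_additivity(self):
        params = MixtureParams("student", 1.3, 0.9)
        assert total_neg_log_likelihood(params, [0.4, 2.2]) == pytest.approx(
            total_neg_log_likelihood(params, [0.4])
            + total_neg_log_likelihood(params, [2.2])
        )


class TestParamsValidation:
    def test_rejects_bad_model(self):
        with pytest.raises(ValueError, match="unknown model"):
            MixtureParams("cauchy", 1.0, 1.0)

    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(ValueError):
            MixtureParams("student", -1.0, 1.0)
        with pytest.raises(ValueError):
            MixtureParams("student", 1.0, 0.0)
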
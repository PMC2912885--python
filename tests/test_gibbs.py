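import numpy as np
import pytest
from scipy import stats

import corefit.mixtures as mixtures
from corefit.em import Hyperprior, update_alpha
from corefit.geometry import RigidTransform, cross_moment, displacements, rotation_angle
from corefit.gibbs import (
    GibbsOptions,
    run_gibbs,
    sample_alpha,
    sample_beta,
    sample_rotation,
    sample_scales,
    sample_translation,
)
from corefit.io_structures import CoordinateSet, MatchedPair
from corefit.mixtures import MixtureParams, draw_mixing_scales
from corefit.synthetic import generate_pair, random_chain, random_rotation

from conftest import rotation_error_deg


class TestSampleRotation:
    def test_zero_moment_gives_haar_uniform(self):
        # under Haar measure E[trace R] = 0
        rng = np.random.default_rng(0)
        tr = np.array([np.trace(sample_rotation(np.zeros((3, 3)), rng))
                       for _ in range(20_000)])
        se = tr.std() / np.sqrt(tr.size)
        assert abs(tr.mean()) < 3 * se

    def test_concentration_increases_with_strength(self):
        rng = np.random.default_rng(1)
        means = []
        for c in (20.0, 200.0):
            ang = [
                rotation_angle(RigidTransform(sample_rotation(c * np.eye(3), rng),
                                              np.zeros(3)))
                for _ in range(1500)
            ]
            means.append(np.mean(ang))
        assert means[0] > means[1]
        assert means[1] < 15.0

    def test_matches_importance_reweighted_uniform(self):
        # brute-force oracle: uniform rotations reweighted by exp(tr(AᵀR)),
        # compared on the statistic tr(AᵀR) via a two-sample KS test
        rng = np.random.default_rng(2)
        A = np.array([[2.0, 0.5, 0.0], [-0.3, 1.0, 0.4], [0.2, 0.0, 1.5]])
        draws = np.array([
            float(np.sum(A * sample_rotation(A, rng))) for _ in range(4000)
        ])
        uni = np.array([float(np.sum(A * random_rotation(rng))) for _ in range(200_000)])
        w = np.exp(uni - uni.max())
        w /= w.sum()
        resampled = rng.choice(uni, size=4000, p=w)
        assert stats.ks_2samp(draws, resampled).pvalue > 0.01

    def test_returns_proper_rotation(self):
        rng = np.random.default_rng(3)
        for c in (0.0, 1.0, 500.0):
            R = sample_rotation(c * np.eye(3), rng)
            np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-10)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)


def _pair_from(x, y):
    ids = np.arange(1, x.shape[0] + 1)
    return MatchedPair(CoordinateSet(x, ids), CoordinateSet(y, ids))


class TestSampleTranslation:
    def test_concentrates_on_true_translation(self):
        rng = np.random.default_rng(4)
        x = random_chain(20, rng)
        t_true = np.array([3.0, -2.0, 5.0])
        pair = _pair_from(x, x + t_true)
        draws = np.array([
            sample_translation(pair, np.eye(3), np.full(20, 1e6), 100.0, rng)
            for _ in range(200
        )])
        assert np.max(np.abs(draws.mean(0) - t_true)) < 0.01
        assert draws.std(0).max() < 0.01

    def test_mean_matches_weighted_least_squares(self):
        rng = np.random.default_rng(5)
        x = random_chain(10, rng)
        y = x + rng.normal(size=(10, 3))
        s = rng.gamma(2.0, size=10)
        pair = _pair_from(x, y)
        draws = np.array([
            sample_translation(pair, np.eye(3), s, 1e9, rng) for _ in range(20_000)
        ])
        ls = (s[:, None] * (y - x)).sum(0) / s.sum()  # flat-prior solution
        assert np.max(np.abs(draws.mean(0) - ls)) < 4 * draws.std(0).max() / np.sqrt(20_000)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(6)
        x = random_chain(5, rng)
        pair = _pair_from(x, x + 1.0)
        a = sample_translation(pair, np.eye(3), np.ones(5), 10.0, np.random.default_rng(1))
        b = sample_translation(pair, np.eye(3), np.ones(5), 10.0, np.random.default_rng(1))
        np.testing.assert_array_equal(a, b)


class TestSampleAlpha:
    @pytest.mark.parametrize("model", ["student", "kdist"])
    def test_matches_quadrature_target(self, model):
        rng = np.random.default_rng(7)
        scales = rng.gamma(2.0, size=15) + 0.1
        hyper = Hyperprior(2.0, 1.0, 2.0, 1.0)
        params = MixtureParams(model, 1.0, 1.3)
        draws = np.array([
            sample_alpha(params, scales, hyper, rng) for _ in range(5000)
        ])

        sign = 1.0 if model == "student" else -1.0
        ls = float(np.log(scales).sum())
        n = scales.size

        def logpost(a):
            return (
                n * a * np.log(params.beta)
                - n * _lgamma(a)
                + sign * a * ls
                + (hyper.alpha_shape - 1) * np.log(a)
                - hyper.alpha_rate * a
            )

        grid = np.linspace(1e-4, draws.max() * 2.5, 4000)
        lp = logpost(grid)
        pdf = np.exp(lp - lp.max())
        cdf = np.cumsum(pdf)
        cdf /= cdf[-1]

        def cdf_fn(v):
            return np.interp(v, grid, cdf)

        assert stats.kstest(draws, cdf_fn).pvalue > 0.01

    def test_mode_near_em_root(self):
        rng = np.random.default_rng(8)
        scales = rng.gamma(3.0, size=50) + 0.1
        hyper = Hyperprior()
        params = MixtureParams("student", 1.0, 1.0)
        root = update_alpha(params, scales, hyper)
        draws = np.array([
            sample_alpha(params, scales, hyper, rng) for _ in range(3000)
        ])
        # posterior is near-symmetric at N=50: median sits close to the mode
        assert abs(np.median(draws) - root) < draws.std()

    def test_seeded_reproducibility(self):
        scales = np.array([0.5, 1.0, 2.0, 4.0])
        params = MixtureParams("student", 1.0, 1.0)
        a = sample_alpha(params, scales, Hyperprior(), np.random.default_rng(3))
        b = sample_alpha(params, scales, Hyperprior(), np.random.default_rng(3))
        assert a == b


def _lgamma(a):
    from scipy.special import gammaln

    return gammaln(a)


class TestSampleBeta:
    @pytest.mark.parametrize("model", ["student", "kdist"])
    def test_mean_matches_conjugate_posterior(self, model):
        rng = np.random.default_rng(9)
        scales = rng.gamma(2.0, size=12) + 0.2
        hyper = Hyperprior(0.5, 0.4, 0.5, 0.4)
        params = MixtureParams(model, 1.6, 1.0)
        draws = np.array([
            sample_beta(params, scales, hyper, rng) for _ in range(100_000)
        ])
        n = scales.size
        shape = n * params.alpha + hyper.beta_shape
        rate = (scales.sum() if model == "student" else (1 / scales).sum()) + hyper.beta_rate
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - shape / rate) < 3 * se

    def test_collapses_to_hyperprior_without_scales(self):
        rng = np.random.default_rng(10)
        hyper = Hyperprior(2.0, 3.0, 2.0, 3.0)
        params = MixtureParams("student", 1.0, 1.0)
        draws = np.array([
            sample_beta(params, np.empty(0), hyper, rng) for _ in range(50_000)
        ])
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - 2.0 / 3.0) < 3 * se


class TestSampleScales:
    @pytest.mark.parametrize("model", ["student", "kdist"])
    def test_matches_conditional_target_by_ks(self, model):
        rng = np.random.default_rng(11)
        params = MixtureParams(model, 1.4, 0.9)
        r = 1.7
        draws = np.array([
            sample_scales(params, np.array([r]), rng)[0] for _ in range(5000)
        ])

        def product(s):
            return (
                s**1.5 * np.exp(-s * r * r / 2)
                * np.exp(mixtures.mixing_log_density(params, s))
            )

        grid = np.linspace(1e-6, draws.max() * 2.5, 4000)
        pdf = product(grid)
        cdf = np.cumsum(pdf)
        cdf /= cdf[-1]
        assert stats.kstest(draws, lambda v: np.interp(v, grid, cdf)).pvalue > 0.01


class TestRunGibbs:
    def test_recovery_on_student_data(self):
        pair, truth = generate_pair(200, model="student", seed=5)
        chain = run_gibbs(pair, "student", GibbsOptions(n_samples=200, burn_in=50, seed=2))
        errs = [rotation_error_deg(T.rotation, truth.transform.rotation)
                for T in chain.transforms]
        assert np.mean(errs) < 2.0
        lo, hi = np.percentile(chain.alphas, [2.5, 97.5])
        assert lo < truth.params.alpha < hi

    def test_exact_reproducibility_from_seed(self):
        pair, _ = generate_pair(50, seed=6)
        opts = GibbsOptions(n_samples=20, burn_in=5, seed=9)
        c1 = run_gibbs(pair, "kdist", opts)
        c2 = run_gibbs(pair, "kdist", opts)
        np.testing.assert_array_equal(c1.log_likelihoods, c2.log_likelihoods)
        np.testing.assert_array_equal(c1.scales, c2.scales)

    def test_posterior_spread_shrinks_with_n(self):
        spreads = []
        for n in (50, 200):
            pair, truth = generate_pair(n, model="gauss",
                                        params=MixtureParams("gauss", 1.0, 4.0), seed=7)
            chain = run_gibbs(pair, "gauss", GibbsOptions(n_samples=150, burn_in=50, seed=3))
            errs = [rotation_error_deg(T.rotation, truth.transform.rotation)
                    for T in chain.transforms]
            spreads.append(np.std(errs) + np.mean(errs))
        assert spreads[1] < spreads[0]

    def test_chain_export_table(self, tmp_path):
        pair, _ = generate_pair(30, seed=8)
        chain = run_gibbs(pair, "student", GibbsOptions(n_samples=12, burn_in=3, seed=4))
        out = tmp_path / "chain.tsv"
        chain.export_table(out)
        lines = out.read_text().splitlines()
        assert len(lines) == 13  # header + 12 samples
        assert len(lines[1].split("\t")) == 15

    def test_stored_rotations_are_proper(self):
        pair, _ = generate_pair(30, seed=9)
        chain = run_gibbs(pair, "laplace", GibbsOptions(n_samples=10, burn_in=2, seed=5))
        for T in chain.transforms:
            np.testing.assert_allclose(T.rotation.T @ T.rotation, np.eye(3), atol=1e-9)


class TestJointCorrectness:
    """Geweke-style successive-conditional test: alternating forward data
    simulation with Gibbs parameter sweeps must leave the prior invariant,
    so the marginal moments of α and β must match their hyperprior."""

    @pytest.mark.parametrize("model", ["student", "kdist"])
    def test_alpha_beta_marginals_match_hyperprior(self, model):
        rng = np.random.default_rng(0 if model == "student" else 1)
        n = 5
        x = random_chain(n, rng)
        xs = CoordinateSet(x, np.arange(1, n + 1))
        hyper = Hyperprior(4.0, 2.0, 4.0, 2.0)  # prior mean 2, variance 1
        prior_sd = 5.0
        alpha, beta = rng.gamma(4.0) / 2.0, rng.gamma(4.0) / 2.0
        R, t = random_rotation(rng), rng.normal(scale=prior_sd, size=3)
        alphas, betas = [], []
        for _ in range(5000):
            params = MixtureParams(model, alpha, beta)
            s = draw_mixing_scales(params, n, rng)
            d = rng.normal(size=(n, 3)) / np.sqrt(s)[:, None]
            pair = _pair_from(x, x @ R.T + t + d)
            scales = sample_scales(params, np.linalg.norm(d, axis=1), rng)
            R = sample_rotation(cross_moment(pair, scales), rng)
            t = sample_translation(pair, R, scales, prior_sd, rng)
            norms = displacements(pair, RigidTransform(R, t)).norms
            scales = sample_scales(params, norms, rng)
            beta = sample_beta(params, scales, hyper, rng)
            params = MixtureParams(model, alpha, beta)
            alpha = sample_alpha(params, scales, hyper, rng)
            alphas.append(alpha)
            betas.append(beta)
        for v in (np.array(alphas[500:]), np.array(betas[500:])):
            batches = np.array([b.mean() for b in np.array_split(v, 30)])
            se = batches.std(ddof=1) / np.sqrt(30)
            assert abs(v.mean() - 2.0) < 5 * se
            assert v.var() == pytest.approx(1.0, abs=0.2)
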
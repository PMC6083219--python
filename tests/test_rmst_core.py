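"""Tests for the restricted multivariate skew-t kernel.

Oracles: 2-D quadrature over the mixing variables of the stochastic
representation for the density; large Monte Carlo samples (with batch-based
standard errors) for the moment formulas; scipy's multivariate t / normal
for the symmetric special cases.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from skewtlst.rmst_core import (
    RmstParams,
    bfactor,
    linear_combination,
    rmst_logpdf,
    rmst_moments,
    rmst_sample,
)


def uni(mu=0.0, sigma2=1.0, delta=0.0, nu=5.0) -> RmstParams:
    return RmstParams(mu=[mu], sigma=[[sigma2]], delta=[delta], nu=nu)


def quadrature_pdf(y: float, sigma2: float, delta: float, nu: float) -> float:
    """Density by integrating the half-normal x gamma mixing representation."""

    def integrand(w, u):
        cond = stats.norm.pdf(y, loc=delta * u / np.sqrt(w), scale=np.sqrt(sigma2 / w))
        return cond * 2.0 * stats.norm.pdf(u) * stats.gamma.pdf(w, a=nu / 2, scale=2 / nu)

    val, _ = integrate.dblquad(integrand, 0, np.inf, 0, np.inf, epsabs=1e-10)
    return val


def batch_se(x: np.ndarray, statistic, n_batches: int = 100) -> float:
    """Monte Carlo SE of a sample statistic via batching."""
    batches = np.array_split(x, n_batches)
    vals = np.array([statistic(b) for b in batches])
    return float(vals.std(ddof=1) / np.sqrt(n_batches))


class TestParams:
    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            RmstParams(mu=[0, 0], sigma=[[1]], delta=[0, 0], nu=5)

    def test_nonpd_sigma_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            RmstParams(mu=[0, 0], sigma=[[1, 2], [2, 1]], delta=[0, 0], nu=5)

    def test_asymmetric_sigma_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            RmstParams(mu=[0, 0], sigma=[[1, 0.5], [0.2, 1]], delta=[0, 0], nu=5)

    def test_low_nu_rejected(self):
        with pytest.raises(ValueError, match="nu"):
            uni(nu=2.0)

    def test_bfactor_value(self):
        # b_5 = sqrt(5/pi) * Gamma(2) / Gamma(2.5)
        expected = np.sqrt(5 / np.pi) * 1.0 / (3 * np.sqrt(np.pi) / 4)
        assert bfactor(5.0) == pytest.approx(expected, rel=1e-12)


class TestSampler:
    def test_normal_limit_mean_variance(self):
        x = rmst_sample(uni(nu=10000.0), 1_000_000, seed=0)[:, 0]
        assert abs(x.mean()) < 3 * x.std() / 1000
        assert x.var() == pytest.approx(1.0, abs=0.01)

    def test_t_variance(self):
        x = rmst_sample(uni(nu=5.0), 1_000_000, seed=1)[:, 0]
        assert x.var() == pytest.approx(5.0 / 3.0, abs=3 * batch_se(x, np.var))

    def test_skew_mean_matches_b_nu_delta(self):
        x = rmst_sample(uni(delta=2.8, nu=5.0), 1_000_000, seed=2)[:, 0]
        assert x.mean() == pytest.approx(bfactor(5.0) * 2.8, abs=3 * x.std() / 1000)
        assert x.mean() == pytest.approx(2.657, abs=0.01)

    def test_determinism(self):
        p = uni(delta=1.0, nu=6.0)
        a = rmst_sample(p, 100, seed=42)
        b = rmst_sample(p, 100, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_n_must_be_positive(self):
        with pytest.raises(ValueError):
            rmst_sample(uni(), 0, seed=0)

    @pytest.mark.parametrize("delta,sign", [(2.0, 1), (-2.0, -1)])
    def test_skew_sign_convention(self, delta, sign):
        x = rmst_sample(uni(delta=delta, nu=8.0), 200_000, seed=3)[:, 0]
        assert np.sign(stats.skew(x)) == sign


class TestLogpdf:
    def test_standard_normal_value(self):
        assert rmst_logpdf(uni(nu=10000.0), np.array([0.0])) == pytest.approx(
            -0.9189385, abs=1e-3
        )

    @pytest.mark.parametrize("delta", [0.0, 2.8, 6.0])
    @pytest.mark.parametrize("nu", [5.0, 30.0, 10000.0])
    def test_normalization(self, delta, nu):
        p = uni(delta=delta, nu=nu)
        val, _ = integrate.quad(
            lambda y: np.exp(rmst_logpdf(p, np.array([y]))),
            -80,
            200,
            limit=400,
        )
        assert val == pytest.approx(1.0, abs=1e-4)

    def test_quadrature_oracle(self):
        p = uni(delta=2.8, nu=5.0)
        got = np.exp(rmst_logpdf(p, np.array([0.5])))
        want = quadrature_pdf(0.5, 1.0, 2.8, 5.0)
        assert got == pytest.approx(want, abs=1e-4)

    def test_reduces_to_multivariate_t(self):
        mu = np.array([0.5, -1.0, 2.0])
        sigma = np.array([[2.0, 0.3, 0.0], [0.3, 1.0, 0.2], [0.0, 0.2, 1.5]])
        p = RmstParams(mu=mu, sigma=sigma, delta=np.zeros(3), nu=7.0)
        y = np.array([[0.0, 0.0, 0.0], [1.0, -2.0, 3.0]])
        want = stats.multivariate_t(loc=mu, shape=sigma, df=7.0).logpdf(y)
        got = rmst_logpdf(p, y)
        np.testing.assert_allclose(got, want, rtol=1e-8)

    def test_reduces_to_multivariate_normal(self):
        mu = np.array([0.5, -1.0])
        sigma = np.array([[2.0, 0.3], [0.3, 1.0]])
        p = RmstParams(mu=mu, sigma=sigma, delta=np.zeros(2), nu=10000.0)
        y = np.array([0.2, 0.4])
        want = stats.multivariate_normal(mean=mu, cov=sigma).logpdf(y)
        assert rmst_logpdf(p, y) == pytest.approx(want, abs=1e-3)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="columns"):
            rmst_logpdf(uni(), np.array([0.0, 1.0]))

    def test_finite_and_continuous(self):
        p = uni(delta=6.0, nu=5.0)
        grid = np.linspace(-50, 100, 2001)[:, None]
        vals = rmst_logpdf(p, grid)
        assert np.all(np.isfinite(vals))
        assert np.max(np.abs(np.diff(vals))) < 1.0

    def test_sampler_density_agreement_gof(self):
        """KS test of 1e5 draws against the numerically integrated CDF."""
        p = uni(delta=2.8, nu=5.0)
        x = rmst_sample(p, 100_000, seed=7)[:, 0]
        grid = np.linspace(x.min() - 1, x.max() + 1, 4000)
        pdf = np.exp(rmst_logpdf(p, grid[:, None]))
        cdf_grid = integrate.cumulative_trapezoid(pdf, grid, initial=0.0)
        cdf_grid /= cdf_grid[-1]
        res = stats.ks_1samp(x, lambda q: np.interp(q, grid, cdf_grid))
        assert res.pvalue > 0.01


class TestMoments:
    def test_normal_limit(self):
        mu = np.array([1.0, 2.0])
        sigma = np.array([[1.0, 0.2], [0.2, 2.0]])
        p = RmstParams(mu=mu, sigma=sigma, delta=np.zeros(2), nu=10000.0)
        mean, cov, skew = rmst_moments(p)
        np.testing.assert_allclose(mean, mu)
        np.testing.assert_allclose(cov, sigma, rtol=1e-3)
        np.testing.assert_allclose(skew, 0.0, atol=1e-3)

    def test_symmetric_t(self):
        mean, cov, skew = rmst_moments(uni(nu=5.0))
        assert mean[0] == 0.0
        assert cov[0, 0] == pytest.approx(5.0 / 3.0)
        assert skew[0] == pytest.approx(0.0, abs=1e-12)

    def test_sampling_oracle_delta6(self):
        p = uni(delta=6.0, nu=5.0)
        mean, cov, skew = rmst_moments(p)
        x = rmst_sample(p, 1_000_000, seed=11)[:, 0]
        assert mean[0] == pytest.approx(x.mean(), abs=3 * batch_se(x, np.mean))
        assert cov[0, 0] == pytest.approx(x.var(), abs=3 * batch_se(x, np.var))
        assert skew[0] == pytest.approx(
            stats.skew(x), abs=3 * batch_se(x, stats.skew)
        )

    def test_sampling_oracle_delta28(self):
        p = uni(delta=2.8, nu=5.0)
        mean, cov, skew = rmst_moments(p)
        x = rmst_sample(p, 1_000_000, seed=12)[:, 0]
        assert mean[0] == pytest.approx(x.mean(), abs=3 * batch_se(x, np.mean))
        assert cov[0, 0] == pytest.approx(x.var(), abs=3 * batch_se(x, np.var))
        assert skew[0] == pytest.approx(
            stats.skew(x), abs=3 * batch_se(x, stats.skew)
        )

    def test_skew_undefined_below_nu3(self):
        _, _, skew = rmst_moments(uni(delta=1.0, nu=2.5))
        assert np.isnan(skew[0])

    def test_covariance_psd_and_monotone(self):
        p_small = uni(sigma2=1.0, delta=2.0, nu=5.0)
        p_large = uni(sigma2=2.0, delta=2.0, nu=5.0)
        _, cov_s, _ = rmst_moments(p_small)
        _, cov_l, _ = rmst_moments(p_large)
        assert cov_l[0, 0] > cov_s[0, 0]
        mu = np.zeros(2)
        sigma = np.array([[1.0, 0.3], [0.3, 1.0]])
        _, cov, _ = rmst_moments(RmstParams(mu, sigma, np.array([2.0, -1.0]), 5.0))
        assert np.all(np.linalg.eigvalsh(cov) > -1e-10)

    @given(
        delta=st.floats(-4, 4),
        nu=st.floats(3.2, 50),
        sigma2=st.floats(0.1, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_skew_sign_follows_delta(self, delta, nu, sigma2):
        _, _, skew = rmst_moments(uni(sigma2=sigma2, delta=delta, nu=nu))
        if delta == 0:
            assert skew[0] == pytest.approx(0.0, abs=1e-12)
        else:
            assert np.sign(skew[0]) == np.sign(delta)


class TestLinearCombination:
    def test_matches_projected_sample(self):
        mu = np.array([1.0, -0.5])
        sigma = np.array([[1.0, 0.4], [0.4, 2.0]])
        delta = np.array([2.0, 1.0])
        p = RmstParams(mu, sigma, delta, 6.0)
        a = np.array([0.7, -1.2])
        proj = linear_combination(p, a)
        x = rmst_sample(p, 500_000, seed=21) @ a
        mean, cov, skew = rmst_moments(proj)
        assert mean[0] == pytest.approx(x.mean(), abs=3 * batch_se(x, np.mean))
        assert cov[0, 0] == pytest.approx(x.var(), abs=3 * batch_se(x, np.var))
        assert skew[0] == pytest.approx(stats.skew(x), abs=3 * batch_se(x, stats.skew))
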
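"""Restricted multivariate skew-t (rMST) distribution.

The rMST family is parameterized by a location vector ``mu`` (length p), a
symmetric positive-definite scale matrix ``Sigma`` (p x p), a skewness vector
``delta`` (length p) and a degrees-of-freedom scalar ``nu``.  It admits the
stochastic representation

    Y = mu + (delta * |U0| + U1) / sqrt(W),

with ``U0`` standard normal, ``U1 ~ N_p(0, Sigma)`` and
``W ~ Gamma(nu/2, rate=nu/2)``, all independent.  Setting ``delta = 0``
recovers the multivariate t distribution; letting ``nu`` grow large recovers
the (restricted) skew-normal; both together give the multivariate normal.

The closed-form density follows from the representation: with
``Omega = Sigma + delta delta'`` it is twice a p-variate t density times a
univariate t CDF factor.  Moment formulas use
``b_nu = sqrt(nu/pi) * Gamma((nu-1)/2) / Gamma(nu/2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats
from scipy.special import gammaln, stdtr

__all__ = [
    "NU_MIN",
    "NU_NORMAL_LIMIT",
    "RmstParams",
    "bfactor",
    "linear_combination",
    "rmst_logpdf",
    "rmst_moments",
    "rmst_sample",
]

# Degrees-of-freedom domain used throughout estimation and sampling: moment
# formulas need nu > 2, and nu = 10000 is treated as the normal-tail limit.
NU_MIN = 2.1
NU_NORMAL_LIMIT = 10000.0


@dataclass(frozen=True, eq=False)
class RmstParams:
    """Parameter set of one rMST component.

    Parameters
    ----------
    mu : array-like, shape (p,)
        Location vector.
    sigma : array-like, shape (p, p)
        Symmetric positive-definite scale matrix.
    delta : array-like, shape (p,)
        Skewness vector; positive entries skew the corresponding margin to
        the right (positive sample skewness).
    nu : float
        Degrees of freedom, must exceed 2.
    """

    mu: np.ndarray
    sigma: np.ndarray
    delta: np.ndarray
    nu: float
    _chol_omega: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))
        delta = np.atleast_1d(np.asarray(self.delta, dtype=float))
        p = mu.shape[0]
        if mu.ndim != 1 or delta.shape != (p,) or sigma.shape != (p, p):
            raise ValueError(
                f"dimension mismatch: mu {mu.shape}, sigma {sigma.shape}, "
                f"delta {delta.shape}"
            )
        if not np.allclose(sigma, sigma.T, atol=1e-10):
            raise ValueError("sigma must be symmetric")
        if not self.nu > 2.0:
            raise ValueError(f"nu must exceed 2, got {self.nu}")
        omega = sigma + np.outer(delta, delta)
        try:
            chol = linalg.cholesky(omega, lower=True)
            # sigma itself must be PD as well (omega PD does not imply it)
            linalg.cholesky(sigma, lower=True)
        except linalg.LinAlgError as exc:
            raise ValueError("sigma must be positive definite") from exc
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "delta", delta)
        object.__setattr__(self, "nu", float(self.nu))
        object.__setattr__(self, "_chol_omega", chol)

    @property
    def p(self) -> int:
        return self.mu.shape[0]

    @property
    def omega(self) -> np.ndarray:
        """Scale matrix of the embedding t distribution, Sigma + delta delta'."""
        return self.sigma + np.outer(self.delta, self.delta)


def bfactor(nu: float) -> float:
    """Scaling constant b_nu = sqrt(nu/pi) * Gamma((nu-1)/2) / Gamma(nu/2)."""
    if not nu > 1:
        raise ValueError("bfactor requires nu > 1")
    return float(
        np.sqrt(nu / np.pi) * np.exp(gammaln((nu - 1.0) / 2.0) - gammaln(nu / 2.0))
    )


def rmst_sample(
    params: RmstParams, n: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Draw ``n`` i.i.d. rMST vectors, one per row.

    Uses the half-normal + gamma mixing representation.  Reproducible given
    an integer ``seed``; an existing :class:`numpy.random.Generator` may be
    passed instead to share a stream.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = params.p
    chol_sigma = linalg.cholesky(params.sigma, lower=True)
    u0 = np.abs(rng.standard_normal(n))
    u1 = rng.standard_normal((n, p)) @ chol_sigma.T
    w = rng.gamma(shape=params.nu / 2.0, scale=2.0 / params.nu, size=n)
    return params.mu + (params.delta * u0[:, None] + u1) / np.sqrt(w)[:, None]


def rmst_logpdf(params: RmstParams, y: np.ndarray) -> np.ndarray | float:
    """Log-density of the rMST distribution.

    ``y`` may be a single length-p vector or an (n, p) matrix; the return is
    a scalar or a length-n vector accordingly.
    """
    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    y2 = np.atleast_2d(y)
    if y2.shape[1] != params.p:
        raise ValueError(f"y has {y2.shape[1]} columns, expected {params.p}")
    out = _logpdf_raw(
        params.mu, params.delta, params.nu, y2, chol_omega=params._chol_omega
    )
    return float(out[0]) if single else out


def _logpdf_raw(
    mu: np.ndarray,
    delta: np.ndarray,
    nu: float,
    y2: np.ndarray,
    sigma: np.ndarray | None = None,
    chol_omega: np.ndarray | None = None,
) -> np.ndarray:
    """Unvalidated vectorized log-density (hot path for the likelihood).

    Raises :class:`numpy.linalg.LinAlgError` for a non-PD Omega; callers on
    the fitting path translate that into an infinite penalty.
    """
    p = mu.shape[0]
    if chol_omega is None:
        chol_omega = np.linalg.cholesky(sigma + np.outer(delta, delta))
    z = y2 - mu
    # solve L x = z'  => x = L^-1 (y-mu)';  Q = ||x||^2 row-wise
    x = linalg.solve_triangular(chol_omega, z.T, lower=True, check_finite=False)
    q = np.einsum("ij,ij->j", x, x)
    logdet = 2.0 * np.sum(np.log(np.diag(chol_omega)))
    log_t = (
        gammaln((nu + p) / 2.0)
        - gammaln(nu / 2.0)
        - 0.5 * p * np.log(nu * np.pi)
        - 0.5 * logdet
        - 0.5 * (nu + p) * np.log1p(q / nu)
    )
    # skewing factor: T_1( a'z * sqrt((nu+p)/(nu+Q)); nu+p )
    half = linalg.solve_triangular(chol_omega, delta, lower=True, check_finite=False)
    oinv_delta = linalg.solve_triangular(
        chol_omega.T, half, lower=False, check_finite=False
    )
    denom = 1.0 - delta @ oinv_delta
    # denom = 1/(1 + delta' Sigma^-1 delta) in exact arithmetic, always > 0
    denom = max(denom, np.finfo(float).tiny)
    lin = (z @ oinv_delta) / np.sqrt(denom)
    arg = lin * np.sqrt((nu + p) / (nu + q))
    return np.log(2.0) + log_t + _t_logcdf(arg, nu + p)


def _t_logcdf(x: np.ndarray, df: float) -> np.ndarray:
    """log of the Student-t CDF; fast C path, exact-tail fallback.

    ``stdtr`` underflows to 0 only in the extreme left tail at large df;
    those entries are recomputed with scipy's asymptotic logcdf.
    """
    cdf = stdtr(df, x)
    with np.errstate(divide="ignore"):
        out = np.log(cdf)
    bad = ~np.isfinite(out)
    if np.any(bad):
        out[bad] = stats.t.logcdf(np.asarray(x)[bad], df=df)
    return out


def rmst_moments(
    params: RmstParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean vector, covariance matrix and componentwise univariate skewness.

    mean = mu + b_nu * delta,
    cov  = nu/(nu-2) * (Sigma + delta delta') - b_nu^2 * delta delta'.

    Skewness of margin k comes from the raw moments of the univariate rMST
    with parameters (mu_k, Sigma_kk, delta_k, nu); it requires nu > 3 and is
    reported as NaN otherwise.
    """
    nu = params.nu
    if not nu > 2.0:
        raise ValueError("covariance undefined for nu <= 2")
    b = bfactor(nu)
    mean = params.mu + b * params.delta
    dd = np.outer(params.delta, params.delta)
    cov = nu / (nu - 2.0) * (params.sigma + dd) - b * b * dd
    skew = np.full(params.p, np.nan)
    if nu > 3.0:
        c = np.sqrt(2.0 / np.pi)
        # E[W^{-3/2}] for W ~ Gamma(nu/2, rate nu/2)
        kappa3 = (nu / 2.0) ** 1.5 * np.exp(gammaln((nu - 3.0) / 2.0) - gammaln(nu / 2.0))
        d = params.delta
        s2 = np.diag(params.sigma)
        m1 = b * d
        m2 = nu / (nu - 2.0) * (s2 + d * d)
        m3 = c * (2.0 * d**3 + 3.0 * d * s2) * kappa3
        mu3 = m3 - 3.0 * m1 * m2 + 2.0 * m1**3
        var = m2 - m1 * m1
        skew = mu3 / var**1.5
    return mean, cov, skew


def linear_combination(params: RmstParams, a: np.ndarray) -> RmstParams:
    """Distribution of the scalar a'Y: univariate rMST with mapped parameters."""
    a = np.asarray(a, dtype=float)
    if a.shape != (params.p,):
        raise ValueError("a must have length p")
    return RmstParams(
        mu=np.array([a @ params.mu]),
        sigma=np.array([[a @ params.sigma @ a]]),
        delta=np.array([a @ params.delta]),
        nu=params.nu,
    )
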
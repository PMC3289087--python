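"""Probability primitives used by the Gibbs sampler.

Only the handful of distributions the model is actually built from live here:
the rectified Gaussian (point mass at zero plus a positive Gaussian branch),
a numerically robust lower-truncated Gaussian sampler, and the conjugate
Normal-Inverse-Gamma (NIG) machinery whose marginal predictive is a Student-t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "RectifiedGaussianParams",
    "NIGParams",
    "cut",
    "rectified_gaussian_sample",
    "rectified_gaussian_mean",
    "truncated_gaussian_sample",
    "nig_posterior",
    "student_t_predictive",
    "student_t_logpdf",
    "truncated_student_t_sample",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class RectifiedGaussianParams:
    """Location/variance of the latent Gaussian whose rectification is observed.

    The rectified Gaussian is the law of ``max(0, s)`` with
    ``s ~ Normal(mu, var)``: a point mass at zero of weight ``Phi(-mu/sigma)``
    plus the positive branch of the Gaussian density.  Unlike a truncated
    Gaussian it retains the zero state, which is how a fully suppressed TF is
    represented.
    """

    mu: float
    var: float

    def __post_init__(self) -> None:
        if not self.var > 0:
            raise ValueError(f"var must be positive, got {self.var}")


@dataclass(frozen=True)
class NIGParams:
    """Normal-Inverse-Gamma prior for a Gaussian (mean, variance) pair.

    Parameterization: ``sigma^2 ~ InvGamma(a0, b0)`` and
    ``mu | sigma^2 ~ Normal(m0, sigma^2 / k0)``.  ``k0`` is the prior-mean
    precision scale (the lambda_0 hyperparameter of the graphical model).
    """

    m0: float = 0.0
    k0: float = 1.0
    a0: float = 2.0
    b0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k0", "a0", "b0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")


def cut(v):
    """Component-wise rectification: ``max(v, 0)`` elementwise. Idempotent."""
    return np.maximum(np.asarray(v, dtype=float), 0.0)


def rectified_gaussian_sample(
    params: RectifiedGaussianParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` variates of ``cut(s)``, ``s ~ Normal(mu, var)``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    s = rng.normal(params.mu, math.sqrt(params.var), size=n)
    return cut(s)


def rectified_gaussian_mean(params: RectifiedGaussianParams) -> float:
    """E[cut(s)] = mu * Phi(mu/sigma) + sigma * phi(mu/sigma)."""
    sigma = math.sqrt(params.var)
    z = params.mu / sigma
    return params.mu * special.ndtr(z) + sigma * math.exp(-0.5 * z * z) / _SQRT_2PI


def _truncated_std_normal(alpha: float, rng: np.random.Generator) -> float:
    """Standard normal conditioned on exceeding ``alpha``.

    Inverse-CDF in the bulk; Robert's exponential rejection in the far right
    tail where the inverse CDF loses all precision.
    """
    if alpha < -8.0:
        # truncation point far in the left tail: plain Gaussian draw suffices,
        # but keep rejecting the (astronomically rare) violations for safety
        while True:
            z = rng.standard_normal()
            if z > alpha:
                return z
    if alpha < 4.0:
        # u uniform on (Phi(alpha), 1); use the survival side for precision
        sf = special.ndtr(-alpha)  # P(Z > alpha)
        u = rng.uniform(0.0, sf)
        # z = Phi^{-1}(1 - u) computed via the complementary quantile
        return -special.ndtri(u) if u > 0 else alpha
    # Robert (1995) translated-exponential rejection
    a_star = 0.5 * (alpha + math.sqrt(alpha * alpha + 4.0))
    while True:
        z = alpha + rng.exponential(1.0 / a_star)
        d = z - a_star
        if rng.random() <= math.exp(-0.5 * d * d):
            return z


def truncated_gaussian_sample(
    mu: float, var: float, lower: float, rng: np.random.Generator
) -> float:
    """One draw of ``Normal(mu, var)`` conditioned on the value exceeding ``lower``."""
    if not var > 0:
        raise ValueError(f"var must be positive, got {var}")
    sigma = math.sqrt(var)
    if lower == -math.inf:
        return mu + sigma * rng.standard_normal()
    alpha = (lower - mu) / sigma
    return mu + sigma * _truncated_std_normal(alpha, rng)


def nig_posterior(prior: NIGParams, count: float, total: float, total_sq: float) -> NIGParams:
    """Conjugate NIG update from sufficient statistics (n, sum, sum of squares)."""
    kn = prior.k0 + count
    mn = (prior.k0 * prior.m0 + total) / kn
    an = prior.a0 + 0.5 * count
    bn = prior.b0 + 0.5 * (total_sq + prior.k0 * prior.m0**2 - kn * mn**2)
    # guard against cancellation pushing bn non-positive
    return NIGParams(m0=mn, k0=kn, a0=an, b0=max(bn, 1e-300))


def student_t_predictive(obs, prior: NIGParams) -> tuple[float, float, float]:
    """Posterior-predictive (df, loc, scale) of one new Gaussian observation.

    ``obs`` are previous observations sharing the unknown (mean, variance)
    with NIG prior ``prior``; with no observations this is the prior
    predictive.  The predictive is Student-t with

        df = 2 a_n,  loc = m_n,  scale^2 = b_n (k_n + 1) / (a_n k_n).
    """
    obs = np.asarray(obs, dtype=float)
    post = nig_posterior(prior, obs.size, float(obs.sum()), float((obs**2).sum()))
    df = 2.0 * post.a0
    scale = math.sqrt(post.b0 * (post.k0 + 1.0) / (post.a0 * post.k0))
    return df, post.m0, scale


def student_t_logpdf(x, df, loc, scale):
    """Vectorized log density of the location-scale Student-t."""
    x = np.asarray(x, dtype=float)
    df = np.asarray(df, dtype=float)
    scale = np.asarray(scale, dtype=float)
    z = (x - loc) / scale
    return (
        special.gammaln(0.5 * (df + 1.0))
        - special.gammaln(0.5 * df)
        - 0.5 * np.log(df * math.pi)
        - np.log(scale)
        - 0.5 * (df + 1.0) * np.log1p(z * z / df)
    )


def truncated_student_t_sample(
    df: float, loc: float, scale: float, upper: float, rng: np.random.Generator
) -> float:
    """Student-t(df, loc, scale) conditioned on the value being <= ``upper``.

    Inverse-CDF via the regularized incomplete beta; adequate because the t
    tails are polynomial and ``stdtrit`` stays accurate far out.
    """
    z_up = (upper - loc) / scale
    cdf_up = special.stdtr(df, z_up)
    if cdf_up <= 0.0:
        return upper  # numerically unreachable region; clamp
    u = rng.uniform(0.0, cdf_up)
    return loc + scale * float(special.stdtrit(df, max(u, 1e-300)))
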
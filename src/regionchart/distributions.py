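"""Generalized gamma distribution in location–scale–shape form.

The normative model describes each regional measurement y > 0 by three
parameters: a location mu > 0 (roughly the median scale of the phenotype),
a scale sigma > 0 (approximately the coefficient of variation), and a real
shape nu controlling skewness.  With

    theta = 1 / (sigma^2 nu^2),        z = (y / mu)^nu,

the log density is

    log f(y) = log|nu| + theta log theta + theta nu (log y - log mu)
               - theta z - log Gamma(theta) - log y,

and the CDF is the regularized lower incomplete gamma P(theta, theta z)
for nu > 0 (its complement for nu < 0).  nu = 1 recovers the gamma
distribution with shape 1/sigma^2 and mean mu; nu -> 0 recovers the
lognormal with log-scale sigma.  theta grows like nu^-2, so the naive
formula loses all precision near nu = 0; everything here is computed
through the equivalent form

    log f(y) = log|nu| + A(theta) - theta * (expm1(nu t) - nu t) - log y,
    A(theta) = theta log theta - theta - log Gamma(theta),
    t = log y - log mu,

with A evaluated by a Stirling tail for large theta, and an explicit
lognormal-series branch below |nu| = 1e-4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

#: below this |nu| the lognormal limit is used (relative error O(nu)).
NU_SMALL = 1e-4
#: above this theta, lgamma is replaced by its Stirling expansion in A(theta).
_THETA_STIRLING = 1e6


@dataclass(frozen=True)
class DistributionParams:
    """(mu, sigma, nu) for one conditional distribution."""

    mu: float
    sigma: float
    nu: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mu) and self.mu > 0):
            raise ValueError(f"mu must be finite and positive, got {self.mu}")
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError(f"sigma must be finite and positive, got {self.sigma}")
        if not np.isfinite(self.nu):
            raise ValueError(f"nu must be finite, got {self.nu}")


def _check_y(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0) or not np.all(np.isfinite(y)):
        raise ValueError("phenotype values must be finite and strictly positive")
    return y


def _stable_A(theta: np.ndarray) -> np.ndarray:
    """theta*log(theta) - theta - lgamma(theta), safe for huge theta."""
    theta = np.asarray(theta, dtype=float)
    out = np.empty_like(theta)
    big = theta > _THETA_STIRLING
    small = ~big
    if np.any(small):
        th = theta[small]
        out[small] = th * np.log(th) - th - special.gammaln(th)
    if np.any(big):
        th = theta[big]
        # Stirling: lgamma = (th-.5)log th - th + .5 log 2pi + 1/(12 th) - ...
        out[big] = 0.5 * np.log(th) - 0.5 * np.log(2.0 * np.pi) - 1.0 / (12.0 * th)
    return out


def gg_log_density(y, mu, sigma, nu):
    """Log density of the generalized gamma; vectorized over all arguments.

    Scalars and arrays broadcast; values must be positive.
    """
    y = _check_y(y)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    nu = np.asarray(nu, dtype=float)
    if np.any(mu <= 0) or np.any(sigma <= 0):
        raise ValueError("mu and sigma must be strictly positive")
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(sigma)) and np.all(np.isfinite(nu))):
        raise ValueError("distribution parameters must be finite")

    y, mu, sigma, nu = np.broadcast_arrays(y, mu, sigma, nu)
    t = np.log(y) - np.log(mu)
    out = np.empty(t.shape, dtype=float)

    small = np.abs(nu) < NU_SMALL
    if np.any(small):
        # lognormal limit with first-order skew correction in nu
        ts, ss, ns = t[small], sigma[small], nu[small]
        quad = ts * ts / (2.0 * ss * ss)
        out[small] = (
            -np.log(ss) - 0.5 * np.log(2.0 * np.pi) - np.log(y[small])
            - quad * (1.0 + ns * ts / 3.0)
        )
    if np.any(~small):
        tg, sg, ng = t[~small], sigma[~small], nu[~small]
        theta = 1.0 / (sg * sg * ng * ng)
        nt = ng * tg
        w = np.expm1(nt) - nt  # = z - 1 - nu*t, accurate for small nt
        out[~small] = (
            np.log(np.abs(ng)) + _stable_A(theta) - theta * w - np.log(y[~small])
        )
    return out if out.shape else float(out)


def gg_cdf(y, mu, sigma, nu):
    """CDF F(y | mu, sigma, nu), strictly increasing in y."""
    y = _check_y(y)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    nu = np.asarray(nu, dtype=float)
    if np.any(mu <= 0) or np.any(sigma <= 0):
        raise ValueError("mu and sigma must be strictly positive")
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(sigma)) and np.all(np.isfinite(nu))):
        raise ValueError("distribution parameters must be finite")
    y, mu, sigma, nu = np.broadcast_arrays(y, mu, sigma, nu)
    t = np.log(y) - np.log(mu)
    out = np.empty(t.shape, dtype=float)

    small = np.abs(nu) < NU_SMALL
    if np.any(small):
        out[small] = stats.norm.cdf(t[small] / sigma[small])
    big = ~small
    if np.any(big):
        tg, sg, ng = t[big], sigma[big], nu[big]
        theta = 1.0 / (sg * sg * ng * ng)
        p = special.gammainc(theta, theta * np.exp(ng * tg))
        out[big] = np.where(ng > 0, p, 1.0 - p)
    return out if out.shape else float(out)


def gg_ppf(q, mu, sigma, nu):
    """Quantile function (inverse CDF) for q in (0, 1)."""
    q = np.asarray(q, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("quantile levels must lie strictly in (0, 1)")
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    nu = np.asarray(nu, dtype=float)
    q, mu, sigma, nu = np.broadcast_arrays(q, mu, sigma, nu)
    out = np.empty(q.shape, dtype=float)

    small = np.abs(nu) < NU_SMALL
    if np.any(small):
        out[small] = np.exp(
            np.log(mu[small]) + sigma[small] * stats.norm.ppf(q[small])
        )
    big = ~small
    if np.any(big):
        qg, mg, sg, ng = q[big], mu[big], sigma[big], nu[big]
        theta = 1.0 / (sg * sg * ng * ng)
        level = np.where(ng > 0, qg, 1.0 - qg)
        g = special.gammaincinv(theta, level)
        out[big] = mg * np.exp(np.log(g / theta) / ng)
    return out if out.shape else float(out)


def gg_rvs(mu, sigma, nu, size=None, rng: np.random.Generator | None = None):
    """Draw samples: y = mu * (G / theta)^(1/nu), G ~ Gamma(theta, 1)."""
    if rng is None:
        rng = np.random.default_rng()
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    nu = np.asarray(nu, dtype=float)
    shape = np.broadcast_shapes(mu.shape, sigma.shape, nu.shape)
    if size is None:
        size = shape
    mu, sigma, nu = (np.broadcast_to(a, size) for a in (mu, sigma, nu))

    out = np.empty(size, dtype=float)
    small = np.abs(nu) < NU_SMALL
    if np.any(small):
        out[small] = np.exp(
            np.log(mu[small]) + sigma[small] * rng.standard_normal(int(small.sum()))
        )
    big = ~small
    if np.any(big):
        sg, ng = sigma[big], nu[big]
        theta = 1.0 / (sg * sg * ng * ng)
        g = rng.gamma(theta)
        out[big] = mu[big] * np.exp(np.log(g / theta) / ng)
    return out


def gg_median(mu, sigma, nu):
    """Closed-form median via the quantile function."""
    return gg_ppf(0.5, mu, sigma, nu)


def loglik_gradients(t, sigma, nu):
    """Per-observation score of the log density w.r.t. the link predictors.

    ``t = log y - log mu``.  Returns ``(d/d eta_mu, d/d eta_sigma, d/d nu)``
    where eta_mu = log mu and eta_sigma = log sigma.  Used by the fitting
    routines; series branch below NU_SMALL avoids 1/nu cancellation.
    """
    t = np.asarray(t, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    nu = np.asarray(nu, dtype=float)
    t, sigma, nu = np.broadcast_arrays(t, sigma, nu)

    g_mu = np.empty(t.shape)
    g_sig = np.empty(t.shape)
    g_nu = np.empty(t.shape)

    small = np.abs(nu) < NU_SMALL
    if np.any(small):
        ts, ss, ns = t[small], sigma[small], nu[small]
        s2 = ss * ss
        g_mu[small] = (ts / s2) * (1.0 + ns * ts / 2.0 + ns * ns * ts * ts / 6.0)
        g_sig[small] = -1.0 + (ts * ts / s2) * (1.0 + ns * ts / 3.0) - s2 * ns * ns / 6.0
        g_nu[small] = -s2 * ns / 6.0 - ts**3 / (6.0 * s2) - ns * ts**4 / (12.0 * s2)
    big = ~small
    if np.any(big):
        tg, sg, ng = t[big], sigma[big], nu[big]
        theta = 1.0 / (sg * sg * ng * ng)
        nt = ng * tg
        em1 = np.expm1(nt)
        w = em1 - nt
        # D = log(theta) - psi(theta) ~ 1/(2 theta) for large theta
        D = np.empty_like(theta)
        hi = theta > _THETA_STIRLING
        D[~hi] = np.log(theta[~hi]) - special.digamma(theta[~hi])
        D[hi] = 0.5 / theta[hi] + 1.0 / (12.0 * theta[hi] ** 2)
        g_mu[big] = theta * ng * em1
        g_sig[big] = -2.0 * theta * (D - w)
        g_nu[big] = 1.0 / ng - (2.0 * theta / ng) * (D - w) - theta * tg * em1
    return g_mu, g_sig, g_nu
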
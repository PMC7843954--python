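"""Log-density kernels shared by the latent-profile and trajectory fitters.

All kernels return log probabilities / log densities and are safe to compose
with log-sum-exp downstream; mixture posteriors would underflow otherwise.

Two observation models carry the substance:

* zero-inflated Poisson (ZIP) for active joint counts — a structural-zero
  mass ``p_zero`` mixed with a Poisson(``rate``);
* censored normal (Tobit) for the two 0–10 cm visual-analogue scores — a
  latent normal observed only inside ``[lower, upper]``, with point masses
  at the bounds.  A score recorded exactly at a bound is censored mass,
  not density, so 0 cm and 10 cm observations get positive probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy.stats import norm

__all__ = [
    "ZipParams",
    "CensNormParams",
    "zip_log_pmf",
    "censnorm_log_density",
    "censnorm_mean",
    "zip_mean",
    "poisson_log_pmf",
    "normal_log_pdf",
    "polynomial_eta",
]


@dataclass(frozen=True)
class ZipParams:
    """Zero-inflated Poisson: rate ``lam`` > 0 and structural-zero mass ``p_zero``."""

    rate: float
    p_zero: float = 0.0

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValueError(f"ZIP rate must be > 0, got {self.rate}")
        if not 0.0 <= self.p_zero <= 1.0:
            raise ValueError(f"p_zero must be in [0, 1], got {self.p_zero}")


@dataclass(frozen=True)
class CensNormParams:
    """Censored (Tobit) normal with latent mean ``mu``, SD ``sigma``, bounds [lower, upper]."""

    mu: float
    sigma: float
    lower: float = 0.0
    upper: float = 10.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not self.lower < self.upper:
            raise ValueError("lower bound must be below upper bound")


def poisson_log_pmf(y, rate):
    """Poisson log pmf, stable in log space: ``y log λ − λ − log y!``."""
    y = np.asarray(y)
    rate = np.asarray(rate, dtype=float)
    if np.any(y < 0):
        raise ValueError("Poisson outcome must be a non-negative integer")
    if np.any(rate <= 0):
        raise ValueError("Poisson rate must be > 0")
    return y * np.log(rate) - rate - special.gammaln(np.asarray(y, dtype=float) + 1.0)


def normal_log_pdf(y, mu, sigma):
    """Normal log density."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be > 0")
    z = (np.asarray(y, dtype=float) - mu) / sigma
    return -0.5 * np.log(2.0 * np.pi) - np.log(sigma) - 0.5 * z * z


def zip_log_pmf(y, params: ZipParams | None = None, *, rate=None, p_zero=None):
    """Log pmf of the zero-inflated Poisson.

    ``log[ p_zero·1{y=0} + (1 − p_zero)·Pois(y; λ) ]``, computed with
    ``logaddexp`` so that small mixture components do not underflow.
    Accepts either a :class:`ZipParams` or explicit ``rate`` / ``p_zero``
    keywords (both may be arrays broadcastable against ``y``).
    """
    if params is not None:
        rate, p_zero = params.rate, params.p_zero
    y = np.asarray(y)
    if np.any(y < 0):
        raise ValueError("ZIP outcome must be a non-negative integer")
    rate = np.asarray(rate, dtype=float)
    p_zero = np.asarray(p_zero, dtype=float)
    pois = poisson_log_pmf(y, rate)
    with np.errstate(divide="ignore"):
        log_p0 = np.log(p_zero)
        log_1mp0 = np.log1p(-np.clip(p_zero, None, 1.0))
    # y == 0: log(p0 + (1-p0) e^{-lam});  y > 0: log(1-p0) + Poisson
    at_zero = np.logaddexp(log_p0, log_1mp0 - rate)
    out = np.where(y == 0, at_zero, log_1mp0 + pois)
    if out.ndim == 0:
        return float(out)
    return out


def censnorm_log_density(y, params: CensNormParams | None = None, *, mu=None,
                         sigma=None, lower=0.0, upper=10.0):
    """Log density/mass of the censored normal.

    Interior points get the normal log density; values exactly at a bound get
    the log of the censored probability mass (``log Φ`` at the lower bound,
    ``log(1 − Φ)`` at the upper bound).
    """
    if params is not None:
        mu, sigma = params.mu, params.sigma
        lower, upper = params.lower, params.upper
    y = np.asarray(y, dtype=float)
    if np.any((y < lower) | (y > upper)):
        raise ValueError(f"observation outside censoring bounds [{lower}, {upper}]")
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be > 0")
    z = (y - mu) / sigma
    interior = norm.logpdf(z) - np.log(sigma)
    at_lower = norm.logcdf((lower - mu) / sigma * np.ones_like(y))
    at_upper = norm.logsf((upper - mu) / sigma * np.ones_like(y))
    out = np.where(y == lower, at_lower, np.where(y == upper, at_upper, interior))
    if out.ndim == 0:
        return float(out)
    return out


def censnorm_mean(mu, sigma, lower=0.0, upper=10.0):
    """Expected *observed* value under censoring at the bounds.

    E[Y] = L·Φ(z_L) + U·(1 − Φ(z_U)) + μ·(Φ(z_U) − Φ(z_L)) + σ·(φ(z_L) − φ(z_U))
    with z_b = (b − μ)/σ.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    zl = (lower - mu) / sigma
    zu = (upper - mu) / sigma
    return (lower * norm.cdf(zl) + upper * norm.sf(zu)
            + mu * (norm.cdf(zu) - norm.cdf(zl))
            + sigma * (norm.pdf(zl) - norm.pdf(zu)))


def zip_mean(rate, p_zero):
    """Mean of the zero-inflated Poisson, ``(1 − p_zero)·λ``."""
    return (1.0 - np.asarray(p_zero, dtype=float)) * np.asarray(rate, dtype=float)


def polynomial_eta(beta, t):
    """Evaluate the trajectory polynomial ``β₀ + β₁t + β₂t² + …``.

    ``beta`` has length order+1 with order between 0 (intercept only) and 3.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.ndim != 1 or beta.size == 0:
        raise ValueError("beta must be a non-empty 1-D coefficient vector")
    if beta.size > 4:
        raise ValueError("trajectory polynomials above cubic are not supported")
    out = np.polynomial.polynomial.polyval(np.asarray(t, dtype=float), beta)
    if np.ndim(out) == 0:
        return float(out)
    return out
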
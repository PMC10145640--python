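"""Distribution theory for whole and observed tick attachment times.

Ticks collected from a captured host form a *prevalent cohort*: a tick is
sampled only if it is attached at the moment of capture, so the sampled
whole attachment times ``T`` are length-biased (inclusion probability
proportional to duration), and the observed capture-to-drop-off time ``V``
is the *forward recurrence time* of the attachment process.  Under the
standard stationarity assumptions — capture position uniform over the
attachment interval, sampling probability proportional to duration — the
forward recurrence time has the renewal-equilibrium density

    f_V(v) = S_T(v) / E[T],

which is monotone non-increasing regardless of the shape of ``T``.

With Weibull whole times ``T ~ Weibull(k, lambda)`` every quantity needed
by the fitting machinery is available in closed form:

* ``E[T] = lambda * Gamma(1 + 1/k)``
* the length-biased law of ``T`` is a generalised gamma distribution
  (``T* = lambda * G**(1/k)`` with ``G ~ Gamma(1 + 1/k)``),
* ``F_V(v) = P(1/k, (v/lambda)**k)`` (regularised lower incomplete gamma),
* ``E[V] = lambda * Gamma(1 + 2/k) / (2 * Gamma(1 + 1/k))``,
* the whole/observed mean ratio ``R(k) = E[T]/E[V] =
  2 * Gamma(1 + 1/k)**2 / Gamma(1 + 2/k)`` depends on the shape alone,
  increases strictly with ``k`` and is confined to (0, 2).

All gamma factors are evaluated through ``gammaln`` and exponentiated from
log space; densities are computed from log densities to avoid underflow
deep in the Weibull tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammainc, gammaln
from scipy.stats import norm

__all__ = [
    "WeibullWholeTime",
    "ForwardRecurrenceDist",
    "whole_density",
    "whole_mean",
    "length_biased_density",
    "forward_density",
    "forward_cdf",
    "forward_mean",
    "mean_ratio",
    "mean_ratio_deriv",
    "mean_ratio_ci",
]


@dataclass(frozen=True)
class WeibullWholeTime:
    """Weibull law of the whole attachment time.

    Parameters
    ----------
    shape : float
        Dimensionless Weibull shape ``k > 0``; larger values concentrate
        attachment times around the scale.
    scale : float
        Weibull scale ``lambda > 0`` in days.
    """

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.shape) and self.shape > 0):
            raise ValueError(f"shape must be a positive finite real, got {self.shape!r}")
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise ValueError(f"scale must be a positive finite real, got {self.scale!r}")

    @property
    def mean(self) -> float:
        return whole_mean(self)

    def pdf(self, t):
        return whole_density(t, self)

    def rvs(self, size, rng: np.random.Generator):
        """Unbiased draws of the whole attachment time."""
        return self.scale * rng.weibull(self.shape, size=size)

    def rvs_length_biased(self, size, rng: np.random.Generator):
        """Draws from the length-biased law t*f(t)/E[T].

        Substituting ``u = (t/lambda)**k`` in the length-biased density
        gives a ``Gamma(1 + 1/k)`` law for ``u``, so the draw is exact.
        """
        g = rng.gamma(1.0 + 1.0 / self.shape, size=size)
        return self.scale * g ** (1.0 / self.shape)


@dataclass(frozen=True)
class ForwardRecurrenceDist:
    """Equilibrium forward-recurrence law of the observed attachment time."""

    parent: WeibullWholeTime

    @property
    def mean(self) -> float:
        return forward_mean(self.parent)

    def pdf(self, v):
        return forward_density(v, self.parent)

    def cdf(self, v):
        return forward_cdf(v, self.parent)

    def rvs(self, size, rng: np.random.Generator):
        """V = U * T* with T* length-biased and U uniform on (0, 1)."""
        tstar = self.parent.rvs_length_biased(size, rng)
        return rng.uniform(size=np.shape(tstar)) * tstar


def whole_density(t, dist: WeibullWholeTime):
    """Weibull density of the whole attachment time; zero for t < 0."""
    t = np.asarray(t, dtype=float)
    k, lam = dist.shape, dist.scale
    out = np.zeros_like(t)
    pos = t > 0
    with np.errstate(divide="ignore"):
        x = t[pos] / lam
        logf = np.log(k / lam) + (k - 1.0) * np.log(x) - x**k
    out[pos] = np.exp(logf)
    if np.any(t == 0):
        # k<1 diverges at 0, k=1 gives 1/lam, k>1 gives 0
        if dist.shape == 1.0:
            out[t == 0] = 1.0 / lam
        elif dist.shape < 1.0:
            out[t == 0] = np.inf
    return out if out.ndim else float(out)


def whole_mean(dist: WeibullWholeTime) -> float:
    """E[T] = lambda * Gamma(1 + 1/k)."""
    return dist.scale * np.exp(gammaln(1.0 + 1.0 / dist.shape))


def length_biased_density(t, dist: WeibullWholeTime):
    """Density of the sampled (length-biased) whole time, t*f(t)/E[T]."""
    t = np.asarray(t, dtype=float)
    out = t * whole_density(t, dist) / whole_mean(dist)
    return out if out.ndim else float(out)


def forward_density(v, dist: WeibullWholeTime):
    """Equilibrium density of the observed time, S_T(v)/E[T]; 0 for v < 0."""
    v = np.asarray(v, dtype=float)
    k, lam = dist.shape, dist.scale
    out = np.zeros_like(v)
    ok = v >= 0
    logf = -((v[ok] / lam) ** k) - np.log(lam) - gammaln(1.0 + 1.0 / k)
    out[ok] = np.exp(logf)
    return out if out.ndim else float(out)


def forward_cdf(v, dist: WeibullWholeTime):
    """CDF of the observed time: P(1/k, (v/lambda)**k), a generalised gamma."""
    v = np.asarray(v, dtype=float)
    k, lam = dist.shape, dist.scale
    out = np.zeros_like(v)
    ok = v > 0
    out[ok] = gammainc(1.0 / k, (v[ok] / lam) ** k)
    return out if out.ndim else float(out)


def forward_mean(dist: WeibullWholeTime) -> float:
    """E[V] = E[T^2]/(2 E[T]) = lambda * Gamma(1+2/k) / (2 Gamma(1+1/k))."""
    k, lam = dist.shape, dist.scale
    return lam * np.exp(gammaln(1.0 + 2.0 / k) - gammaln(1.0 + 1.0 / k)) / 2.0


def mean_ratio(shape):
    """Whole-to-observed mean ratio R(k) = 2 Gamma(1+1/k)^2 / Gamma(1+2/k).

    Depends on the Weibull shape only; R(1) = 1 (memoryless case) and
    R(k) -> 2 as k -> infinity (degenerate attachment time).  Strictly
    increasing in k and bounded in (0, 2).
    """
    k = np.asarray(shape, dtype=float)
    if np.any(k <= 0) or not np.all(np.isfinite(k)):
        raise ValueError("shape must be positive and finite")
    out = 2.0 * np.exp(2.0 * gammaln(1.0 + 1.0 / k) - gammaln(1.0 + 2.0 / k))
    return out if out.ndim else float(out)


def mean_ratio_deriv(shape):
    """dR/dk, analytically: R(k) * (2/k^2) * (psi(1+2/k) - psi(1+1/k))."""
    k = np.asarray(shape, dtype=float)
    r = mean_ratio(k)
    out = r * (2.0 / k**2) * (digamma(1.0 + 2.0 / k) - digamma(1.0 + 1.0 / k))
    return out if out.ndim else float(out)


def mean_ratio_ci(shape_hat: float, shape_se: float, level: float = 0.95):
    """Delta-method confidence interval for the whole/observed mean ratio.

    The ratio is a smooth function of the shape alone, so the interval is
    ``R(k) -/+ z * |R'(k)| * se``, truncated to the attainable range (0, 2).

    Returns ``(estimate, low, high)``.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level!r}")
    if shape_se < 0:
        raise ValueError("shape_se must be non-negative")
    est = mean_ratio(shape_hat)
    z = norm.ppf(0.5 + level / 2.0)
    half = z * abs(mean_ratio_deriv(shape_hat)) * shape_se
    lo = max(est - half, np.nextafter(0.0, 1.0))
    hi = min(est + half, 2.0)
    return float(est), float(lo), float(hi)
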
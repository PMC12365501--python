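"""Empirical-Bayes moderation of per-protein residual variances.

Per-protein variance estimates are noisy because each protein contributes
few observations.  Borrowing strength across proteins assumes the true
variances follow a scaled inverse chi-square prior with ``d0`` degrees of
freedom and location ``s0_sq``; the observed ``s^2`` then follow a scaled
F distribution, and the prior is recovered by moment matching on
``log s^2`` through the digamma/trigamma identities.  The posterior
variance shrinks each ``s^2`` toward ``s0_sq`` and adds ``d0`` to the
test's degrees of freedom.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, polygamma

from .errors import InsufficientProteinsError


@dataclass(frozen=True)
class VariancePrior:
    """Scaled inverse chi-square prior on residual variances."""

    d0: float
    s0_sq: float

    def __post_init__(self):
        # d0 = 0 is the degenerate "no moderation" prior, d0 = inf the
        # fully pooled one; estimation always returns d0 > 0.
        if not (self.d0 >= 0):
            raise ValueError("d0 must be nonnegative")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be positive")


def _trigamma(x):
    return polygamma(1, x)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2, df) -> VariancePrior:
    """Moment-match the variance prior from per-protein (s^2, df) pairs.

    Under the scaled-F model, ``E[log s^2] = log s0^2 + psi(df/2) -
    log(df/2) - psi(d0/2) + log(d0/2)`` and the excess variance of
    ``log s^2`` over ``trigamma(df/2)`` equals ``trigamma(d0/2)``.  When
    the empirical excess variance is non-positive the prior is degenerate:
    ``d0`` infinite with ``s0^2`` at the (adjusted) geometric mean.
    """
    s2 = np.asarray(s2, float)
    df = np.asarray(df, float)
    if df.ndim == 0:
        df = np.full_like(s2, float(df))
    ok = np.isfinite(s2) & np.isfinite(df) & (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if len(s2) < 2:
        raise InsufficientProteinsError(
            f"need >= 2 finite variance estimates, got {len(s2)}"
        )
    if np.all(s2 == s2[0]):
        # zero observed dispersion: the scaled-F moment equations are
        # degenerate; the only sensible prior is fully pooled at the
        # common value
        return VariancePrior(d0=np.inf, s0_sq=float(s2[0]))
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1) - np.mean(_trigamma(df / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        if np.isfinite(d0):
            s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
            return VariancePrior(d0=d0, s0_sq=s0_sq)
    return VariancePrior(d0=np.inf, s0_sq=float(np.exp(emean)))


def posterior_variance(s2, df, prior: VariancePrior):
    """Shrink residual variances toward the prior:
    ``(d0 s0^2 + df s^2) / (d0 + df)``; with infinite ``d0`` the posterior
    is the prior location regardless of ``s^2``."""
    s2 = np.asarray(s2, float)
    df = np.asarray(df, float)
    if np.isinf(prior.d0):
        return np.full(np.broadcast(s2, df).shape, prior.s0_sq)
    if prior.d0 == 0:
        return s2 + 0.0 * df
    return (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)
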
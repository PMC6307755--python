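"""Shared statistical primitives.

Benjamini-Hochberg adjustment, Stouffer z-score combination, and
empirical-Bayes variance moderation for feature-wise linear models.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

__all__ = ["bh_adjust", "stouffer_combine", "signed_z", "squeeze_variances"]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    NaN entries are ignored (they stay NaN and do not count toward the
    number of tests).
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def signed_z(p: np.ndarray, effect: np.ndarray) -> np.ndarray:
    """Signed z-score from a two-sided p-value and the effect direction.

    z = sign(effect) * Phi^-1(1 - p/2); p is clipped away from 0 and 1 so
    the quantile stays finite.
    """
    p = np.clip(np.asarray(p, dtype=float), 1e-300, 1 - 1e-16)
    z = stats.norm.isf(p / 2.0)
    return np.sign(np.asarray(effect, dtype=float)) * z


def stouffer_combine(z: np.ndarray) -> tuple[float, float]:
    """Combine signed z-scores: Z = sum(z_i)/sqrt(n), two-sided p.

    Returns (Z, p). Combining k copies of the same z gives z*sqrt(k).
    """
    z = np.asarray(z, dtype=float)
    n = z.size
    if n == 0:
        raise ValueError("cannot combine an empty set of z-scores")
    zc = float(z.sum() / np.sqrt(n))
    p = float(2.0 * stats.norm.sf(abs(zc)))
    return zc, max(p, 5e-324)


def _trigamma_inverse(y: float) -> float:
    # Newton iteration on psi'(x) = y; psi' is decreasing and convex.
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def squeeze_variances(
    s2: np.ndarray, df: float
) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of residual variances toward a pooled prior.

    Models s2 ~ s0^2 * F(df, df0) and estimates (df0, s0^2) by matching the
    mean and variance of log(s2) (method of moments on the log scale).
    Returns (posterior variances, prior df, prior variance). A prior df of
    ``inf`` means the observed spread of log-variances is no larger than
    expected under equal true variances; all posteriors then equal s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2 > 0
    if not np.any(pos):
        raise ValueError("all residual variances are zero")
    z = np.log(s2[pos])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = np.var(z, ddof=1) if z.size > 1 else 0.0
    resid_var = evar - special.polygamma(1, df / 2.0)
    if resid_var <= 0 or z.size < 2:
        df0 = np.inf
        s02 = float(np.exp(np.mean(e)))
        post = np.full(s2.shape, s02)
        return post, df0, s02
    half = _trigamma_inverse(float(resid_var))
    df0 = 2.0 * half
    s02 = float(np.exp(np.mean(e) + special.digamma(half) - np.log(half)))
    post = (df0 * s02 + df * s2) / (df0 + df)
    return post, df0, s02
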
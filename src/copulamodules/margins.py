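"""Empirical count margins and the distributional transform.

Spike-count data are discrete, so the plain probability transform F(X) does
not produce uniform pseudo-observations.  The distributional transform fixes
this by jittering uniformly inside each CDF jump interval:

    G(x, v) = F_(x) + v * (F(x) - F_(x)),      F_(x) = Pr(X < x),

which maps a discrete sample exactly to U(0,1) when F is the true margin and
approximately when F is the empirical margin of the same sample.  The
resulting pseudo-observations live strictly inside (0,1) and feed the copula
density estimators downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "EmpiricalMargin",
    "fit_empirical_margin",
    "distributional_transform",
    "kendall_tau",
    "to_pseudo_observations",
]

#: pseudo-observations are clipped to [EPS, 1 - EPS]
EPS = 1e-6


@dataclass(frozen=True)
class EmpiricalMargin:
    """Empirical distribution of a non-negative integer sample.

    Attributes
    ----------
    support : sorted distinct observed counts
    cdf_values : F(x) = Pr(X <= x) at each support point (right-continuous)
    cdf_left_values : F_(x) = Pr(X < x) at each support point
    """

    support: np.ndarray
    cdf_values: np.ndarray
    cdf_left_values: np.ndarray = field(repr=False, default=None)

    def cdf(self, x) -> np.ndarray:
        """F(x) = Pr(X <= x); 0 below the support, 1 at/above its max."""
        idx = np.searchsorted(self.support, np.asarray(x), side="right")
        padded = np.concatenate([[0.0], self.cdf_values])
        return padded[idx]

    def cdf_left(self, x) -> np.ndarray:
        """F_(x) = Pr(X < x)."""
        idx = np.searchsorted(self.support, np.asarray(x), side="left")
        padded = np.concatenate([[0.0], self.cdf_values])
        return padded[idx]

    def quantile(self, u) -> np.ndarray:
        """Generalized inverse F^-1(u) = min{x : F(x) >= u}."""
        u = np.asarray(u)
        idx = np.searchsorted(self.cdf_values, u, side="left")
        idx = np.clip(idx, 0, len(self.support) - 1)
        return self.support[idx]

    @property
    def max_support(self) -> int:
        return int(self.support[-1])


def _validate_counts(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if x.size == 0:
        raise ValueError("empty count vector")
    if not np.issubdtype(x.dtype, np.integer):
        xf = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(xf)) or np.any(xf != np.round(xf)):
            raise ValueError("counts must be finite integers")
        x = xf.astype(np.int64)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    return x.astype(np.int64)


def fit_empirical_margin(counts) -> EmpiricalMargin:
    """Fit the empirical CDF of a vector of non-negative integer counts."""
    x = _validate_counts(counts)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    support, freq = np.unique(x, return_counts=True)
    cdf = np.cumsum(freq) / x.size
    cdf[-1] = 1.0
    cdf_left = np.concatenate([[0.0], cdf[:-1]])
    return EmpiricalMargin(support=support, cdf_values=cdf, cdf_left_values=cdf_left)


def distributional_transform(x, margin: EmpiricalMargin, jitter) -> np.ndarray:
    """Map discrete observations to (0,1) pseudo-observations.

    Parameters
    ----------
    x : integer vector of observations, all inside ``margin.support``
    margin : fitted empirical margin
    jitter : uniform [0,1) randoms, same length as x (the V of the transform)
    """
    x = _validate_counts(x)
    v = np.asarray(jitter, dtype=float)
    if v.shape != x.shape:
        raise ValueError("jitter must have the same shape as x")
    if np.any(v < 0) or np.any(v >= 1):
        raise ValueError("jitter entries must lie in [0, 1)")
    if np.any(~np.isin(x, margin.support)):
        raise ValueError("observation outside margin support")
    lo = margin.cdf_left(x)
    hi = margin.cdf(x)
    u = lo + v * (hi - lo)
    return np.clip(u, EPS, 1.0 - EPS)


def kendall_tau(u, v) -> float:
    """Tie-corrected Kendall's tau-b; constant inputs return 0 with a warning."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or u.size < 2:
        raise ValueError("u and v must be equal-length 1-D vectors, length >= 2")
    if np.ptp(u) == 0 or np.ptp(v) == 0:
        warnings.warn("constant input to kendall_tau; returning 0", RuntimeWarning)
        return 0.0
    tau = stats.kendalltau(u, v).statistic
    return float(tau)


def to_pseudo_observations(counts: np.ndarray, seed: int) -> np.ndarray:
    """Column-wise distributional transform of a trials x neurons count matrix.

    One jitter stream per dataset, drawn from ``seed``; margins are the
    empirical margins of each column.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2:
        raise ValueError("expected a 2-D trials x neurons matrix")
    rng = np.random.default_rng(seed)
    jitter = rng.random(counts.shape)
    out = np.empty(counts.shape, dtype=float)
    for j in range(counts.shape[1]):
        margin = fit_empirical_margin(counts[:, j])
        out[:, j] = distributional_transform(counts[:, j], margin, jitter[:, j])
    return out
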
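"""Shared statistical primitives used by every pipeline stage.

Pearson correlation with an exact t-based p-value, the hypergeometric
upper-tail (over-representation) test, Benjamini-Hochberg adjustment, and the
pooled-variance two-sample t-test. All stages call these rather than scipy
directly so that conventions (two-sidedness, degenerate-input behaviour) are
decided in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "ConstantInputError",
    "pearson",
    "hypergeom_sf",
    "bh_adjust",
    "two_sample_t",
]


class ConstantInputError(ValueError):
    """Raised when a correlation is requested for a zero-variance vector."""


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation coefficient with its two-sided p-value.

    Attributes
    ----------
    r : float
        Product-moment correlation, in [-1, 1].
    n : int
        Number of paired observations.
    p : float
        Two-sided p-value from the t transform with n - 2 degrees of freedom.
    """

    r: float
    n: int
    p: float


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation of two vectors with a two-sided p-value.

    The p-value refers t = r * sqrt((n - 2) / (1 - r^2)) to a Student t
    distribution with n - 2 degrees of freedom. Perfect correlation
    (|r| = 1) yields p = 0.

    Raises
    ------
    ConstantInputError
        If either vector has zero variance (correlation undefined).
    ValueError
        If the vectors differ in length or have fewer than 3 elements.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("zero-variance input: correlation undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * scipy.stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r=r, n=n, p=p)


def pearson_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Vectorised two-sided p-values for Pearson r at fixed sample size n."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    p = np.zeros_like(r)
    interior = np.abs(r) < 1.0
    t = r[interior] * np.sqrt((n - 2) / (1.0 - r[interior] ** 2))
    p[interior] = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    return p


def hypergeom_sf(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts category members among n draws without replacement from a
    universe of N items of which K are in the category.

    Parameters follow the over-representation convention: N universe size,
    K category size, n draw (gene-list) size, k observed overlap.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric bounds: N={N}, K={K}, n={n}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    return float(scipy.stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    adj_i = min over j with rank >= rank(i) of p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def two_sample_t(a, b) -> tuple[float, float]:
    """Pooled-variance Student t-test, two-sided.

    Returns (t, p) with n_a + n_b - 2 degrees of freedom. Degenerate case:
    zero pooled variance with equal means gives (0, 1); zero pooled variance
    with different means gives (+/-inf, 0) by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    df = na + nb - 2
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if pooled_var == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        return float(np.sign(diff) * np.inf), 0.0
    t = diff / np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    p = float(2.0 * scipy.stats.t.sf(abs(t), df=df))
    return float(t), p
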
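"""Shared statistics: one-sided two-sample K-S and hypergeometric enrichment.

The one-sided Kolmogorov-Smirnov statistic is the maximal signed difference of
empirical CDFs in the direction of the alternative; its p-value uses the
asymptotic tail exp(-2 D^2 nm/(n+m)), with an exact small-sample computation
(scipy's path-counting method) when n*m <= 10,000.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as _stats

EXACT_KS_LIMIT = 10_000


def ks_one_sided(x, y, alternative: str = "greater") -> tuple[float, float]:
    """One-sided two-sample K-S test.

    ``alternative="greater"`` tests whether ``x`` is stochastically greater
    than ``y`` (CDF of x lies below that of y); the statistic is
    D = max_t [F_y(t) - F_x(t)].  ``"less"`` swaps the roles.

    Returns ``(D, p)``.
    """
    if alternative == "less":
        return ks_one_sided(y, x, "greater")
    if alternative != "greater":
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("empty sample")
    grid = np.concatenate([x, y])
    fx = np.searchsorted(x, grid, side="right") / n
    fy = np.searchsorted(y, grid, side="right") / m
    d = float(max(np.max(fy - fx), 0.0))
    if n * m <= EXACT_KS_LIMIT:
        # scipy's 'less' alternative statistic is max(F_y - F_x) for (x, y)
        try:
            p = float(_stats.ks_2samp(x, y, alternative="less", method="exact").pvalue)
            return d, p
        except Exception:  # pragma: no cover - scipy exact fallback
            pass
    p = math.exp(-2.0 * d * d * n * m / (n + m))
    return d, min(p, 1.0)


def hypergeom_enrichment_p(observed: int, universe: int, with_property: int, drawn: int) -> float:
    """Upper-tail P(X >= observed) drawing ``drawn`` from ``universe`` with
    ``with_property`` marked elements."""
    if drawn == 0:
        return 1.0
    return float(_stats.hypergeom.sf(observed - 1, universe, with_property, drawn))
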
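"""Shared statistical primitives.

The Benjamini–Hochberg adjustment lives here as the single source of
truth for every FDR computation in the pipeline (differential
expression, SNV–expression association, enrichment).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, mapped
    back to the input order.  Output is clipped to [0, 1] and satisfies
    q >= p elementwise and monotonicity in the p-value ordering.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D array of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    # p*m/j at j = rank(i) is >= p mathematically; enforce it against
    # floating-point round-down so q >= p holds exactly
    return np.maximum(q, p)


def pearson_test(x, y) -> tuple[float, float]:
    """Pearson r with a two-sided p-value from the t transform (df = n-2).

    Returns (nan, nan) if either vector has zero variance or fewer than
    three observations; callers treat that as "skip, with a reason".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return (float("nan"), float("nan"))
    res = sps.pearsonr(x, y)
    return (float(res.statistic), float(res.pvalue))


def hypergeom_upper_tail(overlap: int, set_size: int, study_size: int, universe_size: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, set_size, study_size)."""
    if universe_size <= 0:
        raise ValueError("empty universe")
    return float(sps.hypergeom.sf(overlap - 1, universe_size, set_size, study_size))
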
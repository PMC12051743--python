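"""Conversion of test p-values into variance-explained estimates.

A two-sided p-value is mapped back to a t-statistic on ``n - 2`` degrees of
freedom, converted to a correlation ``r = t / sqrt(t^2 + n - 2)``, and the
squared correlation is given the small-sample (Ezekiel-type) adjustment

    r2_adj = r^2 - (1 - r^2) / (n - 2)

which is an approximately unbiased estimate of the proportion of phenotypic
variance implied by the test.  ``r2_adj`` is negative for p near 1 (the
adjustment subtracts the expected chance association), with floor
``-1 / (n - 2)`` at p = 1.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import stats

__all__ = ["R2AdjResult", "p_to_r2adj", "r2adj_from_t"]


class R2AdjResult(NamedTuple):
    t: float
    r: float
    r2: float
    r2_adj: float


def r2adj_from_t(t: float, df: int) -> R2AdjResult:
    """Variance explained implied by a t-statistic on ``df`` degrees of freedom."""
    if df <= 1:
        raise ValueError("df must be > 1")
    t = float(t)
    r = t / np.sqrt(t * t + df)
    r2 = r * r
    r2_adj = r2 - (1.0 - r2) / df
    return R2AdjResult(t, float(r), float(r2), float(r2_adj))


def p_to_r2adj(p: float, n: int) -> R2AdjResult:
    """Convert a two-sided p-value into an adjusted variance-explained estimate.

    Parameters
    ----------
    p : float in (0, 1]
        Two-sided p-value of the per-marker test.
    n : int > 3
        Sample size used by the test; the implied t has ``n - 2`` df.

    Returns
    -------
    R2AdjResult
        Named tuple ``(t, r, r2, r2_adj)``.

    Raises
    ------
    ValueError
        If ``p`` is 0 (no finite t-statistic exists) or outside (0, 1], or
        ``n <= 3``.
    """
    p = float(p)
    if not 0.0 < p <= 1.0:
        raise ValueError("p must be in (0, 1]")
    if n <= 3:
        raise ValueError("n must be > 3")
    df = n - 2
    t = stats.t.isf(p / 2.0, df)
    return r2adj_from_t(t, df)
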
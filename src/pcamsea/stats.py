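"""Shared statistical helpers."""

from __future__ import annotations

import numpy as np

__all__ = ["bh_adjust"]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR-adjusted p-values (q-values).

    ``q_(i) = min_{j >= i}(p_(j) * m / j)`` on the sorted p-values, capped
    at 1 and returned in the original order; monotone nondecreasing along
    the sorted order.

    Raises
    ------
    ValueError
        If any input value lies outside [0, 1] or is NaN.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    m = p.size
    if m == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate((p[order] * m / ranks)[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
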
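"""Sorted factor-loading plot with significance threshold lines."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["significance_threshold_r", "plot_loadings"]


def significance_threshold_r(n: int, alpha: float = 0.05) -> float:
    """|r| at which the two-sided loading test attains p = alpha.

    Inverts t = r sqrt(n-2)/sqrt(1-r^2) at the critical t of the
    t-distribution with n-2 df: r* = t* / sqrt(n - 2 + t*^2).
    """
    if n < 3:
        raise ValueError("insufficient samples for the n-2 df loading test")
    t_crit = sps.t.ppf(1 - alpha / 2, df=n - 2)
    return float(t_crit / np.sqrt(n - 2 + t_crit**2))


def plot_loadings(loadings, n: int, alpha: float = 0.05, ax=None):
    """Plot loadings sorted ascending with dotted +/- threshold lines.

    Returns the matplotlib Axes.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    r = np.sort(np.asarray(loadings, dtype=float))
    if r.size == 0:
        raise ValueError("empty loading vector")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(np.arange(1, r.size + 1), r, ".", color="k", markersize=3)
    thr = significance_threshold_r(n, alpha)
    for y in (thr, -thr):
        ax.axhline(y, linestyle=":", color="gray")
    ax.set_xlabel("metabolite rank (ascending loading)")
    ax.set_ylabel("factor loading (correlation)")
    ax.set_ylim(-1.05, 1.05)
    return ax
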
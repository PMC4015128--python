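"""Welch's two-sample t-test, from raw samples or from summary statistics.

This is the ordinary two-group baseline against which loading-based
selection is compared: an unequal-variance t-test with Welch-Satterthwaite
degrees of freedom and two-sided p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import impute_missing_zero
from .stats import bh_adjust
from .table import MetaboliteTable

__all__ = ["GroupSummary", "welch_from_summary", "welch_per_metabolite"]


@dataclass(frozen=True)
class GroupSummary:
    """Mean, sample SD and size of one group (measurement units)."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def welch_from_summary(g1: GroupSummary, g2: GroupSummary):
    """Welch's t-test from two group summaries.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2) with Welch-Satterthwaite df;
    two-sided p.  Identical zero-variance groups give (0, p=1); unequal
    means with both SDs zero are undefined and raise.

    Returns
    -------
    t, df, p : floats
    """
    v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
    diff = g1.mean - g2.mean
    if v1 + v2 == 0:
        if diff == 0:
            return 0.0, float(g1.n + g2.n - 2), 1.0
        raise ValueError(
            "both groups have zero variance and unequal means: "
            "Welch's t is undefined"
        )
    t = diff / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df=df)
    return float(t), float(df), float(p)


def welch_per_metabolite(
    table: MetaboliteTable, labels=None
) -> pd.DataFrame:
    """Per-metabolite Welch test between exactly two groups.

    Missing cells are zero-imputed first (the package-wide rule).  The
    sign of t records the direction (group 1 minus group 2, groups in
    first-appearance label order) for direction-stratified enrichment.
    BH q-values are adjusted across metabolites.

    Returns a DataFrame indexed by metabolite with columns
    ``t, df, p_value, q_value``.
    """
    if labels is None:
        labels = table.group_labels
    if labels is None:
        raise ValueError("group labels are required")
    labels = list(labels)
    if len(labels) != table.n_samples:
        raise ValueError("one label per sample is required")
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {len(uniq)}")
    idx1 = [i for i, g in enumerate(labels) if g == uniq[0]]
    idx2 = [i for i, g in enumerate(labels) if g == uniq[1]]
    if min(len(idx1), len(idx2)) < 2:
        raise ValueError("each group needs at least 2 samples")
    X = impute_missing_zero(table).values
    rows = []
    for j in range(table.n_metabolites):
        a, b = X[idx1, j], X[idx2, j]
        g1 = GroupSummary(float(a.mean()), float(a.std(ddof=1)), len(a))
        g2 = GroupSummary(float(b.mean()), float(b.std(ddof=1)), len(b))
        try:
            t, df, p = welch_from_summary(g1, g2)
        except ValueError:
            # zero variance in both groups with unequal means: infinitely
            # significant in the limit; report the sentinel explicitly
            t = np.inf if g1.mean > g2.mean else -np.inf
            df, p = float(len(a) + len(b) - 2), 0.0
        rows.append({"t": t, "df": df, "p_value": p})
    out = pd.DataFrame(rows, index=pd.Index(table.metabolite_ids, name="metabolite"))
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out
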
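"""Overrepresentation analysis (ORA) of metabolite sets.

Each pathway is tested against the significant metabolites of one loading
direction with a one-sided Fisher's exact test on the 2x2 cross-tabulation
of pathway membership x significance, the background universe being all
detected metabolites.  The hypergeometric upper-tail probability is
computed with exact integer arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from math import comb

import pandas as pd

from .setio import MetaboliteSetList
from .stats import bh_adjust

__all__ = ["ContingencyTable", "build_contingency", "fisher_one_sided", "msea_ora"]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 cross-tabulation of pathway membership x significance.

    a: in pathway and significant; b: in pathway, not significant;
    c: significant, not in pathway; d: neither.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            iv = int(v)
            if iv != v or iv < 0:
                raise ValueError(f"count {name} must be a nonnegative integer")
            object.__setattr__(self, name, iv)

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d


def build_contingency(pathway, significant, universe) -> ContingencyTable:
    """Cross-tabulate one pathway against the significant set.

    ``significant`` must be a subset of ``universe``; the pathway is
    intersected with the universe (sets should already be restricted via
    :func:`pcamsea.setio.restrict_to_universe`).
    """
    pathway = set(pathway)
    significant = set(significant)
    universe = set(universe)
    stray = significant - universe
    if stray:
        raise ValueError(
            "significant metabolites outside the universe: "
            + ", ".join(sorted(stray)[:10])
        )
    pathway &= universe
    a = len(pathway & significant)
    b = len(pathway) - a
    c = len(significant) - a
    d = len(universe) - a - b - c
    return ContingencyTable(a, b, c, d)


def fisher_one_sided(table: ContingencyTable) -> float:
    """One-sided (enrichment) Fisher's exact test p-value.

    ``P(X >= a)`` for X hypergeometric with population ``N = a+b+c+d``,
    ``K = a+b`` pathway members and ``n = a+c`` draws, evaluated as an
    exact rational and converted to float once.
    """
    N = table.n_total
    K = table.a + table.b
    n = table.a + table.c
    if N == 0:
        return 1.0
    denom = comb(N, n)
    num = sum(comb(K, x) * comb(N - K, n - x) for x in range(table.a, min(K, n) + 1))
    return float(Fraction(num, denom))


def msea_ora(
    sets: MetaboliteSetList,
    positive,
    negative,
    universe,
) -> pd.DataFrame:
    """ORA of both loading directions over a pathway list.

    One Fisher test per (pathway, direction); BH q-values are computed
    across pathways within each direction, matching the per-direction
    column layout of enrichment result tables.  An empty significant set
    yields p = 1 for every pathway in that direction, with a warning.

    Returns a tidy DataFrame with columns ``pathway, direction, overlap,
    set_size, n_significant, n_universe, p_value, q_value``, ordered as in
    the input set list (positive before negative within each pathway).
    """
    universe = set(universe)
    sig = {"positive": set(positive), "negative": set(negative)}
    for direction, s in sig.items():
        if not s:
            warnings.warn(
                f"empty significant set for the {direction} direction; "
                "all p-values are 1"
            )
    rows = []
    for direction in ("positive", "negative"):
        for name, members in sets:
            tab = build_contingency(members, sig[direction], universe)
            rows.append(
                {
                    "pathway": name,
                    "direction": direction,
                    "overlap": tab.a,
                    "set_size": tab.a + tab.b,
                    "n_significant": tab.a + tab.c,
                    "n_universe": tab.n_total,
                    "p_value": fisher_one_sided(tab),
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(q_value=[])
    df["q_value"] = 1.0
    for direction in ("positive", "negative"):
        mask = df["direction"] == direction
        df.loc[mask, "q_value"] = bh_adjust(df.loc[mask, "p_value"].to_numpy())
    # input pathway order, both directions per pathway
    order = {name: i for i, (name, _) in enumerate(sets)}
    df["_ord"] = df["pathway"].map(order)
    df = (
        df.sort_values(["_ord", "direction"], ascending=[True, False])
        .drop(columns="_ord")
        .reset_index(drop=True)
    )
    return df
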
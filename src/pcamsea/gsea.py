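"""Set-permutation enrichment analysis on a loading-ranked metabolite list.

The enrichment score (ES) of a metabolite set S on a list of N metabolites
ranked by descending factor loading r is the signed extremum of the
running sum

    P_hit(i)  = sum_{j<=i, j in S} |r_j|^w / sum_{j in S} |r_j|^w
    P_miss(i) = #{j<=i, j not in S} / (N - |S|)
    ES        = (P_hit - P_miss)[argmax |P_hit - P_miss|]

with weight exponent w (w=1, the "weighted" scoring, by default; w=0
recovers the classic Kolmogorov-Smirnov statistic).  The null distribution
is built by rescoring B uniformly random size-matched metabolite subsets
("gene set" permutation — the ranking, and hence the samples, are never
permuted).  NES divides ES by the mean magnitude of same-sign null scores;
p-values use the add-one estimator (b+1)/(B+1) and are therefore never 0.
Positive ES means enrichment at the top of the ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .setio import MetaboliteSetList
from .stats import bh_adjust

__all__ = [
    "RankedList",
    "enrichment_score",
    "permutation_null",
    "normalize_and_test",
    "leading_edge",
    "msea_sub",
]


@dataclass
class RankedList:
    """Metabolite IDs ordered by descending ranking metric.

    Ties in the metric are broken by metabolite ID (stable, deterministic
    ordering).  Build from a fitted PCA via :meth:`from_loadings`.
    """

    metabolite_ids: list[str]
    metric: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.metabolite_ids) != self.metric.size:
            raise ValueError("ids and metric lengths differ")
        if len(set(self.metabolite_ids)) != len(self.metabolite_ids):
            raise ValueError("metabolite ids must be unique")
        if np.any(np.diff(self.metric) > 0):
            raise ValueError("metric must be in descending order")
        self._index = {m: i for i, m in enumerate(self.metabolite_ids)}

    @classmethod
    def from_loadings(cls, metabolite_ids, loadings) -> "RankedList":
        ids = [str(m) for m in metabolite_ids]
        r = np.asarray(loadings, dtype=float)
        order = sorted(range(len(ids)), key=lambda i: (-r[i], ids[i]))
        return cls([ids[i] for i in order], r[order])

    def __len__(self) -> int:
        return self.metric.size

    def rank_of(self, metabolite_id: str) -> int:
        """1-based rank of a metabolite."""
        return self._index[metabolite_id] + 1


def _hit_vector(ranked: RankedList, pathway) -> np.ndarray:
    hits = np.zeros(len(ranked), dtype=bool)
    for m in pathway:
        i = ranked._index.get(str(m))
        if i is not None:
            hits[i] = True
    return hits


def _batch_running(w_abs: np.ndarray, hits: np.ndarray):
    """Running sums for a batch of hit-indicator rows.

    Parameters
    ----------
    w_abs : (N,) nonnegative weights |r|^w in ranked order.
    hits : (B, N) boolean membership indicators.

    Returns (running (B, N), es (B,), argext (B,) 0-based first extremum).
    """
    hits = np.atleast_2d(hits)
    B, N = hits.shape
    n_hit = hits.sum(axis=1, keepdims=True)
    if np.any(n_hit == 0) or np.any(n_hit == N):
        raise ValueError("each set must have 1 <= size < N members in the list")
    hw = hits * w_abs
    denom = hw.sum(axis=1, keepdims=True)
    zero = denom[:, 0] == 0
    if np.any(zero):
        # all hit metrics are exactly 0: fall back to unweighted increments
        warnings.warn("all member loadings are 0; using unweighted increments")
        hw = np.where(zero[:, None], hits, hw)
        denom = np.where(zero[:, None], n_hit, denom)
    p_hit = np.cumsum(hw, axis=1) / denom
    p_miss = np.cumsum(~hits, axis=1) / (N - n_hit)
    running = p_hit - p_miss
    argext = np.argmax(np.abs(running), axis=1)
    es = running[np.arange(B), argext]
    return running, es, argext


def enrichment_score(ranked: RankedList, pathway, weight: float = 1.0):
    """ES of one metabolite set on the ranked list.

    Returns
    -------
    es : float in [-1, 1]
    argext : int
        1-based position where the running sum attains its extremum
        (first such position on ties).
    running : ndarray (N,)
        The full running-sum curve.
    """
    if weight < 0:
        raise ValueError("weight must be >= 0")
    hits = _hit_vector(ranked, pathway)
    n_hit = int(hits.sum())
    if n_hit == 0:
        raise ValueError("pathway has no members in the ranked universe")
    if n_hit == len(ranked):
        raise ValueError("pathway spans the whole universe; ES undefined")
    w_abs = np.abs(ranked.metric) ** weight
    running, es, argext = _batch_running(w_abs, hits[None, :])
    return float(es[0]), int(argext[0]) + 1, running[0]


def permutation_null(
    ranked: RankedList,
    set_size: int,
    weight: float = 1.0,
    B: int = 1000,
    seed=None,
) -> np.ndarray:
    """Null ES sample from B uniformly random size-matched subsets.

    ``seed`` may be an int or a ``numpy.random.Generator``; results are
    reproducible given the seed.
    """
    N = len(ranked)
    if not 1 <= set_size < N:
        raise ValueError(f"set_size must be in [1, {N - 1}]")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # B random subsets without replacement via partial argsort of uniforms
    u = rng.random((B, N))
    idx = np.argpartition(u, set_size - 1, axis=1)[:, :set_size]
    hits = np.zeros((B, N), dtype=bool)
    np.put_along_axis(hits, idx, True, axis=1)
    w_abs = np.abs(ranked.metric) ** weight
    _, es, _ = _batch_running(w_abs, hits)
    return es


def normalize_and_test(es: float, null_es) -> tuple[float, float]:
    """NES and permutation p-value for an observed ES.

    NES = ES / mean(|same-sign null ES|), sign preserved;
    p = (1 + #{same-sign null at least as extreme}) / (1 + #same-sign null).
    If no null score shares the sign of ES, the full null sample magnitude
    is used with a warning.  ES = 0 returns (0.0, 1.0).
    """
    null_es = np.asarray(null_es, dtype=float)
    if null_es.size == 0:
        raise ValueError("empty null sample")
    if es == 0:
        return 0.0, 1.0
    same = null_es > 0 if es > 0 else null_es < 0
    pool = np.abs(null_es[same])
    if pool.size == 0:
        warnings.warn(
            "no null scores share the sign of ES; using the full null sample"
        )
        pool = np.abs(null_es)
    nes = es / pool.mean()
    p = (1 + int((pool >= abs(es)).sum())) / (1 + pool.size)
    return float(nes), float(p)


def leading_edge(ranked: RankedList, pathway, argext: int, es_sign: float):
    """Leading-edge subset of a pathway.

    For ES > 0: members at ranks <= argext; for ES < 0: members at ranks
    >= argext.  ``argext`` is the 1-based extremum position returned by
    :func:`enrichment_score`.
    """
    members = {str(m) for m in pathway} & set(ranked.metabolite_ids)
    if es_sign > 0:
        return {m for m in members if ranked.rank_of(m) <= argext}
    if es_sign < 0:
        return {m for m in members if ranked.rank_of(m) >= argext}
    return set()


def msea_sub(
    sets: MetaboliteSetList,
    ranked: RankedList,
    weight: float = 1.0,
    B: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Set-permutation enrichment analysis over a pathway list.

    Per pathway: ES, NES, add-one permutation p, BH q (adjusted across
    pathways within each ES-sign stratum), and the semicolon-joined
    leading-edge IDs.  Pathways with no member in the ranked universe (or
    spanning all of it) are reported with NaN statistics and a status
    flag, never dropped.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for name, members in sets:
        detected = members & set(ranked.metabolite_ids)
        base = {
            "pathway": name,
            "n_members": len(detected),
            "ES": np.nan,
            "NES": np.nan,
            "p_value": np.nan,
            "q_value": np.nan,
            "leading_edge": "",
            "status": "ok",
        }
        if not detected:
            base["status"] = "no detected members"
            warnings.warn(f"pathway {name!r} has no members in the ranked list")
            rows.append(base)
            continue
        if len(detected) == len(ranked):
            base["status"] = "spans whole universe"
            warnings.warn(f"pathway {name!r} spans the whole universe")
            rows.append(base)
            continue
        es, argext, _ = enrichment_score(ranked, detected, weight=weight)
        null = permutation_null(
            ranked, len(detected), weight=weight, B=B, seed=rng
        )
        nes, p = normalize_and_test(es, null)
        le = leading_edge(ranked, detected, argext, es)
        base.update(
            ES=es,
            NES=nes,
            p_value=p,
            leading_edge=";".join(sorted(le, key=ranked.rank_of)),
        )
        rows.append(base)
    df = pd.DataFrame(rows)
    ok = df["status"] == "ok"
    for stratum in (df["ES"] > 0, df["ES"] <= 0):
        mask = (ok & stratum).to_numpy()
        if mask.any():
            df.loc[mask, "q_value"] = bh_adjust(df.loc[mask, "p_value"].to_numpy())
    df.attrs.update({"weight": weight, "B": B, "seed": seed})
    return df
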
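"""Seeded two-group metabolomics data generator with known ground truth.

Emulates the structure of a small-n CE-MS-style study: two groups of a
few samples each, a few hundred metabolites with positive, right-skewed
abundances (log-normal), a subset of metabolites shifted between groups
on the log scale, and missing-at-random below-detection cells.  Pathway
lists with one designated enriched pathway are generated alongside, so
every downstream stage (loading test, ORA, set-permutation enrichment)
can be validated against a known truth without any external data.

It does not attempt to imitate real peak tables: no migration times, no
internal-standard normalization, and missingness is independent of
abundance by default (a low-abundance-biased mode is available, since
real below-detection cells are abundance-linked).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .setio import MetaboliteSetList
from .table import MetaboliteTable

__all__ = ["SyntheticSpec", "generate_two_group_matrix", "generate_pathway_sets"]


@dataclass
class SyntheticSpec:
    """Parameters of the two-group generator.

    Defaults emulate a 5-vs-5 mouse liver study with ~280 detected
    metabolites, about a fifth of them responding to the condition with a
    3-within-group-SD shift on the log scale, and 5% missing cells.

    Attributes
    ----------
    n_per_group : samples per group.
    n_metabolites : detected metabolites.
    n_affected : metabolites shifted between groups.
    effect_size : shift in within-group (log-scale) SD units.
    missing_rate : per-cell missingness probability in [0, 1).
    n_pathways : pathways generated; the first is the enriched one.
    pathway_size : members per pathway.
    enriched_fraction_of_affected : fraction of the enriched pathway's
        members drawn from the affected (truth) set.
    seed : RNG seed.
    """

    n_per_group: int = 5
    n_metabolites: int = 280
    n_affected: int = 60
    effect_size: float = 3.0
    missing_rate: float = 0.05
    n_pathways: int = 25
    pathway_size: int = 10
    enriched_fraction_of_affected: float = 1.0
    seed: int = 0
    missing_mode: str = "mcar"  # or "low-abundance"
    shift_direction: str = "up"  # or "mixed"

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_affected > self.n_metabolites:
            raise ValueError("n_affected exceeds n_metabolites")
        if self.pathway_size > self.n_metabolites:
            raise ValueError("pathway_size exceeds n_metabolites")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.enriched_fraction_of_affected <= 1:
            raise ValueError("enriched_fraction_of_affected must be in [0, 1]")
        if self.missing_mode not in ("mcar", "low-abundance"):
            raise ValueError(f"unknown missing_mode {self.missing_mode!r}")
        if self.shift_direction not in ("up", "mixed"):
            raise ValueError(f"unknown shift_direction {self.shift_direction!r}")


def _metabolite_ids(p: int) -> list[str]:
    width = max(3, len(str(p)))
    return [f"M{j + 1:0{width}d}" for j in range(p)]


def generate_two_group_matrix(spec: SyntheticSpec):
    """Generate the abundance matrix and the set of truly affected IDs.

    Baseline log-abundances are Normal(mu_m, sigma_m) with per-metabolite
    mu_m ~ N(3, 1) and within-group SD sigma_m ~ U(0.2, 0.6); abundances
    are exp of these.  Affected metabolites are shifted in group 2 by
    ``effect_size * sigma_m`` on the log scale — upward by default, or
    with a random sign per metabolite if ``shift_direction="mixed"``.
    Missing cells are masked independently at ``missing_rate`` (MCAR) or
    preferentially at low abundance.

    Returns
    -------
    table : MetaboliteTable with group labels ``g1`` / ``g2``.
    truth : set of affected metabolite IDs.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_per_group, spec.n_metabolites
    ids = _metabolite_ids(p)
    mu = rng.normal(3.0, 1.0, size=p)
    sigma = rng.uniform(0.2, 0.6, size=p)
    affected_idx = rng.choice(p, size=spec.n_affected, replace=False)
    shift = np.zeros(p)
    sign = (
        rng.choice([-1.0, 1.0], size=spec.n_affected)
        if spec.shift_direction == "mixed"
        else 1.0
    )
    shift[affected_idx] = spec.effect_size * sigma[affected_idx] * sign
    log_x = rng.normal(mu, sigma, size=(2 * n, p))
    log_x[n:] += shift
    values = np.exp(log_x)
    if spec.missing_rate > 0:
        if spec.missing_mode == "mcar":
            mask = rng.random(values.shape) < spec.missing_rate
        else:
            # low-abundance-biased: missingness probability proportional to
            # the within-column rank of -abundance, scaled to the target rate
            ranks = np.argsort(np.argsort(-values, axis=0), axis=0)
            prob = 2 * spec.missing_rate * (ranks + 0.5) / values.shape[0]
            mask = rng.random(values.shape) < prob
        values = np.where(mask, np.nan, values)
    samples = [f"g1_s{i + 1}" for i in range(n)] + [f"g2_s{i + 1}" for i in range(n)]
    labels = ["g1"] * n + ["g2"] * n
    table = MetaboliteTable(values, samples, ids, labels)
    truth = {ids[j] for j in affected_idx}
    return table, truth


def generate_pathway_sets(spec: SyntheticSpec, truth) -> MetaboliteSetList:
    """Generate pathway sets with one designated enriched pathway.

    The first pathway, named ``"enriched"``, draws
    ``enriched_fraction_of_affected`` of its members from the truth set
    (the rest from unaffected metabolites); the remaining pathways sample
    uniformly from the unaffected metabolites.  Sizes match
    ``spec.pathway_size`` exactly.
    """
    rng = np.random.default_rng(spec.seed + 1)
    ids = _metabolite_ids(spec.n_metabolites)
    truth = sorted({str(m) for m in truth})
    rest = [m for m in ids if m not in set(truth)]
    sets = MetaboliteSetList()
    if spec.n_pathways == 0:
        return sets
    k_true = round(spec.enriched_fraction_of_affected * spec.pathway_size)
    k_true = min(k_true, len(truth))
    k_rest = spec.pathway_size - k_true
    if k_rest > len(rest):
        raise ValueError("not enough unaffected metabolites for pathway sets")
    members = list(rng.choice(truth, size=k_true, replace=False)) + list(
        rng.choice(rest, size=k_rest, replace=False)
    )
    sets.add("enriched", members)
    width = max(2, len(str(spec.n_pathways)))
    for i in range(1, spec.n_pathways):
        if spec.pathway_size > len(rest):
            raise ValueError("not enough unaffected metabolites for pathway sets")
        sets.add(
            f"background_{i:0{width}d}",
            rng.choice(rest, size=spec.pathway_size, replace=False),
        )
    return sets
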
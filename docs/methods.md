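# Methods

## Model and procedure

Let **X** be the n × p matrix of metabolite abundances, samples in rows.
The workflow is:

1. **Zero imputation.** Missing cells are treated as below-detection and
   replaced by 0 on the raw abundance scale, before any centering or
   scaling.  This is the package's only imputation rule; other schemes can
   be applied upstream by the user.
2. **Autoscaling.** Each column is standardized to mean 0 and unit
   *sample* variance (n−1 divisor throughout the package).  Columns with
   zero variance (including columns that became all-zero through
   imputation) are rejected with an explicit error naming the metabolite;
   `drop_constant=True` (CLI `--drop-constant`) drops them with a warning
   instead.  Silent NaN propagation is never allowed.
3. **PCA.** The eigenvalue problem X′Xw/(n−1) = λw is solved by singular
   value decomposition of the autoscaled matrix.  Scores are t = Xw;
   var(t_k) = λ_k; the contribution ratio of component k is 100·λ_k/Σλ.
   Components with λ ≤ 1e−12·λ₁ are numerical null-space directions and
   are discarded.
4. **Factor loadings.** r_pk = corr(t_k, x_p), computed directly as a
   Pearson correlation.  On autoscaled data this equals √λ_k·w_pk; the
   identity is enforced as a test invariant (agreement < 1e−8, observed
   ~1e−14).
5. **Loading test.** t = r√(n−2)/√(1−r²) against a central t-distribution
   with n−2 df, two-sided; BH step-up q-values across metabolites within
   each component.  |r| = 1 is reported as p = 0 with an infinite-t
   sentinel rather than overflowing.  The test requires n ≥ 3.
6. **Selection.** Metabolites with p (default; optionally q) below α are
   split by loading sign on a user-selected component into a positive and
   a negative set.
7. **MSEA.** Either overrepresentation (ORA) of each direction, or a
   permutation enrichment analysis of the full loading-ranked list.

## Statistical conventions and parameters

| Parameter | Default | Meaning |
|---|---|---|
| `alpha` | 0.05 | significance level on the per-metabolite loading test (dimensionless) |
| `use_q` | off | threshold BH q-values instead of raw p-values when selecting |
| sidedness | two-sided | thresholds at both loading signs; one direction can be read from the sign split |
| `weight` | 1.0 | GSEA weight exponent on \|r\|; 0 gives the classic Kolmogorov–Smirnov statistic |
| `B` | 1000 | permutation count for the GSEA null; seeded, and the seed is part of the result metadata |
| universe | detected metabolites | ORA background = all metabolites in the matrix (after any constant-column drops); pathway sets are intersected with it before testing |

**ORA.** One-sided Fisher's exact test, p = P(X ≥ a) for the
hypergeometric upper tail, computed with exact integer arithmetic
(`math.comb` + `fractions.Fraction`) and converted to float once.
Metabolites in several pathways count independently per pathway
(KEGG-style overlapping sets are expected).  BH adjustment runs across
pathways within each loading direction separately, matching the
per-direction column layout of enrichment tables.

**Permutation GSEA.** The running sum accumulates |r|^weight over set
members (normalized by the member total) minus a uniform miss penalty
1/(N−N_H); ES is the signed deviation of maximum absolute value, the first
such position on ties.  A set spanning the whole ranked list, or none of
it, has no defined ES; `enrichment_score` raises, while the batch driver
`msea_sub` reports such pathways with NaN statistics and a status flag
instead of dropping them.  The null distribution rescores B uniformly
random size-matched subsets of the universe ("gene set" permutation — the
class labels and the ranking are never permuted; the class-label variant
is deliberately not implemented).  NES divides ES by the mean magnitude of
same-sign null scores; p = (b+1)/(B+1) (add-one rule, never exactly 0);
q-values are BH within each ES-sign stratum, consistent with the
package-wide BH convention — note this is a dialect choice, not the
NES-ratio FDR of the original GSEA software.  Positive ES means enrichment
at the top of the ranking (large positive loadings).  The leading edge is
the set members at ranks ≤ argext for positive ES, ≥ argext for negative.

**Welch baseline.** t = (m₁−m₂)/√(s₁²/n₁+s₂²/n₂) with
Welch–Satterthwaite df, two-sided, computed from group summaries or per
metabolite column (after zero imputation); "±" summary inputs are sample
SDs.  Both groups constant with equal means gives t = 0, p = 1; with
unequal means the summary route raises, and the per-metabolite route
reports an infinite-t, p = 0 sentinel.

## Numerical and determinism choices

- **Eigenvector sign** is arbitrary; it is fixed so the largest-|entry|
  element of each weight vector is positive (ties: lowest metabolite
  index), making output stable across linear-algebra backends.  The
  biological orientation of a PC is still read from the scores plot.
- **Eigenvalue ties** (exactly equal λ) are ordered by the lexicographic
  order of the sign-fixed weight vectors.  Degenerate subspaces have no
  canonical basis; only bit-stable output for a given input is promised,
  not equivariance under column permutation.
- **Rank ties** in the loading metric are broken by metabolite ID (stable
  secondary sort), so ranked lists and leading edges are deterministic.
- All randomness flows through `numpy.random.Generator` seeds;
  `msea_sub` and the generator are byte-reproducible given a seed.

## The synthetic generator

`SyntheticSpec` emulates a small-n two-group CE-MS-style study: baseline
log-abundances Normal(μ_m, σ_m) with μ_m ~ N(3, 1) and within-group SD
σ_m ~ U(0.2, 0.6) (abundances are the exponentials: positive and
right-skewed, so autoscaling behaves as it does on real data); a chosen
subset of metabolites is shifted in group 2 by `effect_size`·σ_m on the
log scale (upward by default; `shift_direction="mixed"` randomizes the
sign per metabolite); cells are masked missing independently at
`missing_rate` (MCAR) or, optionally, with probability increasing toward
low abundance (closer to how below-detection arises in practice — the
zero-imputation rule implicitly assumes below-detection ≈ 0).  Defaults
(5 per group, 280 metabolites, 60 affected at 3 SD, 5% missing, 25
pathways of 10, one fully enriched) mirror the scale of a typical mouse
liver study.  The pathway generator plants one pathway (named
`"enriched"`) drawing a chosen fraction of its members from the affected
set; background pathways sample only unaffected metabolites.

What the generator does *not* emulate: correlated metabolite blocks,
instrument drift, internal-standard normalization artifacts, or
abundance-dependent variance beyond the log-normal form.  Passing
recovery tests therefore show the pipeline's statistics behave correctly
under the stated model, not that real studies will reach the same power.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use: 50 random matrices
(n 5–20, p 10–200) for the loading identity; exhaustive enumeration of
all 2×2 tables with total ≤ 30 against an independent hypergeometric
oracle; 500 random ranked lists (N ≤ 50) against a brute-force running
sum; 1,000 random p-vectors against an independently coded BH step-up;
10⁵-permutation correlation nulls at n = 20 and 20,000 independent vector
pairs for the type-I error; 100 replicate synthetic studies (5 vs 5, 100
metabolites, 20 affected at 3 SD, 10 pathways of 10, B = 1000) for
end-to-end recovery.

## Known limitations

- **Selection bias.** The tested PC score is derived from the same data
  whose correlations with it are tested.  Under a global null this
  inflates significance relative to the nominal t-distribution (the PC is
  chosen to maximize variance).  The procedure is implemented as defined —
  the t reference is exact for correlations with an independently fixed
  vector — and no correction is applied; treat borderline p-values on
  self-derived scores with caution.
- **Permutation vs t reference.** The randomization distribution of a
  correlation for fixed vectors approaches the t law only as n grows; at
  n ≲ 10 the far tail can deviate noticeably.  The calibration checks run
  at n = 20.
- **Printed-summary precision.** Welch p-values recomputed from rounded
  published group summaries (e.g. 22.20 ± 0.84) can differ from the value
  computed on the raw data in the last significant digit; propagating the
  input rounding gives an uncertainty of roughly one unit in the second
  significant figure of p.
- **ES sign reading.** Positive ES/NES here always means enrichment at
  the top (large positive loadings).  Published MSEA tables sometimes
  describe sets "activated" in the group with *negative* scores, so the
  verbal reading of a sign can differ between sources; this package never
  reinterprets signs.
- The XML dialect (`pathway_list`/`pathway name`/`metabolite id`) is this
  package's own documented schema; compatibility with other tools' pathway
  XML files is not claimed.  KEGG archive ingestion, ID normalization and
  topology-aware pathway analysis are out of scope.
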
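"""PCA with exact significance testing of factor loadings.

The factor loading of metabolite *p* on component *k* is defined as the
Pearson correlation ``r = corr(t_k, x_p)`` between the PC score vector and
the metabolite's abundance vector.  For autoscaled data this correlation
equals ``sqrt(lambda_k) * w[p, k]``, i.e. the eigenvector scaled by the
square root of its eigenvalue — which is what makes an exact test
possible: under the null hypothesis of no correlation the statistic

    t = r * sqrt(n - 2) / sqrt(1 - r**2)

follows a central t-distribution with ``n - 2`` degrees of freedom, so
each metabolite receives an exact two-sided p-value and a BH q-value.

A caveat worth stating: in practice the tested PC score is derived from
the same data whose correlations with it are tested.  Under a global null
this selection inflates significance relative to the nominal
t-distribution.  The procedure is implemented as defined (the test is
exact for correlations with an independently fixed vector); interpret
borderline p-values on self-derived scores with care.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import autoscale, impute_missing_zero
from .stats import bh_adjust
from .table import MetaboliteTable

__all__ = [
    "PCAResult",
    "fit_pca",
    "factor_loadings",
    "loading_test",
    "select_significant",
    "pca_loading_test",
    "LoadingTestPCA",
]

# components with eigenvalue below RETAIN_RTOL * lambda_1 are numerically
# null-space directions and are not retained
RETAIN_RTOL = 1e-12


@dataclass
class PCAResult:
    """Fitted PCA with per-metabolite loading tests.

    Attributes
    ----------
    scores : ndarray (n, K)
        PC score vectors ``t_k`` of the fitting data.
    weights : ndarray (p, K)
        Unit-norm eigenvectors ``w_k`` of the sample covariance of the
        autoscaled matrix.
    eigenvalues : ndarray (K,)
        ``lambda_k`` in descending order; equals ``var(t_k)`` (ddof=1).
    contribution_ratios : ndarray (K,)
        ``100 * lambda_k / sum(lambda)`` in percent, the denominator
        summing over *all* (retained and discarded) components.
    column_sd : ndarray (p,)
        Pre-scaling sample SD of each metabolite.
    loadings : ndarray (p, K)
        Correlations ``corr(t_k, x_p)`` in [-1, 1].
    t_stats, p_values, q_values : ndarray (p, K)
        Loading test statistics, two-sided p-values, and BH q-values
        (adjusted across metabolites within each component).
    n_samples : int
    metabolite_ids, sample_ids : list of str
    """

    scores: np.ndarray
    weights: np.ndarray
    eigenvalues: np.ndarray
    contribution_ratios: np.ndarray
    column_sd: np.ndarray
    loadings: np.ndarray
    t_stats: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    n_samples: int
    metabolite_ids: list[str]
    sample_ids: list[str]

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size


def _fix_signs(weights: np.ndarray, scores: np.ndarray) -> None:
    """Orient each eigenvector so its largest-|entry| element is positive.

    Ties are broken by the lowest metabolite index (argmax returns the
    first maximum).  Scores are flipped consistently, in place.
    """
    for k in range(weights.shape[1]):
        j = int(np.argmax(np.abs(weights[:, k])))
        if weights[j, k] < 0:
            weights[:, k] *= -1
            scores[:, k] *= -1


def fit_pca(scaled: np.ndarray):
    """Eigendecompose the sample covariance of a column-centered matrix.

    Solves ``X'X w / (n-1) = lambda w`` via SVD.  Components with
    eigenvalue below ``RETAIN_RTOL * lambda_1`` are discarded.  Returns
    ``(scores, weights, eigenvalues, total_variance)`` with deterministic
    eigenvector signs and, among exactly tied eigenvalues, components
    ordered by the lexicographic order of their sign-fixed weight vectors.
    """
    X = np.asarray(scaled, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA requires at least 2 samples")
    _, s, Vt = np.linalg.svd(X, full_matrices=False)
    eigvals = s**2 / (n - 1)
    total = float(eigvals.sum())
    if total == 0:
        raise ValueError("matrix has no variance")
    keep = eigvals > RETAIN_RTOL * eigvals[0]
    eigvals = eigvals[keep]
    weights = Vt[keep].T.copy()
    scores = X @ weights
    _fix_signs(weights, scores)
    # deterministic order among exactly tied eigenvalues
    k = 0
    K = eigvals.size
    while k < K:
        j = k
        while j + 1 < K and eigvals[j + 1] == eigvals[k]:
            j += 1
        if j > k:
            block = range(k, j + 1)
            order = sorted(block, key=lambda c: tuple(weights[:, c]))
            weights[:, k : j + 1] = weights[:, order]
            scores[:, k : j + 1] = scores[:, order]
        k = j + 1
    return scores, weights, eigvals, total


def factor_loadings(scores: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Correlation of each PC score vector with each data column.

    Computed directly as ``cov(t_k, x_p) / (sd(t_k) sd(x_p))``; for
    autoscaled input this equals ``sqrt(lambda_k) * w[p, k]``.
    """
    T = np.asarray(scores, dtype=float)
    X = np.asarray(data, dtype=float)
    n = X.shape[0]
    Tc = T - T.mean(axis=0)
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Tc / (n - 1)
    sd_t = T.std(axis=0, ddof=1)
    sd_x = X.std(axis=0, ddof=1)
    if (sd_t == 0).any():
        raise ValueError("zero-variance score vector: loadings undefined")
    if (sd_x == 0).any():
        raise ValueError("zero-variance data column: loadings undefined")
    return cov / np.outer(sd_x, sd_t)


def loading_test(loadings, n: int):
    """Exact t-test of correlation loadings against zero.

    ``t = r sqrt(n-2) / sqrt(1-r^2)`` with a central t_{n-2} reference;
    two-sided by default throughout the package.  ``r = +/-1`` yields an
    infinite-t sentinel and ``p = 0``.

    Returns
    -------
    t_stats, p_values : ndarray matching the shape of ``loadings``.
    """
    if n < 3:
        raise ValueError("insufficient samples for the n-2 df loading test")
    r = np.asarray(loadings, dtype=float)
    if np.abs(r).max(initial=0.0) > 1 + 1e-8:
        raise ValueError("|loading| exceeds 1 beyond numerical tolerance")
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    at_one = np.abs(r) == 1.0
    t = np.where(at_one, np.where(r > 0, np.inf, -np.inf), t)
    p = np.where(at_one, 0.0, 2.0 * sps.t.sf(np.abs(t), df=n - 2))
    return t, p


def select_significant(
    result: PCAResult,
    component: int = 1,
    alpha: float = 0.05,
    use_q: bool = False,
) -> tuple[set[str], set[str]]:
    """Split significant metabolites by loading sign on one component.

    Parameters
    ----------
    component : int
        1-based component index.
    alpha : float
        Significance threshold on the raw p-value (or the BH q-value if
        ``use_q``).

    Returns
    -------
    positive, negative : sets of metabolite IDs (disjoint).
    """
    if not 1 <= component <= result.n_components:
        raise ValueError(
            f"component {component} out of range 1..{result.n_components}"
        )
    k = component - 1
    crit = result.q_values[:, k] if use_q else result.p_values[:, k]
    sig = crit < alpha
    r = result.loadings[:, k]
    ids = np.asarray(result.metabolite_ids, dtype=object)
    return set(ids[sig & (r > 0)]), set(ids[sig & (r < 0)])


def pca_loading_test(
    table: MetaboliteTable, drop_constant: bool = False
) -> PCAResult:
    """Full pipeline: zero-impute, autoscale, PCA, loading test, BH adjust.

    ``drop_constant`` drops zero-variance metabolites (after imputation)
    with a warning instead of raising.
    """
    import warnings

    filled = impute_missing_zero(table)
    ids = list(filled.metabolite_ids)
    X = filled.values
    sds = X.std(axis=0, ddof=1)
    if drop_constant and (sds == 0).any():
        bad = np.flatnonzero(sds == 0)
        warnings.warn(
            "dropping zero-variance metabolite(s): "
            + ", ".join(ids[j] for j in bad)
        )
        keepcol = sds > 0
        X = X[:, keepcol]
        ids = [m for m, k in zip(ids, keepcol) if k]
        if not ids:
            raise ValueError("all metabolites are constant")
    scaled, _, col_sd = autoscale(
        MetaboliteTable(X, filled.sample_ids, ids, filled.group_labels)
    )
    scores, weights, eigvals, total = fit_pca(scaled)
    load = factor_loadings(scores, scaled)
    t, p = loading_test(load, table.n_samples)
    q = np.column_stack([bh_adjust(p[:, k]) for k in range(p.shape[1])])
    return PCAResult(
        scores=scores,
        weights=weights,
        eigenvalues=eigvals,
        contribution_ratios=100.0 * eigvals / total,
        column_sd=col_sd,
        loadings=load,
        t_stats=t,
        p_values=p,
        q_values=q,
        n_samples=table.n_samples,
        metabolite_ids=ids,
        sample_ids=list(table.sample_ids),
    )


class LoadingTestPCA(BaseEstimator, TransformerMixin):
    """PCA transformer with per-metabolite loading significance tests.

    A scikit-learn style estimator: ``fit`` zero-imputes missing cells,
    autoscales each metabolite, fits PCA and runs the exact loading test;
    ``transform`` projects (new) data onto the fitted components using the
    stored means/SDs.

    Parameters
    ----------
    alpha : float, default 0.05
        Significance level used by :meth:`significant_sets`.
    use_q : bool, default False
        Threshold BH q-values instead of raw p-values.
    drop_constant : bool, default False
        Drop zero-variance metabolites with a warning instead of raising.

    Attributes
    ----------
    result_ : PCAResult
        The full fitted result.
    loadings_, p_values_, q_values_ : ndarray (p, K)
    eigenvalues_, contribution_ratios_ : ndarray (K,)
    mean_, scale_ : ndarray (p,)
    feature_names_in_ : ndarray of metabolite IDs used in the fit.
    n_components_ : int
    """

    def __init__(self, alpha: float = 0.05, use_q: bool = False,
                 drop_constant: bool = False):
        self.alpha = alpha
        self.use_q = use_q
        self.drop_constant = drop_constant

    def _as_table(self, X) -> MetaboliteTable:
        if isinstance(X, MetaboliteTable):
            return X
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            return MetaboliteTable.from_dataframe(X)
        X = np.asarray(X, dtype=float)
        return MetaboliteTable(
            X,
            [f"s{i}" for i in range(X.shape[0])],
            [f"m{j}" for j in range(X.shape[1])],
        )

    def fit(self, X, y=None):
        table = self._as_table(X)
        res = pca_loading_test(table, drop_constant=self.drop_constant)
        self.result_ = res
        filled = impute_missing_zero(table)
        cols = [table.metabolite_ids.index(m) for m in res.metabolite_ids]
        sub = filled.values[:, cols]
        self.mean_ = sub.mean(axis=0)
        self.scale_ = res.column_sd
        self.weights_ = res.weights
        self.loadings_ = res.loadings
        self.t_stats_ = res.t_stats
        self.p_values_ = res.p_values
        self.q_values_ = res.q_values
        self.eigenvalues_ = res.eigenvalues
        self.contribution_ratios_ = res.contribution_ratios
        self.scores_ = res.scores
        self.n_samples_ = res.n_samples
        self.n_components_ = res.n_components
        self.feature_names_in_ = np.asarray(res.metabolite_ids, dtype=object)
        return self

    def transform(self, X):
        if not hasattr(self, "result_"):
            raise RuntimeError("LoadingTestPCA is not fitted")
        table = self._as_table(X)
        filled = impute_missing_zero(table)
        idx = {m: j for j, m in enumerate(table.metabolite_ids)}
        missing = [m for m in self.feature_names_in_ if m not in idx]
        if missing:
            raise ValueError(f"metabolites absent from input: {missing[:5]}")
        cols = [idx[m] for m in self.feature_names_in_]
        Xs = (filled.values[:, cols] - self.mean_) / self.scale_
        return Xs @ self.weights_

    def significant_sets(self, component: int = 1, alpha=None, use_q=None):
        """Positive/negative significant metabolite ID sets for a component."""
        if not hasattr(self, "result_"):
            raise RuntimeError("LoadingTestPCA is not fitted")
        return select_significant(
            self.result_,
            component=component,
            alpha=self.alpha if alpha is None else alpha,
            use_q=self.use_q if use_q is None else use_q,
        )
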
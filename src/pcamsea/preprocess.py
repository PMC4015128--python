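"""Preprocessing: zero imputation of missing cells and autoscaling.

Missing abundances are treated as below-detection and replaced by 0 on the
raw scale *before* centering/scaling; each metabolite column is then
standardized to zero mean and unit sample variance (n-1 divisor).
"""

from __future__ import annotations

import numpy as np

from .table import MetaboliteTable

__all__ = ["impute_missing_zero", "autoscale"]


def impute_missing_zero(table: MetaboliteTable) -> MetaboliteTable:
    """Replace every missing (NaN) cell with 0 on the raw abundance scale.

    Non-missing cells are unchanged.  A column that was entirely missing
    becomes all-zero and will later be rejected (or dropped) by
    :func:`autoscale` as zero-variance.
    """
    out = table.copy()
    out.values = np.nan_to_num(out.values, nan=0.0)
    return out


def autoscale(data) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardize each metabolite column to mean 0 and sample variance 1.

    Parameters
    ----------
    data : MetaboliteTable or ndarray
        Complete (no missing cells) samples x metabolites matrix.

    Returns
    -------
    scaled, means, sds : ndarray
        The autoscaled matrix and the original column means and sample
        standard deviations (ddof=1).

    Raises
    ------
    ValueError
        If any cell is missing or any column has zero sample variance;
        the error names the offending metabolite IDs (or column indices).
    """
    if isinstance(data, MetaboliteTable):
        X = data.values
        ids = data.metabolite_ids
    else:
        X = np.asarray(data, dtype=float)
        ids = [str(j) for j in range(X.shape[1])]
    if np.isnan(X).any():
        raise ValueError(
            "matrix contains missing cells; apply impute_missing_zero first"
        )
    if X.shape[0] < 2:
        raise ValueError("autoscaling requires at least 2 samples")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        names = ", ".join(ids[j] for j in bad)
        raise ValueError(f"zero-variance metabolite column(s): {names}")
    return (X - means) / sds, means, sds
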
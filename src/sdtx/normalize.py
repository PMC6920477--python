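"""Quantile normalization of a genes × samples log-intensity matrix.

Each sample's empirical distribution is replaced by the across-sample mean of
order statistics, so after normalization every sample carries an identical
multiset of values while within-sample rank order is preserved.  Ties within
a sample receive the mean of the tied reference quantiles (the common
dialect).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import ExpressionStudy


def quantile_normalize(study: ExpressionStudy) -> ExpressionStudy:
    """Return a new study whose samples share the mean-order-statistic
    distribution.

    Raises
    ------
    ValueError
        If the study has fewer than two samples (nothing to normalize
        against).
    """
    if study.n_samples < 2:
        raise ValueError("quantile normalization needs at least two samples")
    normalized = quantile_normalize_frame(study.values)
    return ExpressionStudy(normalized, study.samples)


def quantile_normalize_frame(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize the columns of a genes × samples DataFrame."""
    x = values.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    order = np.argsort(x, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(x, order, axis=0)
    reference = sorted_vals.mean(axis=1)

    out = np.empty_like(x)
    for j in range(n_samples):
        # assign reference quantiles by rank; average over ties
        ranks = np.empty(n_genes, dtype=int)
        ranks[order[:, j]] = np.arange(n_genes)
        col = reference[ranks]
        # ties: mean of the tied reference values
        uniq, inv, counts = np.unique(x[:, j], return_inverse=True, return_counts=True)
        if len(uniq) < n_genes:
            sums = np.bincount(inv, weights=col)
            col = (sums / counts)[inv]
        out[:, j] = col
    return pd.DataFrame(out, index=values.index, columns=values.columns)
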
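"""Feature preprocessing: [0,1] min-max scaling and variance-threshold PCA.

Every featurization is scaled column-wise into [0,1] and reduced by PCA to
the smallest number of components whose cumulative explained-variance ratio
reaches the configured cutoff (default 0.95).  Scores are centered; no
unit-variance scaling is applied beyond the min-max step.

By default the normalizer and PCA are fit on the full cohort before
cross-validation, matching the study workflow; fitting them inside each
training fold (leakage-free) is available downstream via
``refit_per_fold`` in the evaluation module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datatypes import FeatureTable


@dataclass
class FittedRanges:
    """Column minima/maxima from the fit, for reuse on new rows."""

    minima: pd.Series
    maxima: pd.Series

    def apply(self, table: FeatureTable) -> FeatureTable:
        df = table.data
        if list(df.columns) != list(self.minima.index):
            raise ValueError("column mismatch with fitted ranges")
        span = (self.maxima - self.minima).replace(0, np.nan)
        scaled = (df - self.minima) / span
        scaled = scaled.fillna(0.0)  # constant columns map to 0
        return FeatureTable(scaled, provenance=table.provenance)


def minmax_normalize(table: FeatureTable) -> tuple[FeatureTable, FittedRanges]:
    """Scale each column to [0,1]; a constant column maps to all zeros."""
    if len(table) == 0 or table.n_features == 0:
        raise ValueError("cannot normalize an empty table")
    ranges = FittedRanges(minima=table.data.min(axis=0), maxima=table.data.max(axis=0))
    return ranges.apply(table), ranges


@dataclass
class PCAReduction:
    """Fitted reduction: loadings, explained-variance ratios, chosen rank."""

    n_components: int
    cumulative_variance: float
    loadings: np.ndarray                 # (n_components, n_features)
    explained_variance_ratio: np.ndarray
    column_mean: np.ndarray
    cutoff: float

    def transform(self, table: FeatureTable) -> FeatureTable:
        x = table.values - self.column_mean[None, :]
        scores = x @ self.loadings.T
        df = pd.DataFrame(scores, index=table.data.index,
                          columns=[f"pc{i + 1}" for i in range(self.n_components)])
        return FeatureTable(df, provenance=table.provenance)


def pca_reduce(table: FeatureTable, cutoff: float = 0.95) -> tuple[FeatureTable, PCAReduction]:
    """Reduce a normalized table to the minimal rank reaching ``cutoff``.

    ``n_components`` is the smallest m with cumulative explained-variance
    ratio >= cutoff; a cumulative ratio exactly at the cutoff includes that
    component ("keep 95%" read as >=).
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    if len(table) < 2:
        raise ValueError("PCA needs at least 2 rows")
    x = table.values
    max_rank = min(x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=max_rank, svd_solver="full")
    pca.fit(x)
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    # degenerate zero-variance data: everything is explained by any rank
    if cum[-1] <= 0:
        m = 1
    else:
        reached = np.nonzero(cum >= cutoff - 1e-12)[0]
        m = int(reached[0]) + 1 if len(reached) else max_rank
    reduction = PCAReduction(
        n_components=m,
        cumulative_variance=float(cum[m - 1]),
        loadings=pca.components_[:m],
        explained_variance_ratio=ratios[:m],
        column_mean=pca.mean_,
        cutoff=cutoff,
    )
    return reduction.transform(table), reduction


def preprocess_table(
    table: FeatureTable, cutoff: float = 0.95
) -> tuple[FeatureTable, FittedRanges, PCAReduction]:
    """Convenience: min-max scale then PCA-reduce in one call."""
    normalized, ranges = minmax_normalize(table)
    scores, reduction = pca_reduce(normalized, cutoff=cutoff)
    return scores, ranges, reduction
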
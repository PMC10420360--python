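"""Molecule clustering in PC space and cluster-composition percentages.

The qualitative comparison of featurizations asks: when molecules are
clustered on their (preprocessed) features, do the frequent odor descriptors
concentrate in distinct clusters or pile into one?  Molecules are clustered
agglomeratively in principal-component space (Ward linkage pairs naturally
with the variance-based elbow criterion used to pick the cluster count), and
each top descriptor's positives are apportioned across clusters as
percentages of its total positives — the radar-chart data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .datatypes import DescriptorMatrix, FeatureTable

logger = logging.getLogger(__name__)


def cluster_molecules(
    scores: FeatureTable, n_clusters: int, method: str = "ward"
) -> pd.Series:
    """Agglomerative clustering on Euclidean distance in PC space.

    Returns a Series molecule-id -> cluster index in 1..n_clusters; every
    cluster is non-empty.
    """
    x = scores.values
    if not np.isfinite(x).all():
        raise ValueError("scores contain non-finite values")
    if not 1 <= n_clusters <= len(scores):
        raise ValueError(f"n_clusters must be in [1, {len(scores)}]")
    if n_clusters == 1 or len(scores) == 1:
        labels = np.ones(len(scores), dtype=int)
    else:
        z = linkage(x, method=method)
        labels = fcluster(z, t=n_clusters, criterion="maxclust")
    return pd.Series(labels.astype(int), index=scores.data.index, name="cluster")


def within_cluster_ss(x: np.ndarray, assignments: np.ndarray) -> float:
    """Total squared distance to each cluster's centroid."""
    total = 0.0
    for c in np.unique(assignments):
        pts = x[assignments == c]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def elbow_curve(scores: FeatureTable, k_range: range, method: str = "ward") -> pd.Series:
    """W(k), the within-cluster sum of squares, for each k in the range."""
    x = scores.values
    return pd.Series(
        {k: within_cluster_ss(x, cluster_molecules(scores, k, method).to_numpy())
         for k in k_range},
        name="wcss",
    )


def elbow_select(scores: FeatureTable, k_range: range, method: str = "ward") -> int:
    """Cluster count at the elbow of the W(k) curve.

    Picks the interior k maximizing the second difference
    W(k-1) - 2 W(k) + W(k+1) (ties to the smallest k).  A flat curvature —
    e.g. all points identical — has no elbow and yields the smallest k in
    the range.
    """
    ks = list(k_range)
    if len(ks) < 3:
        raise ValueError("k_range must contain at least 3 values")
    if ks[0] < 1 or ks[-1] > len(scores) - 1:
        raise ValueError(f"k_range must lie within [1, {len(scores) - 1}]")
    w = elbow_curve(scores, k_range, method)
    second = {k: w[k - 1] - 2 * w[k] + w[k + 1] for k in ks[1:-1]}
    values = np.array(list(second.values()))
    if np.allclose(values, values[0]):
        return ks[0]
    best = max(second, key=lambda k: (second[k], -k))
    return int(best)


@dataclass
class CompositionResult:
    """Cluster assignments plus the per-descriptor cluster percentages.

    ``percentages`` has one row per top descriptor and one column per
    cluster; each row sums to 100 (every positive sample belongs to exactly
    one cluster).  ``totals`` holds the positive counts the rows divide by.
    """

    assignments: pd.Series
    percentages: pd.DataFrame
    totals: pd.Series

    def __post_init__(self) -> None:
        sums = self.percentages.sum(axis=1)
        if not np.allclose(sums, 100.0, atol=1e-9):
            raise ValueError("per-descriptor percentages must sum to 100")

    def to_frame(self) -> pd.DataFrame:
        df = self.percentages.copy()
        df.insert(0, "total_positives", self.totals)
        return df.reset_index(names="descriptor")


def top_descriptors(labels: DescriptorMatrix, top_n: int) -> list[str]:
    """The top_n descriptors by positive count (ties broken lexicographically)."""
    if top_n > len(labels.vocabulary):
        raise ValueError("top_n exceeds the vocabulary size")
    counts = labels.positives()
    ranked = sorted(counts.index, key=lambda d: (-counts[d], str(d)))
    return [str(d) for d in ranked[:top_n]]


def descriptor_percentages(
    assignments: pd.Series, labels: DescriptorMatrix, top_n: int = 7
) -> CompositionResult:
    """Share of each top descriptor's positives falling in each cluster."""
    if not assignments.index.equals(labels.data.index):
        raise ValueError("assignments and labels are not row-aligned")
    chosen = top_descriptors(labels, top_n)
    clusters = sorted(assignments.unique())
    counts = labels.positives()
    rows, totals = {}, {}
    for d in chosen:
        total = int(counts[d])
        if total == 0:
            logger.info("descriptor %r has zero positives; excluded from composition", d)
            continue
        positive_ids = labels.data.index[labels.data[d] == 1]
        in_cluster = assignments.loc[positive_ids].value_counts()
        rows[d] = {f"cluster{c}": 100.0 * float(in_cluster.get(c, 0)) / total
                   for c in clusters}
        totals[d] = total
    percentages = pd.DataFrame(rows).T
    percentages.index.name = "descriptor"
    return CompositionResult(
        assignments=assignments,
        percentages=percentages,
        totals=pd.Series(totals, name="total_positives"),
    )
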
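"""Odor-descriptor grouping via word-embedding similarity.

Descriptors like "raspberry" and "blueberry" are semantically close; instead
of predicting each of ~93 rare labels, the vocabulary is clustered into a
few groups by agglomerative clustering on cosine distances between the
descriptors' word vectors, and a molecule is group-positive when it carries
any member descriptor.  Group predictors are then evaluated in ROC space
(true-positive rate vs false-positive rate) alongside F1.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import DescriptorMatrix, FeatureTable
from .predict import BinarySVMSpec, EvaluationResult, OCSVMSpec, evaluate_repeated_cv

logger = logging.getLogger(__name__)

_TOKEN_SPLIT = re.compile(r"[\s\-_/]+")


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u.v / (|u||v|); zero vectors are rejected."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal dimension")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def embed_descriptor(word: str, vectors: Mapping[str, np.ndarray]) -> np.ndarray:
    """Vector for one descriptor; multi-word terms average their token vectors."""
    tokens = [t for t in _TOKEN_SPLIT.split(word.strip().lower()) if t]
    if not tokens:
        raise KeyError(f"empty descriptor {word!r}")
    missing = [t for t in tokens if t not in vectors]
    if missing:
        raise KeyError(f"descriptor {word!r}: token(s) {missing} not in the embedding")
    if len(tokens) > 1:
        logger.info("descriptor %r embedded as the mean of %d token vectors", word, len(tokens))
    return np.mean([np.asarray(vectors[t], dtype=float) for t in tokens], axis=0)


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise cosine similarities over the descriptor vocabulary."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        m = self.data.to_numpy()
        if m.shape[0] != m.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-9):
            raise ValueError("similarity diagonal must be 1")
        if m.size and (m.min() < -1 - 1e-9 or m.max() > 1 + 1e-9):
            raise ValueError("similarities must lie in [-1, 1]")

    @property
    def vocabulary(self) -> list[str]:
        return [str(c) for c in self.data.columns]


def similarity_matrix(
    vocabulary: Sequence[str], vectors: Mapping[str, np.ndarray]
) -> SimilarityMatrix:
    """Pairwise cosine similarities for a descriptor vocabulary."""
    embedded = np.stack([embed_descriptor(w, vectors) for w in vocabulary])
    norms = np.linalg.norm(embedded, axis=1, keepdims=True)
    if (norms == 0).any():
        raise ValueError("zero embedding vector in vocabulary")
    unit = embedded / norms
    sim = np.clip(unit @ unit.T, -1.0, 1.0)
    sim = (sim + sim.T) / 2.0
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(pd.DataFrame(sim, index=list(vocabulary), columns=list(vocabulary)))


@dataclass
class DescriptorGrouping:
    """Partition of the vocabulary into 1..n_clusters groups.

    Group indices are assigned in decreasing order of member count, so the
    naming is stable across runs regardless of dendrogram traversal order.
    """

    assignments: dict[str, int]
    n_clusters: int

    def __post_init__(self) -> None:
        values = set(self.assignments.values())
        if values != set(range(1, self.n_clusters + 1)):
            raise ValueError("every cluster in [1, n_clusters] must be non-empty")

    def members(self, cluster: int) -> list[str]:
        return [w for w, c in self.assignments.items() if c == cluster]

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.assignments.values():
            out[c] = out.get(c, 0) + 1
        return out


def cluster_descriptors(
    sim: SimilarityMatrix, n_clusters: int, method: str = "average"
) -> DescriptorGrouping:
    """Cut the agglomerative tree on distance 1 - similarity at ``n_clusters``.

    Average linkage by default; the linkage method is config-exposed because
    the choice changes the partition for weakly separated vocabularies.
    """
    vocab = sim.vocabulary
    if not 1 <= n_clusters <= len(vocab):
        raise ValueError(f"n_clusters must be in [1, {len(vocab)}]")
    dist = 1.0 - sim.data.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    condensed = squareform(dist, checks=False)
    raw = fcluster(linkage(condensed, method=method), t=n_clusters, criterion="maxclust")
    # relabel by decreasing member count (ties: first appearance)
    order: dict[int, int] = {}
    counts = pd.Series(raw).value_counts()
    first_seen = {int(lab): i for i, lab in enumerate(raw) if int(lab) not in order}
    ranked = sorted(counts.index, key=lambda lab: (-counts[lab], first_seen[int(lab)]))
    relabel = {int(lab): i + 1 for i, lab in enumerate(ranked)}
    return DescriptorGrouping(
        assignments={w: relabel[int(lab)] for w, lab in zip(vocab, raw)},
        n_clusters=len(relabel),
    )


def build_group_targets(labels: DescriptorMatrix, grouping: DescriptorGrouping) -> DescriptorMatrix:
    """Group-level targets: a sample is positive for a group when it carries
    any member descriptor (logical OR)."""
    missing = [w for w in labels.vocabulary if w not in grouping.assignments]
    if missing:
        raise ValueError(f"descriptor(s) missing from grouping: {missing}")
    out = {}
    for c in range(1, grouping.n_clusters + 1):
        members = [w for w in grouping.members(c) if w in labels.data.columns]
        col = labels.data[members].any(axis=1).astype(int) if members else 0
        out[f"group{c}"] = col
    return DescriptorMatrix(pd.DataFrame(out, index=labels.data.index))


@dataclass
class GroupEvaluation:
    """Per-group TPR/FPR/F1 over repeated CV, with fold values retained."""

    rates: pd.DataFrame               # index group, columns tpr/fpr/mean_f1
    detail: EvaluationResult
    excluded: list[str]

    def to_frame(self) -> pd.DataFrame:
        return self.rates.reset_index(names="group")


def evaluate_groups(
    features: FeatureTable | np.ndarray,
    group_targets: DescriptorMatrix,
    model_kind: str = "binary_svm",
    spec: OCSVMSpec | BinarySVMSpec | None = None,
    k: int = 10,
    repeats: int = 3,
    seed: int = 0,
) -> GroupEvaluation:
    """Evaluate group predictors; report ROC-space rates plus F1.

    A group positive for every sample has no negatives to measure an FPR on
    and is excluded (logged); zero-positive groups are excluded by the
    underlying harness.
    """
    all_positive = [g for g in group_targets.vocabulary
                    if group_targets.data[g].all()]
    for g in all_positive:
        logger.info("group %r is positive for every sample; excluded", g)
    kept = DescriptorMatrix(group_targets.data.drop(columns=all_positive))
    detail = evaluate_repeated_cv(features, kept, model_kind, spec,
                                  k=k, repeats=repeats, seed=seed)
    rows = {}
    for g in detail.labels:
        counts = np.array(detail.fold_counts[g], dtype=float)  # tp fp fn tn
        tp, fp, fn, tn = counts.sum(axis=0)
        rows[g] = {
            "tpr": tp / (tp + fn) if tp + fn > 0 else 0.0,
            "fpr": fp / (fp + tn) if fp + tn > 0 else 0.0,
            "mean_f1": detail.mean_f1(g),
        }
    rates = pd.DataFrame(rows).T
    rates.index.name = "group"
    return GroupEvaluation(rates=rates, detail=detail,
                           excluded=all_positive + detail.excluded)
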
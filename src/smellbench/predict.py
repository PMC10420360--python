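"""Per-descriptor predictors and the repeated cross-validation harness.

Odor-descriptor prediction is a long-tailed multilabel problem: most
descriptors have only a handful of positive molecules, so each descriptor
gets its own classifier and the headline metric is the F1 score averaged
over validation folds.  Two model families are supported:

* a binary SVM trained on both classes, and
* a one-class SVM (the imbalance-robust choice) trained on the majority
  class only — the molecules *without* the descriptor.  A validation point
  the frontier scores out-of-class (decision score < 0) is predicted
  descriptor-present.

The one-class objective's nu parameter upper-bounds the fraction of
training points left outside the frontier and lower-bounds the fraction of
support vectors (the "nu-property"), which the test suite asserts.

Folds are stratified: with fewer positives than folds, plain k-fold CV
routinely yields positive-free validation folds and undefined F1.  The
splitter deals shuffled positives and negatives round-robin into k folds, so
it stays valid for descriptors with any positive count (scikit-learn's
stratified splitter rejects classes smaller than k).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC, OneClassSVM

from .datatypes import DescriptorMatrix, FeatureTable

logger = logging.getLogger(__name__)


# -- metrics -----------------------------------------------------------------

def f1_and_recall(tp: int, fp: int, fn: int) -> tuple[float, float]:
    """F1 and recall from confusion counts; any 0/0 yields 0.

    precision = tp/(tp+fp), recall = tp/(tp+fn), F1 = 2PR/(P+R).
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("confusion counts must be >= 0")
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return f1, recall


# -- model specs -------------------------------------------------------------

@dataclass(frozen=True)
class OCSVMSpec:
    """One-class SVM hyperparameters; nu in (0, 1]."""

    nu: float = 0.1
    kernel: str = "rbf"
    gamma: float | str = "scale"

    def __post_init__(self) -> None:
        if not 0 < self.nu <= 1:
            raise ValueError("nu must be in (0, 1]")
        if self.kernel not in ("rbf", "linear"):
            raise ValueError("kernel must be 'rbf' or 'linear'")
        if isinstance(self.gamma, (int, float)) and self.gamma <= 0:
            raise ValueError("numeric gamma must be positive")


@dataclass(frozen=True)
class BinarySVMSpec:
    """Binary SVM hyperparameters (C-parameterized)."""

    C: float = 1.0
    kernel: str = "rbf"
    gamma: float | str = "scale"

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")


#: default search grids (spanning the standard operating range of each model)
DEFAULT_OCSVM_GRID: tuple[OCSVMSpec, ...] = tuple(
    OCSVMSpec(nu=nu, kernel="rbf", gamma=g)
    for nu in (0.01, 0.05, 0.1, 0.2, 0.3, 0.5)
    for g in ("scale", 0.01, 0.1, 1.0)
)
DEFAULT_BINARY_GRID: tuple[BinarySVMSpec, ...] = tuple(
    BinarySVMSpec(C=c, kernel="rbf", gamma="scale") for c in (0.1, 1.0, 10.0, 100.0)
)


# -- one-class model ---------------------------------------------------------

@dataclass
class OCSVMModel:
    """A fitted one-class frontier around the descriptor-absent class."""

    estimator: OneClassSVM
    n_features: int
    n_training: int

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {X.shape[1]}")
        return self.estimator.decision_function(X)

    @property
    def support_fraction(self) -> float:
        return len(self.estimator.support_) / self.n_training

    def training_outlier_fraction(self, X_train: np.ndarray) -> float:
        return float(np.mean(self.decision_scores(X_train) < 0))


def train_one_class(X_majority: np.ndarray, spec: OCSVMSpec = OCSVMSpec()) -> OCSVMModel:
    """Fit the one-class SVM on descriptor-absent rows only."""
    X = np.asarray(X_majority, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 training rows")
    est = OneClassSVM(nu=spec.nu, kernel=spec.kernel, gamma=spec.gamma)
    est.fit(X)
    return OCSVMModel(estimator=est, n_features=X.shape[1], n_training=X.shape[0])


def predict_descriptor(model: OCSVMModel, X: np.ndarray) -> np.ndarray:
    """Map decision scores to labels: out-of-class (score < 0) = present (1)."""
    return (model.decision_scores(X) < 0).astype(int)


# -- cross-validation --------------------------------------------------------

def repeated_stratified_folds(
    y: np.ndarray, k: int, repeats: int, seed: int
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield (train_idx, val_idx) for repeated stratified k-fold CV.

    Positives and negatives are shuffled independently and dealt round-robin,
    so every fold's class balance is as even as integer counts allow.
    Deterministic in ``seed``; repeats use fresh shuffles.
    """
    y = np.asarray(y, dtype=int)
    n = len(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of rows ({n})")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    for _ in range(repeats):
        fold_of = np.empty(n, dtype=int)
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            offset = int(rng.integers(k))
            fold_of[idx] = (np.arange(len(idx)) + offset) % k
        for f in range(k):
            val = np.flatnonzero(fold_of == f)
            train = np.flatnonzero(fold_of != f)
            yield train, val


@dataclass
class EvaluationResult:
    """Fold-level and mean F1/recall per target label.

    ``fold_f1``/``fold_recall`` hold one value per fold (k x repeats of
    them); ``fold_counts`` the (tp, fp, fn, tn) tuples they derive from.
    """

    fold_f1: dict[str, np.ndarray]
    fold_recall: dict[str, np.ndarray]
    fold_counts: dict[str, list[tuple[int, int, int, int]]]
    k: int
    repeats: int
    seed: int
    model_kind: str
    excluded: list[str] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return list(self.fold_f1)

    def mean_f1(self, label: str) -> float:
        return float(np.mean(self.fold_f1[label]))

    def mean_recall(self, label: str) -> float:
        return float(np.mean(self.fold_recall[label]))

    def mean_f1_vector(self) -> pd.Series:
        return pd.Series({lab: self.mean_f1(lab) for lab in self.labels})

    def macro_mean_f1(self) -> float:
        return float(self.mean_f1_vector().mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "mean_f1": [self.mean_f1(l) for l in self.labels],
                "mean_recall": [self.mean_recall(l) for l in self.labels],
                "n_folds": [len(self.fold_f1[l]) for l in self.labels],
            }
        )


def _fit_predict_fold(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    model_kind: str,
    spec: OCSVMSpec | BinarySVMSpec,
) -> np.ndarray:
    if model_kind == "ocsvm":
        majority = X_train[y_train == 0]
        model = train_one_class(majority, spec)  # type: ignore[arg-type]
        return predict_descriptor(model, X_val)
    if model_kind == "binary_svm":
        if len(np.unique(y_train)) < 2:
            return np.full(len(X_val), int(y_train[0]))
        est = SVC(C=spec.C, kernel=spec.kernel, gamma=spec.gamma)  # type: ignore[union-attr]
        est.fit(X_train, y_train)
        return est.predict(X_val).astype(int)
    raise ValueError(f"unknown model kind {model_kind!r}")


def evaluate_repeated_cv(
    features: FeatureTable | np.ndarray,
    labels: DescriptorMatrix,
    model_kind: str = "ocsvm",
    spec: OCSVMSpec | BinarySVMSpec | None = None,
    k: int = 10,
    repeats: int = 3,
    seed: int = 0,
) -> EvaluationResult:
    """Repeated stratified k-fold evaluation, one classifier per descriptor.

    Descriptors with zero positives are excluded (logged).  One-class models
    are fit on the training fold's majority (descriptor-absent) rows only;
    metrics come from validation-fold confusion counts, with the 0/0 -> 0
    convention so rare-positive folds stay defined.
    """
    X = features.values if isinstance(features, FeatureTable) else np.asarray(features, float)
    if isinstance(features, FeatureTable) and features.ids != labels.ids:
        raise ValueError("features and labels are not row-aligned")
    if X.shape[0] != len(labels.data):
        raise ValueError("features and labels disagree on row count")
    if spec is None:
        spec = OCSVMSpec() if model_kind == "ocsvm" else BinarySVMSpec()
    fold_f1: dict[str, np.ndarray] = {}
    fold_recall: dict[str, np.ndarray] = {}
    fold_counts: dict[str, list[tuple[int, int, int, int]]] = {}
    excluded: list[str] = []
    Y = labels.values
    for j, descriptor in enumerate(labels.vocabulary):
        y = Y[:, j]
        if y.sum() == 0:
            logger.info("descriptor %r has no positives; excluded", descriptor)
            excluded.append(descriptor)
            continue
        f1s, recalls, counts = [], [], []
        for train, val in repeated_stratified_folds(y, k, repeats, seed):
            pred = _fit_predict_fold(X[train], y[train], X[val], model_kind, spec)
            truth = y[val]
            tp = int(np.sum((pred == 1) & (truth == 1)))
            fp = int(np.sum((pred == 1) & (truth == 0)))
            fn = int(np.sum((pred == 0) & (truth == 1)))
            tn = int(np.sum((pred == 0) & (truth == 0)))
            f1, rec = f1_and_recall(tp, fp, fn)
            f1s.append(f1)
            recalls.append(rec)
            counts.append((tp, fp, fn, tn))
        fold_f1[descriptor] = np.array(f1s)
        fold_recall[descriptor] = np.array(recalls)
        fold_counts[descriptor] = counts
    return EvaluationResult(fold_f1, fold_recall, fold_counts,
                            k=k, repeats=repeats, seed=seed,
                            model_kind=model_kind, excluded=excluded)


# -- hyperparameter search ---------------------------------------------------

def _spec_sort_key(spec: OCSVMSpec | BinarySVMSpec) -> tuple[float, float]:
    """Tie-break order: smaller nu (or C), then smaller gamma.

    The scale heuristic is ordered after every numeric gamma (its effective
    value is data-dependent, so explicit gammas win ties).
    """
    primary = spec.nu if isinstance(spec, OCSVMSpec) else spec.C
    gamma = spec.gamma if isinstance(spec.gamma, (int, float)) else math.inf
    return (primary, gamma)


def search_hyperparameters(
    features: FeatureTable | np.ndarray,
    labels: DescriptorMatrix,
    grid: Sequence[OCSVMSpec | BinarySVMSpec],
    k: int = 10,
    repeats: int = 3,
    seed: int = 0,
) -> dict[str, OCSVMSpec | BinarySVMSpec]:
    """Best grid point per descriptor by mean validation F1.

    Ties go to the smaller nu (or C), then the smaller gamma.
    """
    if not grid:
        raise ValueError("hyperparameter grid must be non-empty")
    kinds = {("ocsvm" if isinstance(s, OCSVMSpec) else "binary_svm") for s in grid}
    if len(kinds) != 1:
        raise ValueError("grid mixes model kinds")
    (model_kind,) = kinds
    results = {
        spec: evaluate_repeated_cv(features, labels, model_kind, spec,
                                   k=k, repeats=repeats, seed=seed)
        for spec in grid
    }
    best: dict[str, OCSVMSpec | BinarySVMSpec] = {}
    any_result = next(iter(results.values()))
    for descriptor in any_result.labels:
        scored = [(-(res.mean_f1(descriptor)), *_spec_sort_key(spec), i, spec)
                  for i, (spec, res) in enumerate(results.items())]
        scored.sort(key=lambda t: t[:-2])
        best[descriptor] = scored[0][-1]
    return best


# -- feature-set comparison --------------------------------------------------

@dataclass
class ComparisonResult:
    """Paired t-test between two featurizations' per-descriptor mean F1."""

    t_statistic: float
    p_value: float
    n_pairs: int
    mean_difference: float
    exactly_equal: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "n_pairs": self.n_pairs,
            "mean_difference": self.mean_difference,
            "exactly_equal": self.exactly_equal,
        }])


def compare_feature_sets(result_a: EvaluationResult, result_b: EvaluationResult) -> ComparisonResult:
    """Two-sided paired t-test on per-descriptor mean F1 differences.

    t = mean(d) / (sd(d) / sqrt(n)) with n-1 degrees of freedom, d paired by
    descriptor.  Identical results are flagged ``exactly_equal`` rather than
    producing a NaN statistic.
    """
    if result_a.labels != result_b.labels:
        raise ValueError("results cover different (or differently ordered) descriptor sets")
    d = result_a.mean_f1_vector().to_numpy() - result_b.mean_f1_vector().to_numpy()
    n = len(d)
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    sd = float(np.std(d, ddof=1))
    mean = float(np.mean(d))
    if sd == 0.0:
        if mean == 0.0:
            return ComparisonResult(0.0, 1.0, n, 0.0, exactly_equal=True)
        t = math.copysign(math.inf, mean)
        return ComparisonResult(t, 0.0, n, mean)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return ComparisonResult(t, p, n, mean)
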
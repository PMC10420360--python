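"""End-to-end study workflows built from the pipeline stages.

These functions bind generator -> featurization -> preprocessing ->
evaluation into the experiments the analysis drivers and the acceptance
checks run: the signal-recovery study on a ground-truthed synthetic cohort
(with a label-permutation null), and the reproduction of deterministic
counts and reduced dimensions from the study's supplementary workbook when
a local copy is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import io_core
from .datatypes import DescriptorMatrix, FeatureTable
from .predict import OCSVMSpec, EvaluationResult, evaluate_repeated_cv
from .preprocess import preprocess_table
from .synthetic import default_cohort_truth, generate_cohort


@dataclass
class SignalRecoveryResult:
    """Macro mean F1 per signal level against a label-permutation null."""

    macro_f1: dict[float, float]
    per_descriptor_f1: dict[float, pd.Series]
    null_macro_f1: dict[float, np.ndarray]           # one value per permutation
    null_per_descriptor_f1: dict[float, pd.Series]   # mean over permutations
    t_statistic: float = math.nan                    # highest signal vs its null
    p_value_one_sided: float = math.nan
    n_descriptors: int = 0

    def null_mean(self, signal: float) -> float:
        return float(np.mean(self.null_macro_f1[signal]))

    def null_sd(self, signal: float) -> float:
        return float(np.std(self.null_macro_f1[signal], ddof=1))

    def z_score(self, signal: float) -> float:
        """Distance of the observed macro F1 from the permutation null, in null sd."""
        return (self.macro_f1[signal] - self.null_mean(signal)) / self.null_sd(signal)


def _permute_labels(labels: DescriptorMatrix, rng: np.random.Generator) -> DescriptorMatrix:
    perm = rng.permutation(len(labels.data))
    permuted = labels.data.iloc[perm].copy()
    permuted.index = labels.data.index
    return DescriptorMatrix(permuted)


def signal_recovery_experiment(
    n_molecules: int = 200,
    n_descriptors: int = 40,
    signals: Sequence[float] = (0.0, 3.0),
    n_permutations: int = 6,
    modality: str = "enose",
    spec: OCSVMSpec = OCSVMSpec(nu=0.2),
    cutoff: float = 0.95,
    k: int = 10,
    repeats: int = 3,
    seed: int = 0,
) -> SignalRecoveryResult:
    """Evaluate one-class descriptor prediction across planted signal levels.

    For each signal strength a fresh cohort is drawn with the same seed (so
    cohorts differ only through the label-generating signal), features are
    min-max scaled and PCA-reduced, and per-descriptor one-class SVMs are
    scored by repeated stratified CV.  The chance reference re-runs the
    identical evaluation on row-permuted labels ``n_permutations`` times.

    The returned paired statistic compares the highest signal level's
    per-descriptor mean F1 with its permutation-null counterpart (one-sided:
    signal exceeds chance).
    """
    vocabulary = [f"odor{i:02d}" for i in range(n_descriptors)]
    macro: dict[float, float] = {}
    per_desc: dict[float, pd.Series] = {}
    null_macro: dict[float, np.ndarray] = {}
    null_per_desc: dict[float, pd.Series] = {}
    for s in signals:
        truth = default_cohort_truth(vocabulary, signal_strength=s, seed=seed)
        tables, labels = generate_cohort(n_molecules, vocabulary, truth, seed=seed)
        scores, _, _ = preprocess_table(tables[modality], cutoff=cutoff)
        result = evaluate_repeated_cv(scores, labels, "ocsvm", spec,
                                      k=k, repeats=repeats, seed=seed)
        macro[s] = result.macro_mean_f1()
        per_desc[s] = result.mean_f1_vector()
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 211]))
        nulls, null_vectors = [], []
        for _ in range(n_permutations):
            permuted = _permute_labels(labels, rng)
            null_result = evaluate_repeated_cv(scores, permuted, "ocsvm", spec,
                                               k=k, repeats=repeats, seed=seed)
            nulls.append(null_result.macro_mean_f1())
            null_vectors.append(null_result.mean_f1_vector())
        null_macro[s] = np.array(nulls)
        null_per_desc[s] = pd.concat(null_vectors, axis=1).mean(axis=1)

    top = max(signals)
    shared = per_desc[top].index.intersection(null_per_desc[top].index)
    d = per_desc[top].loc[shared].to_numpy() - null_per_desc[top].loc[shared].to_numpy()
    t, p_two = stats.ttest_rel(per_desc[top].loc[shared], null_per_desc[top].loc[shared])
    p_one = p_two / 2 if t > 0 else 1 - p_two / 2
    return SignalRecoveryResult(
        macro_f1=macro,
        per_descriptor_f1=per_desc,
        null_macro_f1=null_macro,
        null_per_descriptor_f1=null_per_desc,
        t_statistic=float(t),
        p_value_one_sided=float(p_one),
        n_descriptors=len(shared),
    )


# -- supplementary-data reproduction ----------------------------------------

#: deterministic quantities the study reports for its measured cohort
STUDY_EXPECTATIONS = {
    "n_molecules": 114,
    "n_descriptors": 93,
    "top_descriptor_counts": {"sweet": 55, "floral": 52},
    "enose_original_dimension": 35,
    "enose_reduced_dimension": 5,
}


@dataclass
class SupplementaryReproduction:
    """Counts and reduced dimensions recomputed from a local S1 workbook."""

    n_molecules: int
    n_descriptors: int
    top_descriptor_counts: dict[str, int]
    enose_original_dimension: int | None = None
    enose_reduced_dimension: int | None = None

    def as_dict(self) -> dict[str, object]:
        return {
            "n_molecules": self.n_molecules,
            "n_descriptors": self.n_descriptors,
            "top_descriptor_counts": self.top_descriptor_counts,
            "enose_original_dimension": self.enose_original_dimension,
            "enose_reduced_dimension": self.enose_reduced_dimension,
        }


def reproduce_supplementary(workbook_path: str | Path, cutoff: float = 0.95,
                            top_n: int = 2) -> SupplementaryReproduction:
    """Recompute the study's deterministic cohort numbers from S1 data.

    Needs a locally downloaded copy of the supplementary workbook (it is not
    redistributable with this package).  Returns the molecule and
    descriptor-vocabulary counts, the positive counts of the most frequent
    descriptors, and the e-nose table's PCA dimension at ``cutoff``.
    """
    workbook_path = Path(workbook_path)
    if not workbook_path.exists():
        raise FileNotFoundError(
            f"supplementary workbook not found at {workbook_path}; download "
            "pone.0289881.s001 and place it there (see README)")
    records, smell = io_core.convert_s1_workbook(workbook_path)
    labels = DescriptorMatrix.from_records(records)
    counts = labels.positives().sort_values(ascending=False)
    result = SupplementaryReproduction(
        n_molecules=len(records),
        n_descriptors=len(labels.vocabulary),
        top_descriptor_counts={str(d): int(counts[d]) for d in counts.index[:top_n]},
    )
    if smell is not None:
        _, _, reduction = preprocess_table(smell, cutoff=cutoff)
        result.enose_original_dimension = smell.n_features
        result.enose_reduced_dimension = reduction.n_components
    return result
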
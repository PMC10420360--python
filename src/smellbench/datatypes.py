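"""Shared domain containers for the featurization benchmark.

The pipeline moves five kinds of objects between stages: raw sensor traces,
annotated molecule records, named feature tables (one per featurization),
the binary molecule x descriptor label matrix, and the run configuration
that pins fold counts, variance cutoffs and seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: provenance tags a FeatureTable may carry
PROVENANCE_TAGS = ("enose", "bfp", "cfp", "descriptors", "spectrum", "synthetic")


@dataclass(frozen=True)
class MoleculeRecord:
    """One odorant: identifier, CAS registry number, SMILES and its odor words.

    Descriptor strings are stored lower-cased and whitespace-trimmed; the
    vocabulary is treated case-insensitively throughout.
    """

    id: str
    cas: str
    smiles: str
    descriptors: frozenset[str]

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("molecule id must be non-empty")
        for d in self.descriptors:
            if not d or d != d.strip().lower():
                raise ValueError(
                    f"descriptor {d!r} of molecule {self.id!r} is not normalized "
                    "(non-empty, trimmed, lower-case)"
                )


@dataclass
class SensorTrace:
    """One QCM measurement: channels x timepoints resonance-frequency readings.

    Parameters
    ----------
    readings
        Array of shape (n_channels, n_timepoints) in Hz.
    sampling_interval
        Seconds between consecutive readings (the device records at 10 Hz).
    shutter_open_index
        Index of the first reading taken with the shutter open; readings
        before it form the pre-exposure baseline window.
    """

    readings: np.ndarray
    sampling_interval: float = 0.1
    shutter_open_index: int = 1

    def __post_init__(self) -> None:
        self.readings = np.asarray(self.readings, dtype=float)
        if self.readings.ndim != 2:
            raise ValueError("readings must be a 2-D channels x timepoints array")
        if self.readings.shape[1] < 2:
            raise ValueError("trace needs at least 2 timepoints")
        if not np.isfinite(self.readings).all():
            raise ValueError("trace contains non-finite readings")
        if not 1 <= self.shutter_open_index <= self.readings.shape[1] - 1:
            raise ValueError(
                f"shutter_open_index={self.shutter_open_index} outside "
                f"[1, {self.readings.shape[1] - 1}]"
            )
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")

    @property
    def n_channels(self) -> int:
        return self.readings.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.readings.shape[1]


@dataclass
class FeatureTable:
    """A named featurization: molecules x numeric features.

    ``data`` is indexed by molecule id; ``provenance`` names the featurization
    (one of :data:`PROVENANCE_TAGS`).
    """

    data: pd.DataFrame
    provenance: str

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate molecule ids in feature table")
        arr = self.data.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ValueError("feature table must be all-numeric")

    @property
    def ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class DescriptorMatrix:
    """Molecules x descriptors binary label matrix."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("label matrix entries must be 0/1")
        self.data = self.data.astype(int)

    @classmethod
    def from_records(
        cls, molecules: Sequence[MoleculeRecord], vocabulary: Sequence[str] | None = None
    ) -> "DescriptorMatrix":
        """Build the binary matrix from molecule annotations.

        The vocabulary defaults to the sorted union of all descriptors seen.
        """
        if vocabulary is None:
            vocabulary = sorted(set().union(*(m.descriptors for m in molecules)) if molecules else set())
        rows = [
            [1 if d in m.descriptors else 0 for d in vocabulary] for m in molecules
        ]
        df = pd.DataFrame(rows, index=[m.id for m in molecules], columns=list(vocabulary))
        return cls(df)

    @property
    def vocabulary(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=int)

    def positives(self) -> pd.Series:
        """Positive-sample count per descriptor."""
        return self.data.sum(axis=0)


@dataclass
class DatasetBundle:
    """Everything loaded for one cohort.

    Invariants: molecule ids unique; every trace/spectrum key refers to a
    listed molecule.
    """

    molecules: list[MoleculeRecord]
    traces: Mapping[str, list[SensorTrace]] | None = None
    smell_vectors: FeatureTable | None = None
    spectra: Mapping[str, list[tuple[int, float]]] | None = None

    def __post_init__(self) -> None:
        ids = [m.id for m in self.molecules]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate molecule ids: {dupes}")
        known = set(ids)
        for name, mapping in (("trace", self.traces), ("spectrum", self.spectra)):
            if mapping is not None:
                unknown = sorted(set(mapping) - known)
                if unknown:
                    raise ValueError(f"{name} keys not in molecule table: {unknown}")

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.molecules]


@dataclass
class RunConfig:
    """Run-level knobs shared across stages, with the study's defaults."""

    variance_cutoff: float = 0.95
    k_folds: int = 10
    n_repeats: int = 3
    model_kind: str = "ocsvm"
    n_label_clusters: int = 6
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.variance_cutoff <= 1:
            raise ValueError("variance_cutoff must be in (0, 1]")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.model_kind not in ("binary_svm", "ocsvm"):
            raise ValueError("model_kind must be 'binary_svm' or 'ocsvm'")
        if self.n_label_clusters < 1:
            raise ValueError("n_label_clusters must be >= 1")
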
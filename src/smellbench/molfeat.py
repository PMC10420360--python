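"""Structure- and spectrum-based featurizations.

Three feature families complement the e-nose smell vectors: Morgan circular
fingerprints (bit presence or substructure counts, radius 3 / 1024 bits by
default — radius 3 corresponds to the "diameter 6" naming of ECFP6), numeric
molecular-descriptor tables, and a mass-spectrum matrix built on the sorted
union of observed integer m/z values (EI stick spectra are unit-resolution).

The cheminformatics backends are pluggable: any callable with the documented
signature can stand in, and the default backends import RDKit lazily so the
rest of the package works without a chemistry stack installed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import FeatureTable, MoleculeRecord

logger = logging.getLogger(__name__)


class CapabilityError(RuntimeError):
    """A required optional backend is not installed."""


@dataclass(frozen=True)
class FingerprintSpec:
    """Morgan fingerprint parameters (radius 3, 1024 bits by default)."""

    radius: int = 3
    n_bits: int = 1024
    kind: str = "bit"

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.n_bits < 1 or (self.n_bits & (self.n_bits - 1)) != 0:
            raise ValueError("n_bits must be a power of two")
        if self.kind not in ("bit", "count"):
            raise ValueError("kind must be 'bit' or 'count'")

    @property
    def provenance(self) -> str:
        return "bfp" if self.kind == "bit" else "cfp"


#: a fingerprint backend maps (smiles, spec) -> integer vector of length n_bits,
#: or None when the SMILES cannot be parsed
FingerprintBackend = Callable[[str, FingerprintSpec], "np.ndarray | None"]

#: a descriptor backend maps a SMILES list -> DataFrame (rows aligned to input),
#: with None rows/NaN where parsing fails
DescriptorBackend = Callable[[Sequence[str]], pd.DataFrame]


def rdkit_fingerprint_backend(smiles: str, spec: FingerprintSpec) -> np.ndarray | None:
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise CapabilityError("RDKit is required for the default fingerprint backend") from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=spec.radius, fpSize=spec.n_bits)
    if spec.kind == "bit":
        fp = gen.GetFingerprint(mol)
        arr = np.zeros(spec.n_bits, dtype=int)
        for bit in fp.GetOnBits():
            arr[bit] = 1
        return arr
    fp = gen.GetCountFingerprint(mol)
    arr = np.zeros(spec.n_bits, dtype=int)
    for bit, count in fp.GetNonzeroElements().items():
        arr[bit] = count
    return arr


def rdkit_descriptor_backend(smiles_list: Sequence[str]) -> pd.DataFrame:
    """Numeric molecular descriptors from RDKit's full descriptor list."""
    try:
        from rdkit import Chem
        from rdkit.Chem import Descriptors
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise CapabilityError("RDKit is required for the default descriptor backend") from exc
    rows = []
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        rows.append(Descriptors.CalcMolDescriptors(mol) if mol is not None else {})
    return pd.DataFrame(rows)


def compute_fingerprints(
    molecules: Sequence[MoleculeRecord],
    spec: FingerprintSpec = FingerprintSpec(),
    backend: FingerprintBackend = rdkit_fingerprint_backend,
) -> FeatureTable:
    """Fingerprint every molecule; identical SMILES yield identical rows."""
    rows, bad = [], []
    for m in molecules:
        vec = backend(m.smiles, spec)
        if vec is None:
            bad.append(m.id)
            rows.append(np.zeros(spec.n_bits, dtype=int))
        else:
            rows.append(np.asarray(vec, dtype=int))
    if bad:
        raise ValueError(f"unparseable SMILES for molecule id(s): {bad}")
    df = pd.DataFrame(np.stack(rows), index=[m.id for m in molecules],
                      columns=[f"b{i}" for i in range(spec.n_bits)])
    return FeatureTable(df, provenance=spec.provenance)


def clean_descriptor_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Drop non-numeric and all-missing columns; log what was removed."""
    numeric = df.select_dtypes(include=[np.number])
    dropped_nonnum = sorted(set(df.columns) - set(numeric.columns))
    keep = numeric.dropna(axis=1, how="all")
    dropped_missing = sorted(set(numeric.columns) - set(keep.columns))
    if dropped_nonnum:
        logger.info("dropped %d non-numeric descriptor column(s): %s",
                    len(dropped_nonnum), dropped_nonnum[:10])
    if dropped_missing:
        logger.info("dropped %d all-missing descriptor column(s): %s",
                    len(dropped_missing), dropped_missing[:10])
    # remaining sporadic NaN (a descriptor undefined for one molecule) -> 0
    return keep.fillna(0.0)


def compute_descriptor_table(
    molecules: Sequence[MoleculeRecord],
    backend: DescriptorBackend = rdkit_descriptor_backend,
) -> FeatureTable:
    """All-numeric molecular-descriptor table from the pluggable backend."""
    raw = backend([m.smiles for m in molecules])
    if len(raw) != len(molecules):
        raise ValueError("descriptor backend returned a misaligned frame")
    cleaned = clean_descriptor_frame(raw)
    cleaned.index = [m.id for m in molecules]
    return FeatureTable(cleaned.astype(float), provenance="descriptors")


@dataclass
class SpectrumMatrixResult:
    """Spectrum feature table plus its sorted m/z axis."""

    table: FeatureTable
    mz_axis: list[int]

    def __post_init__(self) -> None:
        if self.table.n_features != len(self.mz_axis):
            raise ValueError("matrix width must equal the m/z axis length")


def build_spectrum_matrix(
    spectra: Mapping[str, Sequence[tuple[int, float]]],
    mz_range: tuple[int, int] | None = None,
) -> SpectrumMatrixResult:
    """Align spectra on a common m/z axis, zero-filling absent peaks.

    The axis is the sorted union of observed m/z; pass ``mz_range`` to force
    a fixed inclusive integer range instead.  Total intensity is conserved
    (every input peak lands in exactly one cell).
    """
    if not spectra:
        raise ValueError("no spectra given")
    for mol_id, peaks in spectra.items():
        for mz, intensity in peaks:
            if int(mz) != mz or mz <= 0:
                raise ValueError(f"molecule {mol_id}: m/z {mz!r} is not a positive integer")
            if intensity < 0:
                raise ValueError(f"molecule {mol_id}: negative intensity at m/z {mz}")
    if mz_range is None:
        axis = sorted({int(mz) for peaks in spectra.values() for mz, _ in peaks})
    else:
        lo, hi = mz_range
        axis = list(range(int(lo), int(hi) + 1))
    col = {mz: j for j, mz in enumerate(axis)}
    mat = np.zeros((len(spectra), len(axis)))
    ids = list(spectra)
    for i, mol_id in enumerate(ids):
        for mz, intensity in spectra[mol_id]:
            if int(mz) in col:
                mat[i, col[int(mz)]] += intensity
            elif mz_range is not None:
                raise ValueError(f"molecule {mol_id}: m/z {mz} outside fixed range {mz_range}")
    df = pd.DataFrame(mat, index=ids, columns=[f"mz{m}" for m in axis])
    return SpectrumMatrixResult(FeatureTable(df, provenance="spectrum"), axis)
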
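"""Readers and writers for every external format the pipeline touches.

Native formats are plain text: CSV molecule/label tables, CSV sensor traces
(channels as columns, one row per timepoint), word2vec-style text embeddings,
two-column (mz, intensity) CSV spectra, and CSV result tables with a JSON
sidecar carrying the resolved config and seed.  The study's spreadsheet
dialect is supported through :func:`convert_s1_workbook`, not as a native
format.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .datatypes import DescriptorMatrix, FeatureTable, MoleculeRecord, RunConfig, SensorTrace

logger = logging.getLogger(__name__)

DESCRIPTOR_SEPARATOR = ";"

# %.17g round-trips IEEE doubles exactly, keeping write/read bit-identical
_FLOAT_FMT = "%.17g"

_MOLECULE_COLUMNS = ("id", "cas", "smiles", "descriptors")


class FormatError(ValueError):
    """A file does not match the expected layout."""


def normalize_descriptor(raw: str) -> str:
    """Lower-case and trim one descriptor string."""
    return raw.strip().lower()


def parse_descriptor_field(field: str) -> frozenset[str]:
    """Split a delimiter-separated descriptor field into a normalized set."""
    if not isinstance(field, str) or not field.strip():
        return frozenset()
    parts = (normalize_descriptor(p) for p in field.split(DESCRIPTOR_SEPARATOR))
    return frozenset(p for p in parts if p)


def read_molecule_table(path: str | Path) -> list[MoleculeRecord]:
    """Read the molecule table (columns: id, cas, smiles, descriptors).

    Descriptor strings are split on ';', trimmed, lower-cased and
    de-duplicated per molecule, so reading an already-normalized table is a
    no-op on the content.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _MOLECULE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"molecule table {path} is missing column(s): {missing}")
    records = [
        MoleculeRecord(
            id=row["id"].strip(),
            cas=row["cas"].strip(),
            smiles=row["smiles"].strip(),
            descriptors=parse_descriptor_field(row["descriptors"]),
        )
        for _, row in df.iterrows()
    ]
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate molecule id(s) in {path}: {dupes}")
    return records


def write_molecule_table(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    rows = [
        {
            "id": r.id,
            "cas": r.cas,
            "smiles": r.smiles,
            "descriptors": DESCRIPTOR_SEPARATOR.join(sorted(r.descriptors)),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(_MOLECULE_COLUMNS)).to_csv(path, index=False)


def read_sensor_trace(
    path: str | Path,
    shutter_open_index: int,
    sampling_interval: float = 0.1,
    n_channels: int | None = 35,
) -> SensorTrace:
    """Read one trace CSV (channels as columns, one row per timepoint).

    ``n_channels`` asserts the expected channel count; pass ``None`` to accept
    any width (the module supports configurable dimensions).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or not np.isfinite(arr).all():
        bad = np.argwhere(~np.isfinite(df.apply(pd.to_numeric, errors="coerce").to_numpy()))
        where = f" at (row, column)={tuple(bad[0])}" if len(bad) else ""
        raise FormatError(f"non-numeric or missing cell in trace {path}{where}")
    if n_channels is not None and arr.shape[1] != n_channels:
        raise FormatError(
            f"trace {path} has {arr.shape[1]} channels, expected {n_channels}"
        )
    return SensorTrace(arr.T, sampling_interval=sampling_interval,
                       shutter_open_index=shutter_open_index)


def write_sensor_trace(trace: SensorTrace, path: str | Path) -> None:
    df = pd.DataFrame(trace.readings.T, columns=[f"ch{i}" for i in range(trace.n_channels)])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_embedding_table(path: str | Path) -> dict[str, np.ndarray]:
    """Read a word2vec-style text embedding: ``word v1 v2 ... vD`` per line.

    An optional ``<count> <dim>`` header line is consumed.  All vectors must
    share one dimension; a duplicate word keeps the last occurrence (logged).
    """
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if lineno == 1 and len(parts) == 2:
                try:
                    int(parts[0]), int(parts[1])
                    continue  # header "count dim"
                except ValueError:
                    pass
            word, values = parts[0], parts[1:]
            try:
                vec = np.array([float(v) for v in values], dtype=float)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric vector entry") from exc
            if dim is None:
                dim = len(vec)
                if dim == 0:
                    raise FormatError(f"{path}:{lineno}: empty vector")
            elif len(vec) != dim:
                raise FormatError(
                    f"{path}:{lineno}: vector length {len(vec)} != {dim} (ragged file)"
                )
            if word in vectors:
                logger.warning("duplicate word %r in %s; keeping last occurrence", word, path)
            vectors[word] = vec
    return vectors


def write_embedding_table(vectors: Mapping[str, np.ndarray], path: str | Path,
                          header: bool = True) -> None:
    items = list(vectors.items())
    with open(path, "w", encoding="utf-8") as fh:
        if header and items:
            fh.write(f"{len(items)} {len(items[0][1])}\n")
        for word, vec in items:
            fh.write(word + " " + " ".join(repr(float(v)) for v in vec) + "\n")


def read_spectrum(path: str | Path) -> list[tuple[int, float]]:
    """Read one two-column (mz, intensity) CSV spectrum."""
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("mz", "intensity"):
        if col not in df.columns:
            raise FormatError(f"spectrum {path} is missing column {col!r}")
    if (df["intensity"] < 0).any():
        raise ValueError(f"negative intensity in spectrum {path}")
    return [(int(mz), float(i)) for mz, i in zip(df["mz"], df["intensity"])]


def write_spectrum(peaks: Iterable[tuple[int, float]], path: str | Path) -> None:
    pd.DataFrame(peaks, columns=["mz", "intensity"]).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_feature_table(path: str | Path, provenance: str = "synthetic") -> FeatureTable:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    return FeatureTable(df, provenance=provenance)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    df = table.data.copy()
    df.index.name = "id"
    df.to_csv(path, float_format=_FLOAT_FMT)


def read_label_matrix(path: str | Path) -> DescriptorMatrix:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return DescriptorMatrix(df)


def write_label_matrix(labels: DescriptorMatrix, path: str | Path) -> None:
    df = labels.data.copy()
    df.index.name = "id"
    df.to_csv(path)


def write_results(
    result_table: pd.DataFrame,
    path: str | Path,
    config: RunConfig | None = None,
    extra: Mapping[str, object] | None = None,
) -> None:
    """Write a flat result table plus a ``.json`` sidecar with config and seed."""
    path = Path(path)
    result_table.to_csv(path, index=False, float_format=_FLOAT_FMT)
    sidecar: dict[str, object] = {}
    if config is not None:
        sidecar["config"] = dataclasses.asdict(config)
    if extra:
        sidecar.update(extra)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


# -- configuration -----------------------------------------------------------

def load_config(path: str | Path | None, **overrides: object) -> RunConfig:
    """Load the declarative YAML config; keyword overrides win over the file."""
    values: dict[str, object] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise FormatError(f"config {path} must be a mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(values) - known)
    if unknown:
        raise FormatError(f"unknown config key(s): {unknown}")
    cfg = RunConfig(**values)  # type: ignore[arg-type]
    logger.info("resolved config: %s", dataclasses.asdict(cfg))
    return cfg


# -- spreadsheet converter ---------------------------------------------------

def convert_s1_workbook(path: str | Path) -> tuple[list[MoleculeRecord], FeatureTable | None]:
    """Convert the study's spreadsheet dialect into native objects.

    The workbook layout is tolerant of naming variation: the converter looks
    for columns whose lower-cased header contains ``cas``, ``smiles``, and
    ``descriptor`` (or ``odor``); numeric columns beyond those are treated as
    the 35 averaged smell-vector channels when exactly 35 are present.
    Requires ``openpyxl``.
    """
    df = pd.read_excel(path)  # needs openpyxl
    cols = {str(c).strip().lower(): c for c in df.columns}

    def find(*needles: str) -> object | None:
        for low, orig in cols.items():
            if any(n in low for n in needles):
                return orig
        return None

    cas_col = find("cas")
    smiles_col = find("smiles")
    desc_col = find("descriptor", "odor")
    id_col = find("id", "index", "name", "molecule")
    if desc_col is None:
        raise FormatError(f"{path}: no odor-descriptor column found")
    numeric_cols = [
        c for c in df.columns
        if c not in {cas_col, smiles_col, desc_col, id_col}
        and pd.api.types.is_numeric_dtype(df[c])
    ]
    records = []
    for i, row in df.iterrows():
        rid = str(row[id_col]).strip() if id_col is not None else f"m{i}"
        records.append(MoleculeRecord(
            id=rid,
            cas=str(row[cas_col]).strip() if cas_col is not None else "",
            smiles=str(row[smiles_col]).strip() if smiles_col is not None else "",
            descriptors=parse_descriptor_field(
                re.sub(r"[,|]", DESCRIPTOR_SEPARATOR, str(row[desc_col]))
            ),
        ))
    smell: FeatureTable | None = None
    if len(numeric_cols) == 35:
        mat = df[numeric_cols].astype(float)
        mat.index = [r.id for r in records]
        smell = FeatureTable(mat, provenance="enose")
    return records, smell
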
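"""Smell-vector extraction from QCM sensor traces.

A quartz crystal microbalance channel's resonance frequency shifts when
odorant molecules adsorb onto its receptor membrane.  The featurization
summarizes each channel by the base-to-peak frequency difference: the mean
pre-exposure reading minus the reading that deviates most from it, taken in
absolute value so the sign convention of the recording never matters.  Each
of the 35 membranes is treated independently, replicate measurements are
averaged element-wise, and a cohort of traces becomes one molecules x
channels feature table.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import FeatureTable, SensorTrace


def extract_smell_vector(trace: SensorTrace, baseline_window: int | None = None) -> np.ndarray:
    """Per-channel |base - peak| frequency differences, in Hz.

    For each channel independently: ``base`` is the mean of the readings
    before ``shutter_open_index`` (optionally only the last
    ``baseline_window`` of them), ``peak`` is the reading with maximal
    absolute deviation from base over the whole trace, and the feature is
    ``|base - peak|``.  Adding a constant to a channel or flipping the sign
    of its deviations leaves/keeps the result unchanged.
    """
    if trace.shutter_open_index < 1:
        raise ValueError("trace has no pre-exposure window (shutter_open_index must be >= 1)")
    pre = trace.readings[:, : trace.shutter_open_index]
    if baseline_window is not None:
        if baseline_window < 1:
            raise ValueError("baseline_window must be >= 1")
        pre = pre[:, -baseline_window:]
    base = pre.mean(axis=1)
    deviations = trace.readings - base[:, None]
    return np.abs(deviations).max(axis=1)


def average_replicates(vectors: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise arithmetic mean of replicate smell vectors."""
    if len(vectors) == 0:
        raise ValueError("need at least one smell vector")
    lengths = {len(v) for v in vectors}
    if len(lengths) != 1:
        raise ValueError(f"mismatched smell-vector lengths: {sorted(lengths)}")
    return np.mean(np.stack([np.asarray(v, dtype=float) for v in vectors]), axis=0)


def featurize_cohort(
    traces: Mapping[str, Sequence[SensorTrace]],
    baseline_window: int | None = None,
) -> FeatureTable:
    """Average smell vector per molecule, one row per id in input order."""
    if not traces:
        raise ValueError("no traces given")
    channel_counts = {reps[0].n_channels for reps in traces.values()}
    if len(channel_counts) != 1:
        raise ValueError(f"traces disagree on channel count: {sorted(channel_counts)}")
    (n_channels,) = channel_counts
    rows = {
        mol_id: average_replicates(
            [extract_smell_vector(t, baseline_window=baseline_window) for t in reps]
        )
        for mol_id, reps in traces.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[f"ch{i}" for i in range(n_channels)])
    return FeatureTable(df, provenance="enose")
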
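"""Synthetic sensor traces, multimodal cohorts, embeddings and spectra.

Every generator plants a known ground truth so downstream stages can be
tested without any measured data: traces carry known per-channel shift
magnitudes, cohorts share latent factors between features and labels with a
tunable signal strength, embedding fixtures carry a planted descriptor
grouping, and spectra have a controlled sparsity over a fixed m/z axis.

One global seed expands into fixed per-operation substreams, so adding a
stage to a pipeline never perturbs the draws of an earlier one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import DescriptorMatrix, FeatureTable, SensorTrace

logger = logging.getLogger(__name__)

# substream tags: one per generator so streams are independent under one seed
_STREAM_TRACES = 101
_STREAM_COHORT = 102
_STREAM_EMBEDDING = 103
_STREAM_SPECTRA = 104


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


@dataclass
class TraceGroundTruth:
    """Planted parameters of one simulated QCM exposure.

    The response of channel c is ``base[c]`` plus Gaussian noise before the
    onset; from the onset on, the frequency moves toward ``base[c] -
    magnitude[c]`` with an exponential rise (time constant ``rise_tau``
    samples) and, when ``decay_tau`` is finite, relaxes back with that time
    constant.  The rise/decay profile is normalized to peak at exactly 1, so
    the planted magnitude is attained exactly at the peak reading — which is
    what makes noiseless traces an exact oracle for feature extraction.
    """

    base_frequency: np.ndarray
    shift_magnitude: np.ndarray
    onset_index: int
    rise_tau: float = 30.0
    decay_tau: float = math.inf
    noise_sd: float = 0.0
    n_timepoints: int = 300

    def __post_init__(self) -> None:
        self.base_frequency = np.asarray(self.base_frequency, dtype=float)
        self.shift_magnitude = np.asarray(self.shift_magnitude, dtype=float)
        if self.base_frequency.shape != self.shift_magnitude.shape:
            raise ValueError("base_frequency and shift_magnitude must have equal length")
        if (self.shift_magnitude < 0).any():
            raise ValueError("shift magnitudes must be >= 0")
        if not 1 <= self.onset_index <= self.n_timepoints - 1:
            raise ValueError("onset index outside trace length")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ValueError("time constants must be positive")

    @property
    def n_channels(self) -> int:
        return len(self.base_frequency)

    def response_profile(self) -> np.ndarray:
        """Unit-peak response shape over timepoints (0 before onset)."""
        t = np.arange(self.n_timepoints, dtype=float)
        dt = t - self.onset_index + 1.0
        raw = np.where(dt > 0, 1.0 - np.exp(-np.maximum(dt, 0.0) / self.rise_tau), 0.0)
        if math.isfinite(self.decay_tau):
            raw = raw * np.exp(-np.maximum(dt - 1.0, 0.0) / self.decay_tau)
        peak = raw.max()
        return raw / peak if peak > 0 else raw


def paper_like_trace_truth(
    n_channels: int = 35,
    n_timepoints: int = 300,
    onset_index: int = 100,
    seed: int = 0,
    noise_sd: float = 2.0,
) -> TraceGroundTruth:
    """A realistic 35-channel truth: ~10 MHz base, 10-200 Hz shifts, mid-trace peak."""
    rng = _rng(seed, _STREAM_TRACES + 1)
    # integer Hz: the frequency counter reports whole counts, and integer
    # bases keep the noiseless baseline mean float-exact for oracle tests
    return TraceGroundTruth(
        base_frequency=np.round(rng.uniform(9.9e6, 10.1e6, size=n_channels)),
        shift_magnitude=np.round(rng.uniform(10.0, 200.0, size=n_channels)),
        onset_index=onset_index,
        rise_tau=25.0,
        decay_tau=120.0,
        noise_sd=noise_sd,
        n_timepoints=n_timepoints,
    )


def generate_traces(
    n_samples: int,
    truth: TraceGroundTruth | Sequence[TraceGroundTruth],
    n_replicates: int = 3,
    seed: int = 0,
) -> dict[str, list[SensorTrace]]:
    """Simulate replicate traces for ``n_samples`` molecules.

    ``truth`` may be a single ground truth (shared by all samples) or one per
    sample.  Replicates differ only by independent Gaussian noise.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    truths = list(truth) if isinstance(truth, (list, tuple)) else [truth] * n_samples
    if len(truths) != n_samples:
        raise ValueError(f"got {len(truths)} truths for {n_samples} samples")
    rng = _rng(seed, _STREAM_TRACES)
    out: dict[str, list[SensorTrace]] = {}
    for i, tr in enumerate(truths):
        profile = tr.response_profile()  # (T,)
        clean = tr.base_frequency[:, None] - tr.shift_magnitude[:, None] * profile[None, :]
        reps = []
        for _ in range(n_replicates):
            noise = rng.normal(0.0, tr.noise_sd, size=clean.shape) if tr.noise_sd > 0 else 0.0
            reps.append(SensorTrace(clean + noise, shutter_open_index=tr.onset_index))
        out[f"mol{i:03d}"] = reps
    return out


@dataclass
class CohortGroundTruth:
    """Latent structure shared by every modality and the labels.

    Each molecule gets a latent factor vector z ~ N(0, I_d).  Modality m's
    features are ``z @ loadings[m] + noise``; descriptor j is Bernoulli with
    logit ``offset_j + signal_strength * (z . weights_j)`` where ``offset_j``
    is calibrated so the marginal prevalence matches ``prevalences[j]``.
    Descriptor weight vectors are drawn around one center per planted group,
    so semantically grouped descriptors co-occur.
    """

    loadings: Mapping[str, np.ndarray]          # modality -> (d, p_m)
    prevalences: np.ndarray                     # (n_descriptors,) in (0, 1)
    signal_strength: float
    grouping: Mapping[str, int]                 # descriptor -> group index
    descriptor_weights: np.ndarray              # (n_descriptors, d), unit rows
    # loading columns carry ~d units of signal variance; sd 0.3 keeps the
    # planted factors dominant (~2% noise share), like the study's e-nose table
    feature_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        self.prevalences = np.asarray(self.prevalences, dtype=float)
        if not ((self.prevalences > 0) & (self.prevalences < 1)).all():
            raise ValueError("prevalences must lie in (0, 1)")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")
        if len(self.grouping) != len(self.prevalences):
            raise ValueError("grouping must cover the descriptor vocabulary")

    @property
    def latent_dim(self) -> int:
        return self.descriptor_weights.shape[1]


def fig2_like_prevalences(n_descriptors: int, n_molecules: int = 114) -> np.ndarray:
    """A long-tailed prevalence profile like the study cohort's.

    The two most frequent descriptors sit near 55/114 and 52/114 positives and
    the tail decays geometrically to a floor, leaving most descriptors with
    fewer than 12 positives out of 114.
    """
    ranks = np.arange(n_descriptors, dtype=float)
    p = np.maximum(55.0 / n_molecules * np.exp(-0.12 * ranks), 2.5 / n_molecules)
    p[: min(2, n_descriptors)] = [55.0 / n_molecules, 52.0 / n_molecules][: min(2, n_descriptors)]
    return p


def default_cohort_truth(
    vocabulary: Sequence[str],
    signal_strength: float = 3.0,
    latent_dim: int = 5,
    n_groups: int = 6,
    modalities: Sequence[str] = ("enose", "descriptors", "spectrum"),
    modality_widths: Mapping[str, int] | None = None,
    prevalences: np.ndarray | None = None,
    seed: int = 0,
) -> CohortGroundTruth:
    """Build a cohort truth with study-like defaults.

    The latent dimension defaults to 5, the effective dimensionality found
    for the e-nose features; descriptor groups partition the vocabulary into
    ``n_groups`` contiguous-size blocks with group-specific weight centers.
    """
    rng = _rng(seed, _STREAM_COHORT + 1)
    widths = {"enose": 35, "descriptors": 60, "spectrum": 40}
    if modality_widths:
        widths.update(modality_widths)
    loadings = {m: rng.normal(size=(latent_dim, widths.get(m, 30))) for m in modalities}
    n = len(vocabulary)
    if prevalences is None:
        prevalences = fig2_like_prevalences(n)
    group_of = {w: (i % n_groups) + 1 for i, w in enumerate(vocabulary)}
    centers = rng.normal(size=(n_groups, latent_dim))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    weights = np.empty((n, latent_dim))
    for j, w in enumerate(vocabulary):
        v = centers[group_of[w] - 1] + 0.3 * rng.normal(size=latent_dim)
        weights[j] = v / np.linalg.norm(v)
    return CohortGroundTruth(
        loadings=loadings,
        prevalences=np.asarray(prevalences),
        signal_strength=signal_strength,
        grouping=group_of,
        descriptor_weights=weights,
    )


def generate_cohort(
    n_molecules: int,
    vocabulary: Sequence[str],
    truth: CohortGroundTruth,
    seed: int = 0,
) -> tuple[dict[str, FeatureTable], DescriptorMatrix]:
    """Draw one cohort: a feature table per modality plus the label matrix.

    With ``signal_strength = 0`` the labels are independent of every feature
    table by construction (the null cohort).  The logit offset is corrected by
    the logistic-normal factor sqrt(1 + pi * s^2 / 8) so the marginal
    prevalence stays close to the planted one at any signal strength.
    """
    if n_molecules < 2:
        raise ValueError("n_molecules must be >= 2")
    if not vocabulary:
        raise ValueError("vocabulary must be non-empty")
    if len(vocabulary) != len(truth.prevalences):
        raise ValueError("vocabulary size does not match truth.prevalences")
    rng = _rng(seed, _STREAM_COHORT)
    ids = [f"mol{i:03d}" for i in range(n_molecules)]
    d = truth.latent_dim
    z = rng.normal(size=(n_molecules, d))

    tables: dict[str, FeatureTable] = {}
    for modality, L in truth.loadings.items():
        x = z @ L + rng.normal(0.0, truth.feature_noise_sd, size=(n_molecules, L.shape[1]))
        df = pd.DataFrame(x, index=ids, columns=[f"f{k}" for k in range(L.shape[1])])
        tables[modality] = FeatureTable(df, provenance=modality if modality in
                                        ("enose", "bfp", "cfp", "descriptors", "spectrum")
                                        else "synthetic")

    s = truth.signal_strength
    correction = math.sqrt(1.0 + math.pi * s * s / 8.0)
    offsets = correction * np.log(truth.prevalences / (1.0 - truth.prevalences))
    logits = offsets[None, :] + s * (z @ truth.descriptor_weights.T)
    probs = 1.0 / (1.0 + np.exp(-logits))
    y = (rng.uniform(size=probs.shape) < probs).astype(int)
    labels = DescriptorMatrix(pd.DataFrame(y, index=ids, columns=list(vocabulary)))
    return tables, labels


def generate_embedding_fixture(
    grouping: Mapping[str, int],
    dim: int = 300,
    separation: float = 4.0,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Word vectors with planted group structure.

    Each group gets an orthogonalized center; a word's vector is the center
    scaled by ``separation`` plus isotropic noise of unit expected norm,
    normalized to unit length.  The noise scaling makes ``separation``
    dimension-free: at separation s the expected within-group cosine is about
    s^2/(s^2+1), so s >= ~4 separates groups cleanly while ``separation = 0``
    yields pure noise.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = _rng(seed, _STREAM_EMBEDDING)
    groups = sorted(set(grouping.values()))
    raw = rng.normal(size=(dim, max(len(groups), 1)))
    q, _ = np.linalg.qr(raw)  # orthonormal centers when n_groups <= dim
    centers = {g: q[:, i % q.shape[1]] for i, g in enumerate(groups)}
    vectors: dict[str, np.ndarray] = {}
    for word, g in grouping.items():
        v = separation * centers[g] + rng.normal(size=dim) / math.sqrt(dim)
        vectors[word] = v / np.linalg.norm(v)
    return vectors


def generate_spectra(
    n_molecules: int,
    n_mz_bins: int,
    sparsity: float,
    seed: int = 0,
    mz_start: int = 27,
) -> dict[str, list[tuple[int, float]]]:
    """Sparse EI-style stick spectra on integer m/z bins.

    Every spectrum gets exactly ``ceil(sparsity * n_mz_bins)`` peaks with
    positive intensities.  When the cohort has capacity, peak positions are
    repaired so the union of observed m/z covers all configured bins (the
    downstream matrix width then equals the bin count).
    """
    if n_mz_bins < 1:
        raise ValueError("n_mz_bins must be >= 1")
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must be in (0, 1]")
    rng = _rng(seed, _STREAM_SPECTRA)
    k = math.ceil(sparsity * n_mz_bins)
    bins = np.arange(mz_start, mz_start + n_mz_bins)
    peak_sets = [set(rng.choice(bins, size=k, replace=False).tolist())
                 for _ in range(n_molecules)]
    usage: dict[int, int] = {}
    for s in peak_sets:
        for b in s:
            usage[b] = usage.get(b, 0) + 1
    missing = [int(b) for b in bins if b not in usage]
    for b in missing:  # swap under-used bins in where capacity allows
        placed = False
        order = rng.permutation(n_molecules)
        for i in order:
            swappable = [x for x in peak_sets[i] if usage[x] >= 2]
            if swappable:
                out = swappable[int(rng.integers(len(swappable)))]
                peak_sets[i].discard(out)
                peak_sets[i].add(b)
                usage[out] -= 1
                usage[b] = 1
                placed = True
                break
        if not placed:
            logger.info("m/z bin %d left uncovered (cohort capacity too small)", b)
    out: dict[str, list[tuple[int, float]]] = {}
    for i, s in enumerate(peak_sets):
        mzs = sorted(s)
        intensities = rng.uniform(1.0, 100.0, size=len(mzs))
        out[f"mol{i:03d}"] = [(int(m), float(v)) for m, v in zip(mzs, intensities)]
    return out
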
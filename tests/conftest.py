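"""Shared fixtures: small ground-truthed cohorts built at test time."""

from __future__ import annotations

import numpy as np
import pytest

import smellbench as sb


@pytest.fixture(scope="session")
def vocab20() -> list[str]:
    return [f"odor{i:02d}" for i in range(20)]


@pytest.fixture(scope="session")
def signal_cohort(vocab20):
    """A 60-molecule cohort with strong feature-label signal."""
    truth = sb.default_cohort_truth(vocab20, signal_strength=3.0, seed=11)
    tables, labels = sb.generate_cohort(60, vocab20, truth, seed=11)
    return truth, tables, labels


@pytest.fixture(scope="session")
def null_cohort(vocab20):
    """A cohort whose labels are independent of every feature table."""
    truth = sb.default_cohort_truth(vocab20, signal_strength=0.0, seed=12)
    tables, labels = sb.generate_cohort(60, vocab20, truth, seed=12)
    return truth, tables, labels


@pytest.fixture(scope="session")
def planted_embedding():
    """30 words in 3 well-separated groups, plus the planted partition."""
    grouping = {f"w{i:02d}": (i % 3) + 1 for i in range(30)}
    vectors = sb.generate_embedding_fixture(grouping, dim=50, separation=6.0, seed=13)
    return grouping, vectors


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(99)
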
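"""Descriptor grouping: cosine similarity, clustering and group targets."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import smellbench as sb
from smellbench.datatypes import DescriptorMatrix
from smellbench.grouping import embed_descriptor


class TestCosineSimilarity:
    def test_identity_orthogonal_and_half_sqrt2(self):
        assert sb.cosine_similarity([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert sb.cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
        assert sb.cosine_similarity([1, 1], [1, 0]) == pytest.approx(
            math.sqrt(2) / 2, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero vector"):
            sb.cosine_similarity([0, 0], [1, 1])

    def test_matches_brute_force_oracle_on_random_pairs(self, rng):
        for _ in range(100):
            u = rng.normal(size=10)
            v = rng.normal(size=10)
            num = sum(a * b for a, b in zip(u, v))
            den = math.sqrt(sum(a * a for a in u)) * math.sqrt(sum(b * b for b in v))
            assert sb.cosine_similarity(u, v) == pytest.approx(num / den, abs=1e-12)


class TestSimilarityMatrix:
    def test_invariants_hold(self, planted_embedding):
        grouping, vectors = planted_embedding
        sim = sb.similarity_matrix(list(grouping), vectors)
        m = sim.data.to_numpy()
        np.testing.assert_allclose(np.diag(m), 1.0)
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        assert m.min() >= -1 - 1e-12 and m.max() <= 1 + 1e-12

    def test_multiword_descriptor_averages_token_vectors(self):
        vectors = {"green": np.array([1.0, 0.0]), "tea": np.array([0.0, 1.0])}
        np.testing.assert_allclose(embed_descriptor("green tea", vectors), [0.5, 0.5])
        np.testing.assert_allclose(embed_descriptor("green-tea", vectors), [0.5, 0.5])

    def test_out_of_vocabulary_token_raises(self):
        with pytest.raises(KeyError, match="durian"):
            embed_descriptor("durian", {"sweet": np.ones(3)})


class TestClusterDescriptors:
    def test_n_clusters_equal_vocab_gives_singletons(self, planted_embedding):
        grouping, vectors = planted_embedding
        sim = sb.similarity_matrix(list(grouping), vectors)
        result = sb.cluster_descriptors(sim, len(grouping))
        assert sorted(result.sizes().values()) == [1] * len(grouping)

    def test_recovers_planted_two_group_partition(self):
        planted = {f"w{i}": (i % 2) + 1 for i in range(24)}
        vectors = sb.generate_embedding_fixture(planted, dim=40, separation=6.0, seed=81)
        sim = sb.similarity_matrix(list(planted), vectors)
        result = sb.cluster_descriptors(sim, 2)
        truth = [planted[w] for w in planted]
        found = [result.assignments[w] for w in planted]
        assert adjusted_rand_score(truth, found) == 1.0

    def test_93_descriptors_cut_at_6_gives_6_nonempty_groups(self):
        planted = {f"odor{i:02d}": (i % 6) + 1 for i in range(93)}
        vectors = sb.generate_embedding_fixture(planted, dim=100, separation=5.0, seed=82)
        sim = sb.similarity_matrix(list(planted), vectors)
        result = sb.cluster_descriptors(sim, 6)
        assert result.n_clusters == 6
        assert all(s > 0 for s in result.sizes().values())
        # stable naming: cluster 1 is the largest
        sizes = [result.sizes()[c] for c in range(1, 7)]
        assert sizes == sorted(sizes, reverse=True)

    def test_partition_invariant_to_vocabulary_order(self, planted_embedding):
        grouping, vectors = planted_embedding
        words = list(grouping)
        sim1 = sb.similarity_matrix(words, vectors)
        sim2 = sb.similarity_matrix(list(reversed(words)), vectors)
        r1 = sb.cluster_descriptors(sim1, 3)
        r2 = sb.cluster_descriptors(sim2, 3)
        a1 = [r1.assignments[w] for w in words]
        a2 = [r2.assignments[w] for w in words]
        assert adjusted_rand_score(a1, a2) == 1.0

    def test_range_validation(self, planted_embedding):
        grouping, vectors = planted_embedding
        sim = sb.similarity_matrix(list(grouping), vectors)
        with pytest.raises(ValueError):
            sb.cluster_descriptors(sim, 0)
        with pytest.raises(ValueError):
            sb.cluster_descriptors(sim, len(grouping) + 1)


class TestGroupTargets:
    @staticmethod
    def tiny_labels():
        return DescriptorMatrix(pd.DataFrame(
            [[0, 1, 0], [0, 0, 0], [1, 1, 1]],
            index=["m0", "m1", "m2"], columns=["a", "b", "c"]))

    def test_or_rule(self):
        grouping = sb.DescriptorGrouping({"a": 1, "b": 1, "c": 2}, n_clusters=2)
        targets = sb.build_group_targets(self.tiny_labels(), grouping)
        np.testing.assert_array_equal(targets.values,
                                      [[1, 0], [0, 0], [1, 1]])

    def test_descriptorless_sample_is_all_zero(self):
        grouping = sb.DescriptorGrouping({"a": 1, "b": 1, "c": 2}, n_clusters=2)
        targets = sb.build_group_targets(self.tiny_labels(), grouping)
        assert targets.data.loc["m1"].sum() == 0

    def test_missing_descriptor_named_in_error(self):
        grouping = sb.DescriptorGrouping({"a": 1, "b": 2}, n_clusters=2)
        with pytest.raises(ValueError, match="'c'"):
            sb.build_group_targets(self.tiny_labels(), grouping)

    def test_or_bounds_on_synthetic_cohort(self, signal_cohort):
        """max member positives <= group positives <= sum of member positives."""
        truth, _, labels = signal_cohort
        grouping = sb.DescriptorGrouping(dict(truth.grouping),
                                         n_clusters=max(truth.grouping.values()))
        targets = sb.build_group_targets(labels, grouping)
        member_counts = labels.positives()
        for c in range(1, grouping.n_clusters + 1):
            members = grouping.members(c)
            g = int(targets.data[f"group{c}"].sum())
            assert g >= max(member_counts[m] for m in members)
            assert g <= sum(member_counts[m] for m in members)


class TestEvaluateGroups:
    def test_separable_groups_sit_in_the_good_roc_corner(self, rng):
        n = 120
        y = np.zeros(n, dtype=int)
        y[:50] = 1
        x = rng.normal(size=(n, 2))
        x[y == 1] += 8.0
        targets = DescriptorMatrix(pd.DataFrame({"group1": y},
                                   index=[f"m{i}" for i in range(n)]))
        ev = sb.evaluate_groups(x, targets, "binary_svm", k=5, repeats=2, seed=6)
        assert ev.rates.loc["group1", "tpr"] >= 0.95
        assert ev.rates.loc["group1", "fpr"] <= 0.05

    def test_permuted_targets_land_near_chance_diagonal(self, rng):
        n = 150
        y = np.zeros(n, dtype=int)
        y[:60] = 1
        x = rng.normal(size=(n, 2))
        x[y == 1] += 8.0
        permuted = DescriptorMatrix(pd.DataFrame({"group1": rng.permutation(y)},
                                    index=[f"m{i}" for i in range(n)]))
        ev = sb.evaluate_groups(x, permuted, "binary_svm", k=5, repeats=2, seed=6)
        tpr = ev.rates.loc["group1", "tpr"]
        fpr = ev.rates.loc["group1", "fpr"]
        assert abs(tpr - fpr) < 0.25  # near the diagonal

    def test_all_positive_group_excluded(self, rng):
        n = 30
        targets = DescriptorMatrix(pd.DataFrame(
            {"group1": np.ones(n, int), "group2": (np.arange(n) < 10).astype(int)},
            index=[f"m{i}" for i in range(n)]))
        ev = sb.evaluate_groups(rng.normal(size=(n, 2)), targets,
                                "binary_svm", k=3, repeats=1, seed=1)
        assert "group1" in ev.excluded
        assert list(ev.rates.index) == ["group2"]
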
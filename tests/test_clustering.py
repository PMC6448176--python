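import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from problist.clustering import (
    cut,
    deduplicate,
    default_height_grid,
    infer_cutoff,
    to_newick,
    upgma,
)
from problist.corpus import Corpus
from .conftest import make_item


def brute_force_average_linkage(distances):
    """O(n^3) UPGMA oracle: repeatedly merge the pair of clusters with the
    smallest mean pairwise original distance; returns (merge heights, list of
    partitions after each merge as sets of frozensets)."""
    n = distances.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    heights, partitions = [], []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean(
                    [distances[i, j] for i in clusters[a] for j in clusters[b]]
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
        heights.append(d)
        partitions.append(set(clusters))
    return heights, partitions


def random_distance_matrix(rng, n):
    d = rng.random((n, n))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def partition_as_sets(topic_partition):
    return {frozenset(int(x) for x in members) for members in
            topic_partition.clusters.values()}


class TestUpgma:
    def test_four_point_example(self):
        # two tight pairs, all cross distances 0.8
        d = np.full((4, 4), 0.8)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 0.1
        d[2, 3] = d[3, 2] = 0.2
        dendrogram = upgma(d, ["a", "b", "c", "d"])
        np.testing.assert_allclose(dendrogram.heights, [0.1, 0.2, 0.8])
        partition = cut(dendrogram, 0.5)
        assert {frozenset(m) for m in partition.clusters.values()} == {
            frozenset({"a", "b"}),
            frozenset({"c", "d"}),
        }

    def test_two_points(self):
        dendrogram = upgma(np.array([[0.0, 0.5], [0.5, 0.0]]))
        np.testing.assert_allclose(dendrogram.heights, [0.5])

    def test_identical_points_merge_at_zero(self):
        dendrogram = upgma(np.zeros((5, 5)))
        np.testing.assert_allclose(dendrogram.heights, 0.0)

    def test_rejects_asymmetric(self):
        d = np.array([[0.0, 0.4], [0.5, 0.0]])
        with pytest.raises(ValueError):
            upgma(d)

    def test_rejects_negative(self):
        d = np.array([[0.0, -0.1], [-0.1, 0.0]])
        with pytest.raises(ValueError):
            upgma(d)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        d = random_distance_matrix(rng, n)
        dendrogram = upgma(d)
        heights, partitions = brute_force_average_linkage(d)
        np.testing.assert_allclose(sorted(dendrogram.heights), sorted(heights),
                                   atol=1e-12)
        # identical flat partitions between any two consecutive merge heights
        boundaries = sorted(heights)
        for level, oracle_partition in zip(boundaries, partitions):
            probe = cut(dendrogram, level + 1e-9)
            assert partition_as_sets(probe) == oracle_partition


class TestCut:
    def test_height_zero_gives_singletons(self):
        d = random_distance_matrix(np.random.default_rng(0), 6)
        dendrogram = upgma(d)
        assert cut(dendrogram, 0.0).n_topics == 6

    def test_height_above_max_gives_one_cluster(self):
        d = random_distance_matrix(np.random.default_rng(0), 6)
        dendrogram = upgma(d)
        assert cut(dendrogram, 1.0).n_topics == 1

    def test_merge_at_exact_height_joins(self):
        dendrogram = upgma(np.array([[0.0, 0.5], [0.5, 0.0]]))
        assert cut(dendrogram, 0.5).n_topics == 1  # closed boundary

    def test_monotone_nesting_along_grid(self):
        rng = np.random.default_rng(7)
        dendrogram = upgma(random_distance_matrix(rng, 10))
        previous = None
        for height in default_height_grid():
            membership = cut(dendrogram, height).membership
            if previous is not None:
                # raising the height never splits an existing cluster
                for i in membership:
                    for j in membership:
                        if previous[i] == previous[j]:
                            assert membership[i] == membership[j]
            previous = membership


class TestInferCutoff:
    def make_separated(self):
        # within-group distances < between-group distances
        d = np.full((6, 6), 0.9)
        for block in ([0, 1, 2], [3, 4, 5]):
            for i in block:
                for j in block:
                    d[i, j] = 0.1 if i != j else 0.0
        return upgma(d, [f"x{i}" for i in range(6)])

    def test_separated_groups_reach_f1(self):
        dendrogram = self.make_separated()
        labels = {"x0": "A", "x1": "A", "x2": "A", "x3": "B", "x4": "B", "x5": "B"}
        result = infer_cutoff(dendrogram, labels, default_height_grid())
        assert result.best_f == pytest.approx(1.0)
        # smallest grid height that completes both groups: 0.1
        assert result.best_height == pytest.approx(0.1)

    def test_single_shared_code_best_at_smallest_complete_height(self):
        dendrogram = self.make_separated()
        labels = {f"x{i}": "A" for i in range(6)}
        result = infer_cutoff(dendrogram, labels, default_height_grid())
        assert result.best_f == pytest.approx(1.0)
        assert result.best_height == pytest.approx(0.9)

    def test_grid_zero_on_distinct_points_gives_f0(self):
        dendrogram = self.make_separated()
        labels = {"x0": "A", "x1": "A", "x3": "B"}
        result = infer_cutoff(dendrogram, labels, [0.0])
        assert result.best_f == 0.0
        assert result.trace == [(0.0, 0.0, 0.0, 0.0)]

    def test_requires_two_coded_items(self):
        dendrogram = self.make_separated()
        with pytest.raises(ValueError):
            infer_cutoff(dendrogram, {"x0": "A"}, [0.5])

    def test_requires_a_same_code_pair(self):
        dendrogram = self.make_separated()
        with pytest.raises(ValueError):
            infer_cutoff(dendrogram, {"x0": "A", "x1": "B"}, [0.5])

    def test_trace_maximum_is_best_f(self):
        dendrogram = self.make_separated()
        labels = {"x0": "A", "x1": "A", "x2": "B", "x3": "B", "x4": "C", "x5": "C"}
        result = infer_cutoff(dendrogram, labels, default_height_grid())
        f_values = [f for _, _, _, f in result.trace]
        assert result.best_f == max(f_values)
        assert result.best_height == min(
            h for h, _, _, f in result.trace if f == result.best_f
        )


class TestDeduplicate:
    def test_multiplicity_map(self):
        corpus = Corpus(
            [
                make_item("i1", "Pneumonie"),
                make_item("i2", "Pneumonie"),
                make_item("i3", "Lumbalgie"),
            ]
        )
        unique, groups = deduplicate(corpus)
        assert unique == ["Pneumonie", "Lumbalgie"]
        assert groups == {"Pneumonie": ["i1", "i2"], "Lumbalgie": ["i3"]}

    def test_all_identical(self):
        corpus = Corpus([make_item(f"i{k}", "Pneumonie") for k in range(5)])
        unique, groups = deduplicate(corpus)
        assert unique == ["Pneumonie"]
        assert len(groups["Pneumonie"]) == 5

    def test_all_distinct_is_identity(self):
        corpus = Corpus([make_item(f"i{k}", f"Diagnose {k}") for k in range(4)])
        unique, groups = deduplicate(corpus)
        assert len(unique) == 4
        assert all(len(v) == 1 for v in groups.values())


def test_newick_export_parses_and_covers_leaves():
    d = random_distance_matrix(np.random.default_rng(3), 5)
    leaf_ids = [f"item {i}" for i in range(5)]
    newick = to_newick(upgma(d, leaf_ids))
    assert newick.endswith(";")
    assert newick.count(",") == 4  # n leaves -> n-1 separators in a binary tree
    for leaf in leaf_ids:
        assert f"'{leaf}'" in newick  # quoted because of the space
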
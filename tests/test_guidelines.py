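"""Clustering and guideline-extraction tests with planted ground truth."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster

import moodkit as mk
from moodkit.errors import ConfigError, InvalidParameterError
from moodkit.fixtures import FixtureSpec, make_fixture
from moodkit.guidelines import cluster_tree, extract_guidelines, kruskal_wallis, select_k


class TestKruskalWallis:
    def test_hand_computed_two_groups(self):
        # ranks 1..6, R1=6, R2=15: H = 12/(6*7) * (36/3 + 225/3) - 3*7
        h, p = kruskal_wallis([1, 2, 3, 4, 5, 6], [1, 1, 1, 2, 2, 2])
        assert h == pytest.approx(3.857142857, abs=1e-6)
        assert 0 < p < 1

    def test_hand_computed_five_vs_five(self):
        vals = list(range(1, 11))
        labels = [1] * 5 + [2] * 5
        h, _ = kruskal_wallis(vals, labels)
        assert h == pytest.approx(6.818181818, abs=1e-6)

    def test_identical_values_zero_h(self):
        h, p = kruskal_wallis([3.0] * 8, [1, 1, 1, 1, 2, 2, 2, 2])
        assert h == 0.0 and p == 1.0

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(4)
        vals = rng.random(20)
        labels = np.repeat([1, 2], 10)
        h1, p1 = kruskal_wallis(vals, labels)
        h2, p2 = kruskal_wallis(vals, np.where(labels == 1, 2, 1))
        assert h1 == h2 and p1 == p2

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidParameterError):
            kruskal_wallis([1.0, 2.0], [1, 1])


def _wpgmc_oracle(X):
    """Brute-force weighted-centroid agglomeration for tiny inputs.

    Returns the merge heights in order. Median/WPGMC linkage: the merged
    cluster's centroid is the midpoint of its parents' centroids and
    inter-cluster distance is the Euclidean centroid distance.
    """
    clusters = [np.asarray(x, dtype=float) for x in X]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = float(np.linalg.norm(clusters[i] - clusters[j]))
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = 0.5 * (clusters[i] + clusters[j])
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return heights


class TestClusterTree:
    def test_two_blobs_split_exactly(self):
        rng = np.random.default_rng(0)
        front = np.vstack([
            rng.normal([0.1, 0.9], 0.02, (10, 2)),
            rng.normal([0.9, 0.1], 0.02, (10, 2)),
        ])
        tree = cluster_tree(front)
        labels = fcluster(tree, t=2, criterion="maxclust")
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]

    def test_four_point_merges_match_oracle(self):
        front = np.array([[0.0, 0.0], [0.1, 0.0], [1.0, 1.0], [0.8, 1.0]])
        tree = cluster_tree(front)
        # the tree is built on min-max normalized coordinates
        X = mk.normalize_front(front)
        expected = _wpgmc_oracle(list(X))
        assert np.allclose(sorted(tree[:, 2]), sorted(expected), atol=1e-12)

    def test_duplicate_points_merge_at_zero_height(self):
        front = np.array([[0.2, 0.4]] * 3 + [[0.9, 0.1]])
        tree = cluster_tree(front)
        assert tree[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_single_solution_rejected(self):
        with pytest.raises(ConfigError):
            cluster_tree(np.array([[1.0, 2.0]]))


class TestSelectK:
    def planted(self, seed=0, effect=1.0):
        return make_fixture(FixtureSpec(kind="planted", size=40,
                                        effect=effect, seed=seed))

    def test_planted_two_clusters_recovered(self):
        for seed in (0, 1, 2):
            data = self.planted(seed)
            tree = cluster_tree(data.front)
            res = select_k(tree, data.theta, alpha=0.05, names=list(data.names))
            assert res.k == 2
            tab = res.table[res.table.k == 2]
            sig = set(tab[tab.significant]["parameter"])
            assert {data.names[j] for j in data.shifted} <= sig

    def test_constant_parameters_tie_to_smallest_k(self):
        data = self.planted(0)
        theta = np.full_like(data.theta, 0.5)  # H = 0 everywhere, all k tie
        tree = cluster_tree(data.front)
        res = select_k(tree, theta, alpha=0.05, names=list(data.names))
        assert res.k == 2

    def test_labels_partition_all_solutions(self):
        data = self.planted(3)
        tree = cluster_tree(data.front)
        res = select_k(tree, data.theta, names=list(data.names))
        assert res.labels.size == data.front.shape[0]
        assert set(np.unique(res.labels)) == set(range(1, res.k + 1))

    def test_monotone_recovery_in_effect_size(self):
        """A larger planted shift never finds fewer significant parameters."""
        for seed in (0, 1):
            counts = []
            for effect in (0.2, 0.6, 1.0):
                data = self.planted(seed, effect)
                tree = cluster_tree(data.front)
                res = select_k(tree, data.theta, names=list(data.names))
                tab = res.table[res.table.k == res.k]
                counts.append(int(tab["significant"].sum()))
            assert counts == sorted(counts)


class TestExtractGuidelines:
    def test_planted_classification(self):
        data = make_fixture(FixtureSpec(kind="planted", size=40, seed=1))
        tree = cluster_tree(data.front)
        clustering = select_k(tree, data.theta, names=list(data.names))
        report = extract_guidelines(clustering, data.theta, data.bounds)
        for j in data.shifted:
            entry = report[data.names[j]]
            assert entry.category == "cluster-specific"
            # planted shift of 1.0 separates the per-cluster ranges entirely
            r1, r2 = (entry.per_cluster[c] for c in sorted(entry.per_cluster))
            assert r1[1] < r2[0] or r2[1] < r1[0]

    def test_full_width_parameter_unconstrained(self):
        rng = np.random.default_rng(2)
        front = np.vstack([
            rng.normal([0.2, 0.8], 0.03, (15, 2)),
            rng.normal([0.8, 0.2], 0.03, (15, 2)),
        ])
        theta = np.linspace(0.0, 1.0, 30)[:, None]  # spans its full bounds
        tree = cluster_tree(front)
        clustering = select_k(tree, theta, names=["p0"])
        report = extract_guidelines(clustering, theta, {"p0": (0.0, 1.0)},
                                    alpha=1e-9)  # suppress cluster-specificity
        assert report["p0"].category == "unconstrained"

    def test_compressed_parameter_becomes_general(self):
        data = make_fixture(FixtureSpec(kind="planted", size=30, seed=5,
                                        options={"n_shift": 0}))
        theta = 0.4 + 0.05 * np.random.default_rng(0).random((30, 1))
        tree = cluster_tree(data.front)
        clustering = select_k(tree, theta, names=["p0"], alpha=1e-9)
        report = extract_guidelines(clustering, theta, {"p0": (0.0, 1.0)},
                                    alpha=1e-9, shrink_threshold=0.6)
        assert report["p0"].category == "general"

    def test_ranges_within_initial_bounds(self):
        data = make_fixture(FixtureSpec(kind="planted", size=40, seed=7))
        tree = cluster_tree(data.front)
        clustering = select_k(tree, data.theta, names=list(data.names))
        report = extract_guidelines(clustering, data.theta, data.bounds)
        for e in report.entries:
            lo, hi = e.initial
            assert lo <= e.overall[0] <= e.overall[1] <= hi
            for r in e.per_cluster.values():
                assert lo <= r[0] <= r[1] <= hi

    def test_report_frame_has_one_row_per_parameter(self):
        data = make_fixture(FixtureSpec(kind="planted", size=40, seed=8))
        tree = cluster_tree(data.front)
        clustering = select_k(tree, data.theta, names=list(data.names))
        report = extract_guidelines(clustering, data.theta, data.bounds)
        frame = report.to_frame()
        assert list(frame["parameter"]) == list(data.names)
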
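"""Conservation filter, clustering, link tables and map exports."""

import itertools

import numpy as np
import pytest

from pocketmap import (
    NOISE,
    SimilarityMatrix,
    build_cluster_map,
    cluster_link_table,
    conservation_filter,
    dbscan_map,
    hierarchical_map,
    write_map_outputs,
)
from pocketmap.mapping import MappingError


def matrix_from(scores, targets=None, ids=None):
    scores = np.asarray(scores, float)
    n = len(scores)
    ids = ids or [f"p{k}" for k in range(n)]
    targets = targets or ["T"] * n
    return SimilarityMatrix(patch_ids=ids, target_labels=targets, scores=scores)


def block_matrix(sizes, within=4.0, across=0.0, diag=4.0):
    """Square matrix of within-block / across-block scores."""
    n = sum(sizes)
    scores = np.full((n, n), across)
    start = 0
    for size in sizes:
        scores[start:start + size, start:start + size] = within
        start += size
    np.fill_diagonal(scores, diag)
    return scores


# --- brute-force oracles ------------------------------------------------------

def brute_force_dbscan(points, eps, min_samples):
    """Literal textbook DBSCAN: core points by neighbourhood count (self
    included), clusters as connected components of core points, borders
    attached to the lowest-id reachable cluster, the rest noise."""
    n = len(points)
    dist = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    neighbors = [set(np.nonzero(dist[i] <= eps)[0]) for i in range(n)]
    core = [i for i in range(n) if len(neighbors[i]) >= min_samples]
    labels = {i: None for i in range(n)}
    cluster = 0
    for seed in core:
        if labels[seed] is not None:
            continue
        frontier = {seed}
        while frontier:
            i = frontier.pop()
            if labels[i] is not None:
                continue
            labels[i] = cluster
            if i in core:
                frontier |= {j for j in neighbors[i] if labels[j] is None}
        cluster += 1
    return {i: (NOISE if lab is None else lab) for i, lab in labels.items()}


def brute_force_average_linkage(points):
    """Naive agglomerative clustering; returns the sorted merge heights."""
    clusters = {i: [i] for i in range(len(points))}
    dist = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    heights = []
    next_id = len(points)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0] - 1e-15:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return sorted(heights)


class TestConservationFilter:
    def test_three_identical_patches(self):
        m = matrix_from(block_matrix([3]))
        assert conservation_filter(m, min_links=2, threshold=2.0) == ["p0", "p1", "p2"]
        assert conservation_filter(m, min_links=5, threshold=2.0) == []

    def test_exact_link_count_boundary(self):
        """Patch 0 has exactly 5 strong links, patch 1 only 4."""
        scores = np.zeros((8, 8))
        np.fill_diagonal(scores, 4.0)
        for j in range(2, 7):  # p0 links to p2..p6 -> 5 strong links
            scores[0, j] = scores[j, 0] = 2.5
        for j in range(2, 6):  # p1 links to p2..p5 -> only 4
            scores[1, j] = scores[j, 1] = 2.5
        m = matrix_from(scores)
        retained = conservation_filter(m, min_links=5, threshold=2.0)
        assert "p0" in retained and "p1" not in retained

    def test_zero_threshold_retains_everything(self):
        m = matrix_from(np.zeros((8, 8)))
        assert len(conservation_filter(m, min_links=5, threshold=0.0)) == 8

    def test_monotone_in_both_parameters(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(0, 4, (20, 20))
        scores = (scores + scores.T) / 2
        np.fill_diagonal(scores, 4.0)
        m = matrix_from(scores)
        base = set(conservation_filter(m, min_links=5, threshold=2.0))
        assert set(conservation_filter(m, min_links=6, threshold=2.0)) <= base
        assert set(conservation_filter(m, min_links=5, threshold=2.5)) <= base


class TestHierarchicalMap:
    def test_top_split_separates_blocks(self):
        m = matrix_from(block_matrix([5, 5]))
        result = hierarchical_map(m, level="global", cut_n_clusters=2)
        labels = result["global"].flat_labels
        first = {labels[f"p{k}"] for k in range(5)}
        second = {labels[f"p{k}"] for k in range(5, 10)}
        assert len(first) == 1 and len(second) == 1 and first != second

    def test_identical_rows_merge_at_zero(self):
        m = matrix_from(block_matrix([3, 2]))
        z = hierarchical_map(m, level="global")["global"].linkage
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_leaf_order_is_a_permutation(self):
        rng = np.random.default_rng(5)
        scores = rng.uniform(0, 4, (12, 12))
        scores = (scores + scores.T) / 2
        m = matrix_from(scores)
        order = hierarchical_map(m, level="global")["global"].leaf_order
        assert sorted(order) == sorted(m.patch_ids)

    def test_matches_brute_force_merge_heights(self):
        """Average-linkage heights agree with a naive all-pairs implementation
        on small instances."""
        from scipy.spatial.distance import pdist

        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(5, 15))
            scores = rng.uniform(0, 4, (n, n))
            scores = (scores + scores.T) / 2
            np.fill_diagonal(scores, 4.0)
            m = matrix_from(scores)
            z = hierarchical_map(m, level="global")["global"].linkage
            expected = brute_force_average_linkage(np.nan_to_num(scores))
            np.testing.assert_allclose(sorted(z[:, 2]), expected, atol=1e-9)

    def test_within_target_uses_local_columns(self):
        scores = block_matrix([4, 4], within=4.0, across=1.0)
        m = matrix_from(scores, targets=["A"] * 4 + ["B"] * 4)
        result = hierarchical_map(m, level="within_target")
        assert set(result) == {"A", "B"}
        assert sorted(result["A"].leaf_order) == [f"p{k}" for k in range(4)]

    def test_singleton_target(self):
        m = matrix_from(block_matrix([3, 1]), targets=["A"] * 3 + ["B"])
        result = hierarchical_map(m, level="within_target")
        assert result["B"].leaf_order == ["p3"]


class TestDbscanMap:
    def test_dense_cluster_with_outliers(self):
        """12 near-identical rows form one cluster; 3 distant rows are noise."""
        scores = block_matrix([12, 1, 1, 1], within=4.0, across=0.0)
        scores[12, 13] = scores[13, 12] = 0.5  # outliers unrelated to each other
        m = matrix_from(scores)
        labels = dbscan_map(m, eps=7.0, min_samples=10, per_target=False)
        assert sum(1 for v in labels.values() if v != NOISE) == 12
        assert {labels[f"p{k}"] for k in range(12)} == {0}
        assert all(labels[f"p{k}"] == NOISE for k in (12, 13, 14))

    def test_min_samples_above_n_is_all_noise(self):
        m = matrix_from(block_matrix([5]))
        labels = dbscan_map(m, eps=7.0, min_samples=10, per_target=False)
        assert set(labels.values()) == {NOISE}

    def test_shuffle_leaves_partition_unchanged(self):
        rng = np.random.default_rng(8)
        scores = block_matrix([6, 6], within=3.5, across=0.3)
        scores += rng.normal(0, 0.05, scores.shape)
        scores = (scores + scores.T) / 2
        m = matrix_from(scores)
        labels = dbscan_map(m, eps=3.0, min_samples=4, per_target=False)
        perm = rng.permutation(12)
        m2 = m.submatrix([f"p{k}" for k in perm])
        labels2 = dbscan_map(m2, eps=3.0, min_samples=4, per_target=False)

        def partition(lab):
            groups = {}
            for pid, v in lab.items():
                if v != NOISE:
                    groups.setdefault(v, set()).add(pid)
            return {frozenset(g) for g in groups.values()}

        assert partition(labels) == partition(labels2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_reference(self, seed):
        """Core/noise structure agrees with a literal DBSCAN implementation on
        small random instances."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 15))
        scores = rng.uniform(0, 4, (n, n))
        scores = (scores + scores.T) / 2
        np.fill_diagonal(scores, 4.0)
        m = matrix_from(scores)
        eps, min_samples = 4.0, 3
        ours = dbscan_map(m, eps=eps, min_samples=min_samples, per_target=False)
        reference = brute_force_dbscan(np.nan_to_num(scores), eps, min_samples)

        ours_noise = {f"p{i}" for i in range(n) if ours[f"p{i}"] == NOISE}
        ref_noise = {f"p{i}" for i, v in reference.items() if v == NOISE}
        # border points may attach to either adjacent cluster; cores and the
        # core-cluster partition must agree exactly
        dist = np.linalg.norm(
            np.nan_to_num(scores)[:, None, :] - np.nan_to_num(scores)[None, :, :], axis=2
        )
        cores = {i for i in range(n) if (dist[i] <= eps).sum() >= min_samples}
        assert {i for i in cores if ours[f"p{i}"] == NOISE} == set()
        for i, j in itertools.combinations(sorted(cores), 2):
            assert (ours[f"p{i}"] == ours[f"p{j}"]) == (reference[i] == reference[j])
        assert ours_noise - {f"p{i}" for i in range(n) if i not in cores} == set()
        assert ref_noise <= {f"p{i}" for i in range(n) if i not in cores} | set()

    def test_core_points_have_enough_neighbours(self):
        """Post-hoc invariant: every clustered core point has >= min_samples
        neighbours within eps (self included)."""
        rng = np.random.default_rng(9)
        scores = block_matrix([8, 8], within=3.8, across=0.2)
        scores += rng.normal(0, 0.1, scores.shape)
        scores = (scores + scores.T) / 2
        m = matrix_from(scores)
        eps, min_samples = 3.0, 5
        labels = dbscan_map(m, eps=eps, min_samples=min_samples, per_target=False)
        rows = np.nan_to_num(m.scores)
        dist = np.linalg.norm(rows[:, None, :] - rows[None, :, :], axis=2)
        clustered = [k for k in range(16) if labels[f"p{k}"] != NOISE]
        # each cluster must contain at least one core point and every member
        # of a cluster is within eps of one of its cores
        for k in clustered:
            assert (dist[k] <= eps).sum() >= 2  # sanity: not isolated
        cores = [k for k in clustered if (dist[k] <= eps).sum() >= min_samples]
        assert cores


class TestClusterLinkTable:
    def _setup(self):
        scores = block_matrix([4, 4, 4], within=4.0, across=0.0)
        # cross-cluster maxima: A-B strong, A-C weak, B-C weak
        scores[0, 4] = scores[4, 0] = 3.1
        scores[0, 8] = scores[8, 0] = 1.9
        scores[4, 8] = scores[8, 4] = 0.5
        targets = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        m = matrix_from(scores, targets=targets)
        labels = {f"p{k}": 0 for k in range(12)}
        target_of = dict(zip(m.patch_ids, targets))
        return labels, target_of, m

    def test_rows_and_highlighting(self):
        labels, target_of, m = self._setup()
        rows = cluster_link_table(labels, target_of, m, highlight_threshold=2.0)
        assert len(rows) == 3
        by_pair = {(r.target_a, r.target_b): r for r in rows}
        assert by_pair[("A", "B")].max_patch_score == pytest.approx(3.1)
        assert by_pair[("A", "B")].highlighted
        assert by_pair[("A", "C")].max_patch_score == pytest.approx(1.9)
        assert not by_pair[("A", "C")].highlighted
        assert not by_pair[("B", "C")].highlighted

    def test_noise_patches_excluded(self):
        labels, target_of, m = self._setup()
        labels = dict(labels)
        for k in range(8, 12):
            labels[f"p{k}"] = NOISE
        rows = cluster_link_table(labels, target_of, m)
        assert {(r.target_a, r.target_b) for r in rows} == {("A", "B")}


class TestWriteMapOutputs:
    @pytest.fixture()
    def toy_map(self):
        scores = block_matrix([12, 12], within=3.8, across=0.4)
        scores[0, 12] = scores[12, 0] = 2.4
        targets = ["A"] * 12 + ["B"] * 12
        m = matrix_from(scores, targets=targets)
        cmap = build_cluster_map(m, min_links=5, link_threshold=2.0,
                                 eps=7.0, min_samples=10)
        sub = m.submatrix(cmap.retained_ids)
        links = cluster_link_table(cmap.per_target_labels, cmap.target_of, sub)
        return m, cmap, links

    def test_outputs_are_complete_and_stable(self, toy_map, tmp_path):
        m, cmap, links = toy_map
        first = write_map_outputs(cmap, links, m, tmp_path / "run1")
        second = write_map_outputs(cmap, links, m, tmp_path / "run2")
        for name in first:
            assert first[name].exists()
            assert first[name].read_bytes() == second[name].read_bytes()
        link_lines = [l for l in first["links"].read_text().splitlines() if l]
        assert len(link_lines) == len(links)

    def test_reordered_matrix_is_a_permutation(self, toy_map, tmp_path):
        m, cmap, links = toy_map
        paths = write_map_outputs(cmap, links, m, tmp_path / "out")
        reordered = SimilarityMatrix.load(paths["matrix"])
        assert sorted(reordered.patch_ids) == sorted(cmap.retained_ids)
        idx = [m.index_of(i) for i in reordered.patch_ids]
        np.testing.assert_allclose(
            reordered.scores, m.scores[np.ix_(idx, idx)], atol=1e-6
        )

    def test_id_mismatch_is_an_error(self, toy_map, tmp_path):
        m, cmap, links = toy_map
        cmap.retained_ids = cmap.retained_ids + ["ghost"]
        with pytest.raises(MappingError):
            write_map_outputs(cmap, links, m, tmp_path / "bad")
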
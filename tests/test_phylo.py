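"""Distance matrices, UPGMA, Newick export, cophenetic and ARI checks."""

import itertools

import dendropy
import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from echemfp import (
    DegenerateInputError,
    DistanceMatrix,
    InvalidArgumentError,
    adjusted_rand,
    agglomerate,
    cophenetic_correlation,
    cut_clusters,
    distance_matrix,
    to_newick,
    upgma,
)
from echemfp.phylo import cophenetic_matrix, groups_form_exclusive_clades


def brute_force_upgma(D):
    """From-scratch average linkage: recompute every inter-cluster average
    over leaf pairs from the original matrix at every step."""
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    next_id = n
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0] or (d == best[0] and (a, b) < best[1:]):
                best = (d, a, b)
        d, a, b = best
        merges.append((a, b, d / 2.0, len(clusters[a]) + len(clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


def random_distance_matrix(rng, n):
    M = rng.uniform(0.1, 10.0, size=(n, n))
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0.0)
    return M


def block_matrix():
    # {A,B} and {C,D} at distance 2 inside, 10 across
    M = np.full((4, 4), 10.0)
    M[0, 1] = M[1, 0] = 2.0
    M[2, 3] = M[3, 2] = 2.0
    np.fill_diagonal(M, 0.0)
    return DistanceMatrix(["A", "B", "C", "D"], M)


class TestDistanceMatrix:
    def test_identical_rows_zero_distance(self):
        X = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        D = distance_matrix(X)
        assert D.values[0, 1] == 0.0

    def test_three_four_five_triangle(self):
        D = distance_matrix(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert D.values[0, 1] == pytest.approx(5.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(20)
        X = rng.normal(size=(5, 8))
        D = distance_matrix(X)
        for i in range(5):
            for j in range(5):
                expected = np.sqrt(sum((X[i, k] - X[j, k]) ** 2 for k in range(8)))
                assert abs(D.values[i, j] - expected) < 1e-12

    def test_correlation_metric_and_constant_row(self):
        X = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, 2.0, 1.0]])
        D = distance_matrix(X, metric="correlation")
        assert D.values[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert D.values[0, 2] == pytest.approx(2.0)
        with pytest.raises(DegenerateInputError):
            distance_matrix(np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]]), "correlation")


class TestUpgma:
    def test_two_taxa_merge_at_half_distance(self):
        D = DistanceMatrix(["A", "B"], np.array([[0.0, 3.0], [3.0, 0.0]]))
        den = upgma(D)
        assert len(den.merges) == 1
        assert den.merges[0].height == pytest.approx(1.5)

    def test_block_example_merge_order_and_heights(self):
        den = upgma(block_matrix())
        assert [(m.a, m.b) for m in den.merges] == [(0, 1), (2, 3), (4, 5)]
        assert [m.height for m in den.merges] == pytest.approx([1.0, 1.0, 5.0])

    def test_equal_distances_tie_break_by_index(self):
        n = 5
        M = np.full((n, n), 4.0)
        np.fill_diagonal(M, 0.0)
        den = upgma(DistanceMatrix(list("ABCDE"), M))
        assert (den.merges[0].a, den.merges[0].b) == (0, 1)
        assert den.merges[0].height == pytest.approx(2.0)
        # every later merge also happens at height 2 (all distances equal)
        assert all(m.height == pytest.approx(2.0) for m in den.merges)

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            M = random_distance_matrix(rng, n)
            den = upgma(DistanceMatrix([str(i) for i in range(n)], M))
            expected = brute_force_upgma(M)
            for mine, (a, b, h, size) in zip(den.merges, expected):
                assert (mine.a, mine.b) == (a, b)
                assert mine.height == pytest.approx(h, abs=1e-10)
                assert mine.size == size

    def test_cophenetic_matches_scipy_linkage(self):
        rng = np.random.default_rng(22)
        M = random_distance_matrix(rng, 12)
        den = upgma(DistanceMatrix([str(i) for i in range(12)], M))
        Z = linkage(squareform(M), method="average")
        scipy_coph = squareform(cophenet(Z))
        assert np.allclose(cophenetic_matrix(den), scipy_coph, atol=1e-10)

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(23)
        for linkage_name in ("average", "single", "complete"):
            for _ in range(10):
                M = random_distance_matrix(rng, 10)
                den = agglomerate(
                    DistanceMatrix([str(i) for i in range(10)], M), linkage_name
                )
                heights = [m.height for m in den.merges]
                assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))


class TestCutClusters:
    def test_extreme_cuts(self):
        den = upgma(block_matrix())
        assert set(cut_clusters(den, 1).values()) == {1}
        assert sorted(cut_clusters(den, 4).values()) == [1, 2, 3, 4]

    def test_block_example_two_clusters(self):
        labels = cut_clusters(upgma(block_matrix()), 2)
        assert labels == {"A": 1, "B": 1, "C": 2, "D": 2}

    def test_out_of_range_raises(self):
        den = upgma(block_matrix())
        for k in (0, 5):
            with pytest.raises(InvalidArgumentError):
                cut_clusters(den, k)


class TestNewick:
    def test_two_leaf_string(self):
        D = DistanceMatrix(["A", "B"], np.array([[0.0, 2.0], [2.0, 0.0]]))
        assert to_newick(upgma(D)) == "(A:1,B:1);"

    def test_round_trip_preserves_leaves_and_distances(self):
        rng = np.random.default_rng(24)
        M = random_distance_matrix(rng, 7)
        ids = [f"t{i}" for i in range(7)]
        den = upgma(DistanceMatrix(ids, M))
        tree = dendropy.Tree.get(data=to_newick(den), schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == set(ids)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        C = cophenetic_matrix(den)
        for i in range(7):
            for j in range(i + 1, 7):
                assert pdm.patristic_distance(
                    taxa[ids[i]], taxa[ids[j]]
                ) == pytest.approx(C[i, j], abs=1e-9)

    def test_ultrametric_root_to_tip_paths(self):
        rng = np.random.default_rng(25)
        M = random_distance_matrix(rng, 9)
        den = upgma(DistanceMatrix([f"t{i}" for i in range(9)], M))
        tree = dendropy.Tree.get(data=to_newick(den), schema="newick")
        root_height = den.merges[-1].height
        for leaf in tree.leaf_node_iter():
            depth, node = 0.0, leaf
            while node.parent_node is not None:
                depth += node.edge.length
                node = node.parent_node
            assert depth == pytest.approx(root_height, abs=1e-9)


class TestCophenetic:
    def test_block_example_exact_correlation(self):
        D = block_matrix()
        den = upgma(D)
        assert np.allclose(cophenetic_matrix(den), D.values)
        assert cophenetic_correlation(den, D) == pytest.approx(1.0)

    def test_correlation_decreases_with_perturbation(self):
        rng = np.random.default_rng(26)
        D0 = block_matrix()
        correlations = []
        for eps in (0.1, 1.0, 4.0):
            noise = rng.uniform(0, eps, size=(4, 4))
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0.0)
            D = DistanceMatrix(D0.ids, D0.values + noise)
            correlations.append(cophenetic_correlation(upgma(D), D))
        assert all(-1 < c < 1 + 1e-12 for c in correlations)
        assert correlations[0] > correlations[-1]

    def test_constant_distances_raise(self):
        M = np.full((3, 3), 2.0)
        np.fill_diagonal(M, 0.0)
        D = DistanceMatrix(["A", "B", "C"], M)
        with pytest.raises(DegenerateInputError):
            cophenetic_correlation(upgma(D), D)


def pair_counting_ari(a, b):
    """Brute-force ARI over all unordered taxon pairs."""
    keys = sorted(a)
    same_a = same_b = both = 0
    npairs = 0
    for x, y in itertools.combinations(keys, 2):
        npairs += 1
        sa, sb = a[x] == a[y], b[x] == b[y]
        same_a += sa
        same_b += sb
        both += sa and sb
    expected = same_a * same_b / npairs
    max_index = (same_a + same_b) / 2
    if max_index == expected:
        return 1.0
    return (both - expected) / (max_index - expected)


class TestAdjustedRand:
    def test_identical_partitions(self):
        labels = {"a": 1, "b": 1, "c": 2, "d": 3}
        assert adjusted_rand(labels, labels) == pytest.approx(1.0)

    def test_single_cluster_versus_split_is_zero(self):
        a = {k: 1 for k in "abcdef"}
        b = {"a": 1, "b": 1, "c": 2, "d": 2, "e": 3, "f": 3}
        assert adjusted_rand(a, b) == pytest.approx(0.0)

    def test_six_taxon_example_matches_pair_counting_oracle(self):
        a = {"t1": 1, "t2": 1, "t3": 1, "t4": 2, "t5": 2, "t6": 3}
        b = {"t1": 1, "t2": 1, "t3": 2, "t4": 2, "t5": 3, "t6": 3}
        assert adjusted_rand(a, b) == pytest.approx(pair_counting_ari(a, b))

    def test_random_partitions_match_oracle(self):
        rng = np.random.default_rng(27)
        for _ in range(20):
            keys = [f"x{i}" for i in range(10)]
            a = {k: int(rng.integers(1, 4)) for k in keys}
            b = {k: int(rng.integers(1, 4)) for k in keys}
            if len(set(a.values())) == 1 and len(set(b.values())) == 1:
                continue
            assert adjusted_rand(a, b) == pytest.approx(pair_counting_ari(a, b))

    def test_mismatched_taxa_raise(self):
        with pytest.raises(InvalidArgumentError):
            adjusted_rand({"a": 1}, {"b": 1})


class TestExclusiveClades:
    def test_blocks_are_exclusive(self):
        den = upgma(block_matrix())
        assert groups_form_exclusive_clades(den, {"left": ["A", "B"], "right": ["C", "D"]}) == []

    def test_split_group_detected(self):
        den = upgma(block_matrix())
        assert groups_form_exclusive_clades(den, {"bad": ["A", "C"]}) == ["bad"]
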
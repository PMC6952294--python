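"""Clustering tests: dendrogram construction, slicing, k-medoids,
centroid designation, and dimension estimation on synthetic point sets."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from latticecluster import distance_matrix
from latticecluster.cluster import (
    ClusterAssignment,
    Dendrogram,
    designate_centroid,
    estimate_dimension,
    hierarchical,
    kmedoids,
    seeds_from_slice,
    slice_dendrogram,
)
from latticecluster.metrics import DistanceMatrix

from conftest import NAMES


def _dm_from_points(points, labels=None):
    d = cdist(points, points)
    labels = labels or [str(i) for i in range(len(points))]
    return DistanceMatrix(d, labels)


@pytest.fixture(scope="module")
def published_dm(primitive_cells):
    return distance_matrix([primitive_cells[n] for n in NAMES], "cs6dist", NAMES)


@pytest.fixture(scope="module")
def published_tree(published_dm):
    return hierarchical(published_dm, "average")


# ---------------------------------------------------------------------------
# dendrogram


def test_duplicate_lattices_merge_at_height_zero(published_tree):
    # 1DPY/1FE5 and 1G0Z/1U4J are identical lattices: the first two
    # merges happen at height ~0
    heights = np.sort(published_tree.heights)
    assert heights[0] == pytest.approx(0.0, abs=1e-6)
    assert heights[1] == pytest.approx(0.0, abs=1e-6)
    assert heights[2] > 0.05


def test_single_linkage_three_points_by_hand():
    # points on a line at 0, 1, 5: merges at 1 then 4
    dm = _dm_from_points(np.array([[0.0], [1.0], [5.0]]), ["p0", "p1", "p2"])
    dg = hierarchical(dm, "single")
    merges = dg.merges
    assert merges[0][2] == pytest.approx(1.0)
    assert {merges[0][0], merges[0][1]} == {0, 1}
    assert merges[1][2] == pytest.approx(4.0)


def test_average_linkage_three_points_by_hand():
    dm = _dm_from_points(np.array([[0.0], [1.0], [5.0]]))
    dg = hierarchical(dm, "average")
    # average of d(0,2)=5 and d(1,2)=4
    assert dg.merges[1][2] == pytest.approx(4.5)


def test_largest_gap_level_finds_the_gap():
    dm = _dm_from_points(np.array([[0.0], [1.0], [10.0], [11.0]]))
    dg = hierarchical(dm, "average")
    level = dg.largest_gap_level()
    # merges at 1, 1, 10: cut between 1 and 10
    assert 1.0 < level < 10.0
    assignment = slice_dendrogram(dg, level, dm)
    assert assignment.k == 2


def test_largest_gap_level_without_gap_gives_single_cluster():
    dm = _dm_from_points(np.array([[0.0], [1.0], [2.1], [3.0]]))
    dg = hierarchical(dm, "average")
    level = dg.largest_gap_level(min_gap=5.0)
    assert level > dg.heights.max()
    assert slice_dendrogram(dg, level, dm).k == 1


def test_newick_export(published_tree):
    nwk = published_tree.to_newick()
    assert nwk.endswith(";")
    assert nwk.count("(") == len(NAMES) - 1
    for name in NAMES:
        assert name in nwk


def test_dendrogram_rejects_bad_linkage_shapes():
    with pytest.raises(ValueError):
        Dendrogram(np.zeros((2, 4)), ["a", "b"])
    with pytest.raises(ValueError):
        # decreasing merge heights
        Dendrogram(np.array([[0, 1, 2.0, 2], [2, 3, 1.0, 3]]), ["a", "b", "c"])


# ---------------------------------------------------------------------------
# slicing


def test_slice_at_low_level_reproduces_duplicate_pairs(published_dm, published_tree):
    assignment = slice_dendrogram(published_tree, 0.01, published_dm)
    lab = dict(zip(NAMES, assignment.labels))
    assert lab["1DPY"] == lab["1FE5"]
    assert lab["1G0Z"] == lab["1U4J"]
    assert assignment.k == 4


def test_slice_at_one_angstrom_level_gives_two_chemistry_groups(
    published_dm, published_tree
):
    # the rhombohedral 57.98 pair versus the 57.0-57.1 family
    assignment = slice_dendrogram(published_tree, 1.0, published_dm)
    lab = dict(zip(NAMES, assignment.labels))
    assert assignment.k == 2
    assert lab["1DPY"] == lab["1FE5"]
    assert len({lab["1G0Z"], lab["1U4J"], lab["1G2X"], lab["2OSN"]}) == 1
    assert lab["1DPY"] != lab["1G0Z"]


def test_slices_are_nested(published_dm, published_tree):
    # a finer slice refines a coarser one
    fine = slice_dendrogram(published_tree, 0.2, published_dm).labels
    coarse = slice_dendrogram(published_tree, 1.0, published_dm).labels
    mapping = {}
    for f, c in zip(fine, coarse):
        assert mapping.setdefault(f, c) == c


def test_medoids_belong_to_their_clusters(published_dm, published_tree):
    assignment = slice_dendrogram(published_tree, 1.0, published_dm)
    for ci, m in enumerate(assignment.medoids):
        assert assignment.labels[m] == ci


def test_assignment_validation():
    with pytest.raises(ValueError):
        ClusterAssignment(np.array([0, 0, 2]), [0, 2], 0.0)
    with pytest.raises(ValueError):
        # medoid not in its own cluster
        ClusterAssignment(np.array([0, 1]), [1, 0], 0.0)


def test_assignment_tsv(published_dm, published_tree):
    assignment = slice_dendrogram(published_tree, 1.0, published_dm)
    lines = assignment.to_tsv().strip().splitlines()
    assert lines[0] == "id\tcluster\tis_medoid"
    assert len(lines) == 1 + len(NAMES)
    assert sum(line.endswith("\t1") for line in lines[1:]) == assignment.k


# ---------------------------------------------------------------------------
# k-medoids


def test_kmedoids_two_well_separated_blobs():
    rng = np.random.default_rng(3)
    pts = np.vstack([rng.normal(0, 0.5, (10, 2)), rng.normal(10, 0.5, (12, 2))])
    dm = _dm_from_points(pts)
    assignment = kmedoids(dm, 2)
    assert assignment.k == 2
    first = assignment.labels[:10]
    second = assignment.labels[10:]
    assert len(set(first)) == 1 and len(set(second)) == 1
    assert first[0] != second[0]


def test_kmedoids_k2_separates_the_two_lattice_families(published_dm):
    assignment = kmedoids(published_dm, 2, rng_seed=0)
    lab = dict(zip(NAMES, assignment.labels))
    assert lab["1DPY"] == lab["1FE5"]
    assert lab["1G0Z"] == lab["1U4J"] == lab["1G2X"] == lab["2OSN"]
    assert lab["1DPY"] != lab["1G0Z"]


def test_kmedoids_seeded_from_slice(published_dm, published_tree):
    seeds = seeds_from_slice(published_tree, 1.0, published_dm)
    assert len(seeds) == 2
    assignment = kmedoids(published_dm, 2, seeds=seeds)
    assert assignment.k == 2


def test_kmedoids_k_equals_n(published_dm):
    assignment = kmedoids(published_dm, published_dm.n)
    assert assignment.objective == pytest.approx(0.0, abs=1e-9)
    assert sorted(assignment.medoids) == list(range(published_dm.n))


def test_kmedoids_k1_is_global_medoid(published_dm):
    assignment = kmedoids(published_dm, 1)
    sums = published_dm.d.sum(axis=1)
    assert assignment.medoids == [int(np.argmin(sums))]


def test_kmedoids_objective_never_worse_with_more_restarts():
    rng = np.random.default_rng(8)
    pts = rng.normal(0, 1, (40, 3))
    dm = _dm_from_points(pts)
    few = kmedoids(dm, 4, restarts=1, rng_seed=5)
    many = kmedoids(dm, 4, restarts=20, rng_seed=5)
    assert many.objective <= few.objective + 1e-9


def test_kmedoids_rejects_bad_k(published_dm):
    with pytest.raises(ValueError):
        kmedoids(published_dm, 0)
    with pytest.raises(ValueError):
        kmedoids(published_dm, published_dm.n + 1)
    with pytest.raises(ValueError):
        kmedoids(published_dm, 2, seeds=[0])


# ---------------------------------------------------------------------------
# centroid designation


def test_designate_centroid_star_graph():
    # star graph metric: hub (index 0) at distance 1 to all leaves,
    # leaves pairwise 2 apart; the hub wins for any landmark pair
    # (landmark-leaf sums tie at 2, broken by lowest index)
    n = 8
    d = np.full((n, n), 2.0)
    d[0, :] = d[:, 0] = 1.0
    np.fill_diagonal(d, 0.0)
    dm = DistanceMatrix(d)
    for seed in range(10):
        assert designate_centroid(dm, n_dim=2, rng_seed=seed) == 0


def test_designate_centroid_with_all_landmarks_matches_min_sum():
    rng = np.random.default_rng(12)
    pts = rng.normal(0, 1, (15, 2))
    dm = _dm_from_points(pts)
    # n_dim = n-1 makes every other item a landmark: centroid == min-sum
    # medoid over all items except possibly the random start
    c = designate_centroid(dm, n_dim=dm.n - 1, rng_seed=0)
    sums = dm.d.sum(axis=1)
    assert c == int(np.argmin(sums))


def test_designate_centroid_validates_n_dim(published_dm):
    with pytest.raises(ValueError):
        designate_centroid(published_dm, 0)
    with pytest.raises(ValueError):
        designate_centroid(published_dm, published_dm.n)


# ---------------------------------------------------------------------------
# dimension estimation


@pytest.mark.parametrize("true_dim", [1, 2, 3])
def test_dimension_recovery_in_euclidean_point_clouds(true_dim):
    hits = 0
    replicates = 20
    for rep in range(replicates):
        rng = np.random.default_rng([true_dim, rep])
        pts = rng.uniform(0, 1, size=(500, true_dim))
        dm = _dm_from_points(pts)
        center = int(np.argmin(((pts - 0.5) ** 2).sum(axis=1)))
        est = estimate_dimension(dm, center)
        if abs(est.dimension - true_dim) <= 0.5:
            hits += 1
    assert hits >= 0.9 * replicates


def test_dimension_zero_for_coincident_points():
    dm = DistanceMatrix(np.zeros((12, 12)))
    est = estimate_dimension(dm, 0)
    assert est.dimension == 0.0


def test_dimension_requires_enough_items():
    dm = DistanceMatrix(np.zeros((4, 4)))
    with pytest.raises(ValueError):
        estimate_dimension(dm, 0)
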
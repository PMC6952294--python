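"""Reflection handling tests: merging statistics, completeness,
correlation coefficients, the CC distance matrix, and file I/O."""

import math

import numpy as np
import pytest

from latticecluster import UnitCell
from latticecluster.reflections import (
    ImageRecord,
    ReflectionSet,
    cc_distance_matrix,
    completeness,
    merge,
    pearson_cc,
    read_manifest,
    read_reflections,
    resolutions,
    spot_filter,
    unique_reflections,
    write_manifest,
    write_reflections,
)

CELL = UnitCell(20.0, 20.0, 20.0, 90.0, 90.0, 90.0)
D_MIN = 5.0


def _full_set(cell=CELL, d_min=D_MIN, seed=0, scale=1.0):
    hkl = unique_reflections(cell, d_min)
    rng = np.random.default_rng(seed)
    intensity = scale * rng.lognormal(2.0, 1.0, size=len(hkl))
    sigma = 0.1 * np.abs(intensity) + 0.01
    return ReflectionSet(hkl, intensity, sigma, cell, d_min)


# ---------------------------------------------------------------------------
# reflection enumeration and resolution


def test_unique_reflections_respects_resolution_limit():
    hkl = unique_reflections(CELL, D_MIN)
    assert len(hkl) > 0
    d = resolutions(CELL, hkl)
    assert (d >= D_MIN - 1e-9).all()
    # cubic a=20: (4,0,0) has d exactly 5, (5,0,0) has d=4 and is excluded
    keys = {tuple(h) for h in hkl}
    assert (4, 0, 0) in keys
    assert (5, 0, 0) not in keys


def test_unique_reflections_are_friedel_unique():
    keys = {tuple(h) for h in unique_reflections(CELL, D_MIN)}
    for h in keys:
        neg = (-h[0], -h[1], -h[2])
        assert neg not in keys
    assert (0, 0, 0) not in keys


def test_resolution_of_axial_reflection():
    d = resolutions(CELL, np.array([[2, 0, 0]]))
    assert d[0] == pytest.approx(10.0, rel=1e-9)


# ---------------------------------------------------------------------------
# validation


def test_reflection_set_rejects_duplicates_and_bad_sigma():
    hkl = np.array([[1, 0, 0], [1, 0, 0]])
    with pytest.raises(ValueError):
        ReflectionSet(hkl, [1.0, 2.0], [0.1, 0.1], CELL, D_MIN)
    with pytest.raises(ValueError):
        ReflectionSet([[1, 0, 0]], [1.0], [0.0], CELL, D_MIN)
    with pytest.raises(ValueError):
        # beyond the stated resolution limit
        ReflectionSet([[5, 0, 0]], [1.0], [0.1], CELL, D_MIN)


# ---------------------------------------------------------------------------
# spot filter


def test_spot_filter_partitions_by_count_and_indexability():
    imgs = [
        ImageRecord("a", 100, CELL),
        ImageRecord("b", 5, CELL),
        ImageRecord("c", 100, None),  # never indexed
    ]
    kept, discarded = spot_filter(imgs, min_spots=10)
    assert [i.id for i in kept] == ["a"]
    assert [i.id for i in discarded] == ["b", "c"]
    kept, discarded = spot_filter(imgs, min_spots=0)
    assert [i.id for i in kept] == ["a", "b"]


# ---------------------------------------------------------------------------
# merging


def test_merge_inverse_variance_closed_form():
    a = ReflectionSet([[1, 0, 0]], [10.0], [1.0], CELL, D_MIN)
    b = ReflectionSet([[1, 0, 0]], [20.0], [1.0], CELL, D_MIN)
    m = merge([a, b])
    assert m.intensity[0] == pytest.approx(15.0)
    assert m.sigma[0] == pytest.approx(1.0 / math.sqrt(2.0))


def test_merge_weights_by_precision():
    # a tighter sigma pulls the merged intensity toward its observation
    a = ReflectionSet([[1, 0, 0]], [10.0], [0.5], CELL, D_MIN)
    b = ReflectionSet([[1, 0, 0]], [20.0], [1.0], CELL, D_MIN)
    m = merge([a, b])
    expected = (10.0 / 0.25 + 20.0 / 1.0) / (1.0 / 0.25 + 1.0 / 1.0)
    assert m.intensity[0] == pytest.approx(expected)
    assert m.intensity[0] < 15.0


def test_merge_with_itself_halves_the_variance():
    rs = _full_set(seed=1)
    m = merge([rs, rs])
    np.testing.assert_allclose(m.intensity, rs.intensity[np.lexsort(
        (rs.hkl[:, 2], rs.hkl[:, 1], rs.hkl[:, 0]))], rtol=1e-9)
    np.testing.assert_allclose(
        np.sort(m.sigma), np.sort(rs.sigma) / math.sqrt(2.0), rtol=1e-9
    )


def test_merge_is_associative():
    sets = [_full_set(seed=s) for s in range(3)]
    left = merge([merge(sets[:2]), sets[2]])
    right = merge([sets[0], merge(sets[1:])])
    flat = merge(sets)
    for other in (left, right):
        np.testing.assert_array_equal(flat.hkl, other.hkl)
        np.testing.assert_allclose(flat.intensity, other.intensity, rtol=1e-9)
        np.testing.assert_allclose(flat.sigma, other.sigma, rtol=1e-9)


def test_merge_unions_disjoint_index_sets():
    hkl = unique_reflections(CELL, D_MIN)
    half = len(hkl) // 2
    a = ReflectionSet(hkl[:half], np.ones(half), np.ones(half), CELL, D_MIN)
    b = ReflectionSet(hkl[half:], np.ones(len(hkl) - half),
                      np.ones(len(hkl) - half), CELL, D_MIN)
    m = merge([a, b])
    assert len(m) == len(hkl)
    np.testing.assert_allclose(m.sigma, 1.0)  # unshared records keep their sigma


def test_merge_rejects_incompatible_cells():
    other_cell = UnitCell(40.0, 45.0, 50.0, 90.0, 90.0, 90.0)
    a = _full_set()
    b = ReflectionSet([[1, 0, 0]], [1.0], [0.1], other_cell, D_MIN)
    with pytest.raises(ValueError):
        merge([a, b], compatibility=2.0)
    # explicit opt-out skips the check
    m = merge([a, b], compatibility=None)
    assert len(m) == len(a)


# ---------------------------------------------------------------------------
# completeness


def test_completeness_full_sphere_is_one():
    assert completeness(_full_set(), D_MIN) == pytest.approx(1.0)


def test_completeness_empty_set_is_zero():
    rs = ReflectionSet(np.empty((0, 3), int), [], [], CELL, D_MIN)
    assert completeness(rs, D_MIN) == 0.0


def test_completeness_of_seeded_half_sample():
    hkl = unique_reflections(CELL, D_MIN)
    rng = np.random.default_rng(2)
    picked = rng.choice(len(hkl), size=len(hkl) // 2, replace=False)
    rs = ReflectionSet(hkl[picked], np.ones(len(picked)),
                       np.ones(len(picked)), CELL, D_MIN)
    assert completeness(rs, D_MIN) == pytest.approx(0.5, abs=0.02)


def test_completeness_monotone_under_merge():
    hkl = unique_reflections(CELL, D_MIN)
    third = len(hkl) // 3
    a = ReflectionSet(hkl[:third], np.ones(third), np.ones(third), CELL, D_MIN)
    b = ReflectionSet(hkl[third:2 * third], np.ones(third), np.ones(third),
                      CELL, D_MIN)
    ca = completeness(a, D_MIN)
    cm = completeness(merge([a, b]), D_MIN)
    assert cm >= ca
    assert cm == pytest.approx(ca + completeness(b, D_MIN), abs=1e-9)


# ---------------------------------------------------------------------------
# correlation


def test_pearson_cc_identical_sets():
    rs = _full_set(seed=3)
    cc, n = pearson_cc(rs, rs)
    assert cc == pytest.approx(1.0)
    assert n == len(rs)


def test_pearson_cc_negated_intensities():
    rs = _full_set(seed=3)
    neg = ReflectionSet(rs.hkl, -rs.intensity, rs.sigma, rs.cell, rs.d_min)
    cc, _ = pearson_cc(rs, neg)
    assert cc == pytest.approx(-1.0)


def test_pearson_cc_undefined_below_min_common():
    rs = _full_set(seed=3)
    small = ReflectionSet(rs.hkl[:5], rs.intensity[:5], rs.sigma[:5],
                          rs.cell, rs.d_min)
    cc, n = pearson_cc(rs, small, min_common=20)
    assert cc is None
    assert n == 5


def test_pearson_cc_undefined_for_constant_intensities():
    hkl = unique_reflections(CELL, D_MIN)[:30]
    const = ReflectionSet(hkl, np.ones(30), np.ones(30), CELL, D_MIN)
    varied = ReflectionSet(hkl, np.arange(1.0, 31.0), np.ones(30), CELL, D_MIN)
    cc, _ = pearson_cc(const, varied, min_common=20)
    assert cc is None


def test_cc_distance_matrix_extremes_and_flags():
    rs = _full_set(seed=3)
    neg = ReflectionSet(rs.hkl, -rs.intensity, rs.sigma, rs.cell, rs.d_min)
    tiny = ReflectionSet(rs.hkl[:5], rs.intensity[:5], rs.sigma[:5],
                         rs.cell, rs.d_min)
    dm, undefined = cc_distance_matrix([rs, rs, neg, tiny], min_common=20)
    assert dm.d[0, 1] == pytest.approx(0.0, abs=1e-6)       # identical
    assert dm.d[0, 2] == pytest.approx(math.sqrt(2.0))      # anti-correlated
    assert set(undefined) == {(0, 3), (1, 3), (2, 3)}
    # undefined pairs are filled with the maximum defined distance
    assert dm.d[0, 3] == pytest.approx(math.sqrt(2.0))


# ---------------------------------------------------------------------------
# file I/O


def test_reflection_file_round_trip(tmp_path):
    rs = _full_set(seed=4)
    path = tmp_path / "img.hkl"
    write_reflections(path, rs)
    back = read_reflections(path, rs.cell, rs.d_min)
    np.testing.assert_array_equal(np.sort(back.hkl, axis=0), np.sort(rs.hkl, axis=0))
    assert back.as_dict()[tuple(rs.hkl[0])][0] == pytest.approx(
        rs.intensity[0], rel=1e-6
    )


def test_manifest_round_trip(tmp_path):
    images = [
        ImageRecord("good", 100, CELL, _full_set(seed=5)),
        ImageRecord("weak", 4, CELL, None),
        ImageRecord("junk", 2, None, None),
    ]
    manifest = write_manifest(tmp_path / "manifest.csv", images, D_MIN)
    back = read_manifest(manifest)
    assert [img.id for img in back] == ["good", "weak", "junk"]
    assert back[0].cell is not None and back[0].reflections is not None
    assert len(back[0].reflections) == len(images[0].reflections)
    assert back[1].reflections is None and back[1].cell is not None
    assert back[2].cell is None
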
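"""Binarization, dependency vectors, KS comparison, global correlogram."""

import numpy as np
import pytest
from scipy import stats

from metalesion import (
    BinaryLesionStack,
    CohortStack,
    GreyMatterMask,
    binarize_lesion_stack,
    global_correlogram,
    ks_compare_magnitudes,
    local_dependency_field,
)
from metalesion.lesioncov import (
    DependencyVectorField,
    _NEIGHBOUR_OFFSETS,
    axis_decay_lengths,
    _canonicalize,
)


def stack_on_grid(data, grid):
    mask = GreyMatterMask(grid, np.eye(4), 1.0)
    ids = [f"s{i}" for i in range(data.shape[0])]
    return CohortStack(np.asarray(data, dtype=float), ids, mask)


def lesions_on_grid(binary, grid):
    mask = GreyMatterMask(grid, np.eye(4), 1.0)
    return BinaryLesionStack(np.asarray(binary, dtype=bool), mask)


def brute_force_field(lesions):
    """Direct per-voxel loop oracle for the dependency vector field."""
    mask = lesions.mask
    coords = mask.coordinates()
    index_of = {tuple(c): i for i, c in enumerate(coords)}
    vectors = np.full((mask.n_voxels, 3), np.nan)
    for v, c in enumerate(coords):
        at_v = lesions.data[:, v]
        if at_v.sum() == 0:
            continue
        vec = np.zeros(3)
        for off in _NEIGHBOUR_OFFSETS:
            u = tuple(c + off)
            if u in index_of:
                p = lesions.data[at_v, index_of[u]].mean()
            else:
                p = 0.0
            vec = vec + p * off
        vectors[v] = vec / 6.0
    return vectors


class TestBinarization:
    def test_worked_example_median_minus_two_sd(self):
        """Values [10,10,10,10,2]: median 10, sample SD ~3.578, threshold
        ~2.844 -> only the subject at 2 is lesioned."""
        grid = np.ones((1, 1, 1), dtype=bool)
        stack = stack_on_grid(np.array([[10.0], [10.0], [10.0], [10.0], [2.0]]), grid)
        lesions = binarize_lesion_stack(stack)
        assert np.array_equal(lesions.data.ravel(), [False, False, False, False, True])
        sd = np.std([10, 10, 10, 10, 2], ddof=1)
        assert sd == pytest.approx(3.5777, abs=1e-4)
        assert 10 - 2 * sd == pytest.approx(2.8446, abs=1e-4)

    def test_zero_variance_voxel_never_lesioned(self):
        grid = np.ones((1, 1, 2), dtype=bool)
        data = np.column_stack([np.full(5, 4.0), [1.0, 2, 3, 4, -50]])
        lesions = binarize_lesion_stack(stack_on_grid(data, grid))
        assert not lesions.data[:, 0].any()
        assert lesions.data[:, 1].any()

    def test_location_invariance(self):
        rng = np.random.default_rng(0)
        grid = np.ones((2, 2, 2), dtype=bool)
        data = rng.standard_normal((20, 8))
        a = binarize_lesion_stack(stack_on_grid(data, grid))
        b = binarize_lesion_stack(stack_on_grid(data + 17.3, grid))
        assert np.array_equal(a.data, b.data)

    def test_too_few_subjects_rejected(self):
        grid = np.ones((1, 1, 1), dtype=bool)
        with pytest.raises(ValueError, match="3 subjects"):
            binarize_lesion_stack(stack_on_grid(np.array([[1.0], [2.0]]), grid))


class TestLocalDependency:
    def test_single_plus_x_neighbour_gives_magnitude_one_sixth(self):
        grid = np.ones((3, 3, 3), dtype=bool)
        binary = np.zeros((4, 27), dtype=bool)
        centre = 13  # (1,1,1) in C order
        plus_x = 22  # (2,1,1)
        binary[:, centre] = True
        binary[:, plus_x] = True
        field = local_dependency_field(lesions_on_grid(binary, grid))
        assert np.allclose(field.vectors[centre], [1 / 6, 0, 0])
        assert field.magnitude[centre] == pytest.approx(1 / 6, abs=1e-12)

    def test_symmetric_neighbours_cancel(self):
        grid = np.ones((3, 3, 3), dtype=bool)
        binary = np.zeros((5, 27), dtype=bool)
        binary[:, :] = False
        # centre plus all six face neighbours lesioned in every subject
        centre_coord = np.array([1, 1, 1])
        idx = lambda c: int(np.ravel_multi_index(c, (3, 3, 3)))
        binary[:, idx(centre_coord)] = True
        for off in _NEIGHBOUR_OFFSETS:
            binary[:, idx(centre_coord + off)] = True
        field = local_dependency_field(lesions_on_grid(binary, grid))
        assert field.magnitude[idx(centre_coord)] == pytest.approx(0.0, abs=1e-12)

    def test_never_lesioned_voxel_flagged_undefined(self):
        grid = np.ones((2, 1, 1), dtype=bool)
        binary = np.array([[True, False], [True, False]])
        field = local_dependency_field(lesions_on_grid(binary, grid))
        assert field.defined[0] and not field.defined[1]
        assert np.isnan(field.magnitude[1])

    def test_matches_brute_force_oracle_and_bounded(self):
        rng = np.random.default_rng(1)
        grid = rng.random((4, 4, 4)) > 0.25
        grid[0, 0, 0] = True
        nvox = int(grid.sum())
        for trial in range(5):
            binary = rng.random((10, nvox)) > 0.6
            lesions = lesions_on_grid(binary, grid)
            field = local_dependency_field(lesions)
            oracle = brute_force_field(lesions)
            assert np.allclose(
                field.vectors[field.defined], oracle[field.defined], atol=1e-12
            )
            assert np.all(field.magnitude[field.defined] <= 1.0 + 1e-12)

    def test_reflection_negates_axis_component(self):
        rng = np.random.default_rng(2)
        grid = np.ones((4, 3, 3), dtype=bool)
        binary = rng.random((12, 36)) > 0.65
        lesions = lesions_on_grid(binary, grid)
        field = local_dependency_field(lesions)
        flipped_grid = grid[::-1].copy()
        full = np.zeros((12, 4, 3, 3), dtype=bool)
        full.reshape(12, -1)[:, lesions.mask.indices] = binary
        flipped = full[:, ::-1, :, :].reshape(12, -1)[
            :, GreyMatterMask(flipped_grid, np.eye(4), 1.0).indices
        ]
        field_f = local_dependency_field(
            lesions_on_grid(flipped, flipped_grid)
        )
        # voxel (i,j,k) maps to (3-i,j,k): x components negate, y/z preserved
        coords = lesions.mask.coordinates()
        remap = {tuple(c): i for i, c in enumerate(coords)}
        for v, c in enumerate(coords):
            w = remap[(3 - c[0], c[1], c[2])]
            if field.defined[v]:
                assert field_f.vectors[w, 0] == pytest.approx(-field.vectors[v, 0], abs=1e-12)
                assert field_f.vectors[w, 1] == pytest.approx(field.vectors[v, 1], abs=1e-12)


def field_from(magnitudes):
    m = np.asarray(magnitudes, dtype=float)
    return DependencyVectorField(
        vectors=np.zeros((len(m), 3)),
        magnitude=m,
        lesion_count=np.ones(len(m), dtype=int),
        defined=np.ones(len(m), dtype=bool),
        mask=None,
    )


class TestKS:
    def test_identical_samples_give_zero(self):
        d, p = ks_compare_magnitudes(field_from([0.1, 0.5, 0.9]), field_from([0.1, 0.5, 0.9]))
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_support_gives_one(self):
        d, _ = ks_compare_magnitudes(field_from([0.0, 0.0]), field_from([1.0, 1.0]))
        assert d == 1.0

    def test_small_sample_matches_exhaustive_ecdf_oracle(self):
        d, _ = ks_compare_magnitudes(field_from([0.1, 0.4, 0.7]), field_from([0.2, 0.5]))
        assert d == pytest.approx(1 / 3, abs=1e-12)

    def test_asymptotic_p_matches_scipy(self):
        rng = np.random.default_rng(3)
        a, b = rng.random(80), rng.random(60) ** 2
        d, p = ks_compare_magnitudes(field_from(a), field_from(b))
        ref = stats.ks_2samp(a, b, method="asymp")
        assert d == pytest.approx(ref.statistic, abs=1e-12)
        # p follows the plain asymptotic Kolmogorov law at effective n
        en = np.sqrt(len(a) * len(b) / (len(a) + len(b)))
        assert p == pytest.approx(stats.kstwobign.sf(en * d), rel=1e-9)
        # and agrees with scipy's finite-sample-corrected asymp to first order
        assert p == pytest.approx(ref.pvalue, rel=0.6)

    def test_empty_sample_rejected(self):
        empty = DependencyVectorField(
            vectors=np.zeros((1, 3)), magnitude=np.array([np.nan]),
            lesion_count=np.zeros(1, int), defined=np.zeros(1, bool), mask=None,
        )
        with pytest.raises(ValueError):
            ks_compare_magnitudes(empty, field_from([0.5]))


def brute_force_correlogram(lesions, max_offset):
    """O(V^2) oracle using np.corrcoef per pair."""
    coords = lesions.mask.coordinates()
    bins = {}
    skipped = 0
    nv = coords.shape[0]
    for i in range(nv):
        for j in range(i + 1, nv):
            d = coords[j] - coords[i]
            if np.abs(d).max() > max_offset:
                continue
            xi = lesions.data[:, i].astype(float)
            xj = lesions.data[:, j].astype(float)
            if xi.std() == 0 or xj.std() == 0:
                skipped += 1
                continue
            nz = np.flatnonzero(d)
            if len(nz) and d[nz[0]] < 0:
                d = -d
            bins.setdefault(tuple(d), []).append(np.corrcoef(xi, xj)[0, 1])
    return {k: np.median(v) for k, v in bins.items()}, {
        k: len(v) for k, v in bins.items()
    }, skipped


class TestGlobalCorrelogram:
    def test_identical_columns_have_rho_one(self):
        grid = np.ones((2, 1, 1), dtype=bool)
        binary = np.array([[1, 1], [0, 0], [1, 1], [0, 0]], dtype=bool)
        corr = global_correlogram(lesions_on_grid(binary, grid), max_offset_voxels=1)
        assert corr.median_rho[0] == pytest.approx(1.0)

    def test_single_pair_bin_matches_contingency_phi(self):
        grid = np.ones((2, 1, 1), dtype=bool)
        xi = np.array([1, 1, 0, 0, 1, 0], dtype=bool)
        xj = np.array([1, 0, 0, 0, 1, 1], dtype=bool)
        corr = global_correlogram(
            lesions_on_grid(np.column_stack([xi, xj]), grid), max_offset_voxels=1
        )
        n = 6
        n11 = (xi & xj).sum()
        phi = (n * n11 - xi.sum() * xj.sum()) / np.sqrt(
            xi.sum() * (n - xi.sum()) * xj.sum() * (n - xj.sum())
        )
        assert corr.median_rho[0] == pytest.approx(phi, abs=1e-12)
        assert corr.n_pairs[0] == 1

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        grid = rng.random((3, 3, 3)) > 0.3
        grid[1, 1, 1] = True
        binary = rng.random((15, int(grid.sum()))) > 0.55
        lesions = lesions_on_grid(binary, grid)
        corr = global_correlogram(lesions, max_offset_voxels=2)
        medians, counts, skipped = brute_force_correlogram(lesions, 2)
        assert corr.n_skipped == skipped
        assert corr.total_pairs() == sum(counts.values())
        got = {tuple(o): r for o, r in zip(corr.offsets, corr.median_rho)}
        assert set(got) == set(medians)
        for k in medians:
            assert got[k] == pytest.approx(medians[k], abs=1e-10)

    def test_independent_columns_median_near_zero(self):
        rng = np.random.default_rng(5)
        grid = np.ones((3, 3, 3), dtype=bool)
        binary = rng.random((4000, 27)) < 0.5
        corr = global_correlogram(lesions_on_grid(binary, grid), max_offset_voxels=2)
        assert np.abs(corr.median_rho).max() < 0.05

    def test_hemisphere_split_excludes_midline(self):
        grid = np.ones((3, 2, 2), dtype=bool)  # x = 1 is the midline
        rng = np.random.default_rng(6)
        binary = rng.random((20, 12)) > 0.5
        left = global_correlogram(lesions_on_grid(binary, grid), "left", 2)
        both = global_correlogram(lesions_on_grid(binary, grid), "both", 2)
        assert left.total_pairs() < both.total_pairs()

    def test_canonical_sign_convention(self):
        d = np.array([[-1, 2, 0], [0, -1, 3], [0, 0, -2], [1, -5, 0]])
        out = _canonicalize(d)
        assert np.array_equal(out, [[1, -2, 0], [0, 1, -3], [0, 0, 2], [1, -5, 0]])


def test_axis_decay_lengths_on_synthetic_bins():
    offsets = np.array([
        [1, 0, 0], [2, 0, 0], [3, 0, 0],
        [0, 1, 0], [0, 2, 0], [0, 3, 0],
        [0, 0, 1], [0, 0, 2],
    ])
    rho = np.array([0.8, 0.4, 0.1, 0.9, 0.7, 0.6, 0.2, 0.0])
    corr = type("C", (), {"offsets": offsets, "median_rho": rho})
    lengths = axis_decay_lengths(corr, level=0.5)
    assert lengths[0] == pytest.approx(1 + 0.3 / 0.4)  # interpolate 0.8 -> 0.4
    assert lengths[1] == pytest.approx(3.0)  # never decays in range
    # z: interpolate between (0, 1.0) and (1, 0.2): (1 - 0.5) / 0.8
    assert lengths[2] == pytest.approx(0.625)
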
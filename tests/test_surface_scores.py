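import numpy as np
import pytest

from emvolscore.surface_scores import (
    SurfaceExtractionError,
    SurfacePointSet,
    cd_gdt,
    chamfer_distance,
    exposure_filter,
    gradient_normals,
    normal_vector_score,
    surface_A,
    surface_M,
    surface_T,
)
from emvolscore.volume_io import DensityMap
from tests.conftest import contour_at


def mask_map(mask, spacing=1.0):
    return DensityMap(data=mask.astype(float), spacing=spacing)


def brute_force_surface_A(mask):
    """26-neighbourhood scan; outside the grid counts as background."""
    nz, ny, nx = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                for dz in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            if dz == dy == dx == 0:
                                continue
                            zz, yy, xx = z + dz, y + dy, x + dx
                            if not (0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx):
                                out[z, y, x] = True
                            elif not mask[zz, yy, xx]:
                                out[z, y, x] = True
    return out


def brute_force_exposure(mask, window):
    """Enumerate the three 1D windows per voxel, centre counted once."""
    nz, ny, nx = mask.shape
    h = window // 2
    out = np.zeros(mask.shape)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                total = 0.0
                for d in range(-h, h + 1):
                    if 0 <= x + d < nx:
                        total += mask[z, y, x + d]
                    if 0 <= y + d < ny:
                        total += mask[z, y + d, x]
                    if 0 <= z + d < nz:
                        total += mask[z + d, y, x]
                total -= 2.0 * mask[z, y, x]
                out[z, y, x] = total / (3 * window - 2)
    return out


def points(arr):
    return SurfacePointSet(np.asarray(arr, dtype=float), "T")


class TestSurfaceT:
    def test_band_matches_direct_inequality_scan(self, single_blob_map):
        thr = 0.5 * single_blob_map.data.max()
        c = contour_at(thr, sigma=1.0)
        surf = surface_T(single_blob_map, c)
        expected = np.argwhere(
            (single_blob_map.data >= thr - 0.1) & (single_blob_map.data <= thr + 0.1)
        )
        assert len(surf) == len(expected)
        np.testing.assert_array_equal(
            np.sort(surf.voxel_indices, axis=0), np.sort(expected, axis=0)
        )

    def test_band_outside_range_errors(self, single_blob_map):
        c = contour_at(10 * single_blob_map.data.max(), sigma=0.001)
        with pytest.raises(SurfaceExtractionError):
            surface_T(single_blob_map, c)

    def test_wide_band_selects_everything(self, single_blob_map):
        c = contour_at(0.0, sigma=1e6)
        surf = surface_T(single_blob_map, c)
        assert len(surf) == single_blob_map.data.size


class TestSurfaceA:
    def test_single_voxel_is_surface(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        surf = surface_A(mask_map(mask), contour_at(0.5))
        assert len(surf) == 1

    def test_cube_3_has_26_surface_voxels(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[1:4, 1:4, 1:4] = True
        surf = surface_A(mask_map(mask), contour_at(0.5))
        assert len(surf) == 26

    def test_cube_10_surface_count(self):
        mask = np.zeros((12, 12, 12), dtype=bool)
        mask[1:11, 1:11, 1:11] = True
        surf = surface_A(mask_map(mask), contour_at(0.5))
        assert len(surf) == 10**3 - 8**3

    def test_boundary_voxels_count_outside_as_background(self):
        mask = np.ones((4, 4, 4), dtype=bool)  # solid block filling the grid
        surf = surface_A(mask_map(mask), contour_at(0.5))
        assert len(surf) == 4**3 - 2**3

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(4, 17, size=3))
        mask = rng.random(shape) < 0.4
        if not mask.any():
            mask[0, 0, 0] = True
        surf = surface_A(mask_map(mask), contour_at(0.5))
        expected = brute_force_surface_A(mask)
        got = np.zeros(shape, dtype=bool)
        got[tuple(surf.voxel_indices.T)] = True
        np.testing.assert_array_equal(got, expected)


class TestExposure:
    def test_deep_interior_is_one(self):
        mask = np.ones((31, 31, 31), dtype=bool)
        f = exposure_filter(mask_map(mask), contour_at(0.5), window=21)
        assert f.values[15, 15, 15] == pytest.approx(1.0)

    def test_isolated_voxel_value(self):
        mask = np.zeros((25, 25, 25), dtype=bool)
        mask[12, 12, 12] = True
        f = exposure_filter(mask_map(mask), contour_at(0.5), window=21)
        assert f.values[12, 12, 12] == pytest.approx(1 / 61)

    def test_half_space_face_value_from_enumeration(self):
        # voxel on the flat face of a half space: 11 in-mask samples along
        # the normal axis, 21 along each tangent axis, centre counted once
        mask = np.zeros((31, 31, 31), dtype=bool)
        mask[:, :, :16] = True
        f = exposure_filter(mask_map(mask), contour_at(0.5), window=21)
        assert f.values[15, 15, 15] == pytest.approx((11 + 21 + 21 - 2) / 61)

    @pytest.mark.parametrize("window", [5, 9])
    def test_matches_brute_force_enumeration(self, window, rng):
        mask = rng.random((10, 11, 12)) < 0.5
        f = exposure_filter(mask_map(mask), contour_at(0.5), window=window)
        np.testing.assert_allclose(
            f.values, brute_force_exposure(mask, window), atol=1e-12
        )

    def test_bounded_and_monotone_under_mask_shrinkage(self, rng):
        mask = rng.random((12, 12, 12)) < 0.6
        sub = mask & (rng.random((12, 12, 12)) < 0.7)
        f_full = exposure_filter(mask_map(mask), contour_at(0.5), window=7)
        f_sub = exposure_filter(mask_map(sub), contour_at(0.5), window=7)
        assert f_full.values.min() >= 0 and f_full.values.max() <= 1
        both = sub
        assert np.all(f_sub.values[both] <= f_full.values[both] + 1e-12)


class TestSurfaceM:
    def test_isolated_voxel_selected(self):
        mask = np.zeros((25, 25, 25), dtype=bool)
        mask[12, 12, 12] = True
        surf = surface_M(mask_map(mask), contour_at(0.5))
        assert len(surf) == 1

    def test_bulky_solid_has_no_points_below_cutoff(self):
        m = mask_map(np.ones((30, 30, 30), dtype=bool))
        with pytest.raises(SurfaceExtractionError):
            surface_M(m, contour_at(0.5))

    def test_blob_surface_shell_nonempty(self, single_blob_map):
        c = contour_at(0.5 * single_blob_map.data.max())
        surf = surface_M(single_blob_map, c)
        assert 0 < len(surf) < single_blob_map.data.size


class TestChamfer:
    def test_identical_sets_zero(self, rng):
        pts = points(rng.random((30, 3)) * 10)
        assert chamfer_distance(pts, pts) == 0.0

    def test_single_points(self):
        assert chamfer_distance(points([[0, 0, 0]]), points([[3, 4, 0]])) == 5.0

    def test_matches_brute_force(self, rng):
        a = points(rng.random((50, 3)) * 20)
        b = points(rng.random((50, 3)) * 20)
        brute = np.mean(
            [min(np.linalg.norm(p - q) for q in b.points) for p in a.points]
        )
        assert chamfer_distance(a, b) == pytest.approx(brute, abs=1e-9)

    def test_symmetric_option_averages_directions(self, rng):
        a = points(rng.random((20, 3)) * 20)
        b = points(rng.random((35, 3)) * 20)
        sym = chamfer_distance(a, b, symmetric=True)
        assert sym == pytest.approx(
            0.5 * (chamfer_distance(a, b) + chamfer_distance(b, a))
        )

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            chamfer_distance(points(np.empty((0, 3))), points([[0, 0, 0]]))


class TestCdGdt:
    def test_all_within_first_bin_scores_one(self):
        a = points([[0, 0, 0], [1, 0, 0]])
        b = points([[0.1, 0, 0], [1.1, 0, 0]])
        assert cd_gdt(a, b) == pytest.approx(1.0)

    def test_all_beyond_dmax_scores_zero(self):
        a = points([[0, 0, 0]])
        b = points([[100, 0, 0]])
        assert cd_gdt(a, b) == 0.0

    def test_half_near_half_far_scores_half(self):
        a = points([[0, 0, 0], [50, 0, 0]])
        b = points([[0.5, 0, 0], [81, 0, 0]])  # distances 0.5 and 31
        assert cd_gdt(a, b) == pytest.approx(0.5)

    def test_matches_brute_force_weighted_sum(self, rng):
        a = points(rng.random((100, 3)) * 40)
        b = points(rng.random((100, 3)) * 40)
        d = np.array(
            [min(np.linalg.norm(p - q) for q in b.points) for p in a.points]
        )
        k, dmax = 30, 30.0
        total = 0.0
        for i in range(1, k + 1):
            total += (k - i + 1) * np.mean(d <= i * dmax / k)
        expected = total / (k * (k + 1) / 2)
        assert cd_gdt(a, b) == pytest.approx(expected, abs=1e-9)

    def test_monotone_as_a_distance_grows(self):
        base = points([[0, 0, 0], [10, 0, 0]])
        scores = [
            cd_gdt(base, points([[0, 0, 0], [10 + d, 0, 0]]))
            for d in (0.0, 3.0, 8.0, 15.0, 40.0)
        ]
        assert all(a >= b for a, b in zip(scores, scores[1:]))


class TestNormals:
    def test_linear_ramp_normals_along_x(self):
        nz = ny = nx = 6
        iz, iy, ix = np.meshgrid(
            np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
        )
        m = DensityMap(data=ix.astype(float), spacing=1.0)
        idx = np.array([[2, 2, 2], [3, 3, 3]])
        pts = SurfacePointSet(idx[:, ::-1].astype(float), "A", voxel_indices=idx)
        out = gradient_normals(m, pts)
        np.testing.assert_allclose(out.normals, [[1, 0, 0], [1, 0, 0]], atol=1e-12)

    def test_spherical_blob_normals_radial(self, single_blob_map):
        c = contour_at(0.5 * single_blob_map.data.max())
        surf = surface_A(single_blob_map, c)
        out = gradient_normals(single_blob_map, surf)
        center = np.array([31.0, 31.0, 31.0])
        radial = center - out.points
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        ang = np.degrees(
            np.arccos(np.clip(np.sum(out.normals * radial, axis=1), -1, 1))
        )
        assert np.all(ang < 5.0)

    def test_constant_map_errors(self):
        m = DensityMap(data=np.ones((5, 5, 5)), spacing=1.0)
        idx = np.array([[2, 2, 2]])
        pts = SurfacePointSet(idx[:, ::-1].astype(float), "A", voxel_indices=idx)
        with pytest.raises(ValueError):
            gradient_normals(m, pts)


class TestNormalVectorScore:
    def test_self_comparison_zero(self, single_blob_map):
        c = contour_at(0.5 * single_blob_map.data.max())
        surf = surface_A(single_blob_map, c)
        score = normal_vector_score(single_blob_map, single_blob_map, surf)
        assert score == pytest.approx(0.0, abs=1e-6)

    def test_negated_map_scores_one(self, single_blob_map):
        c = contour_at(0.5 * single_blob_map.data.max())
        surf = surface_A(single_blob_map, c)
        neg = single_blob_map.copy_with(-single_blob_map.data)
        assert normal_vector_score(single_blob_map, neg, surf) == pytest.approx(1.0)

    def test_perpendicular_ramps_score_half(self):
        n = 6
        iz, iy, ix = np.meshgrid(
            np.arange(n), np.arange(n), np.arange(n), indexing="ij"
        )
        mx = DensityMap(data=ix.astype(float), spacing=1.0)
        my = DensityMap(data=iy.astype(float), spacing=1.0)
        idx = np.array([[2, 2, 2], [3, 2, 1]])
        pts = SurfacePointSet(idx[:, ::-1].astype(float), "T", voxel_indices=idx)
        assert normal_vector_score(mx, my, pts) == pytest.approx(0.5)


class TestExports:
    def test_csv_and_pdb_written(self, tmp_path, single_blob_map):
        c = contour_at(0.5 * single_blob_map.data.max())
        surf = gradient_normals(single_blob_map, surface_A(single_blob_map, c))
        csv = tmp_path / "s.csv"
        pdb = tmp_path / "s.pdb"
        surf.to_csv(csv)
        surf.to_pdb(pdb)
        assert csv.read_text().startswith("x,y,z,nx,ny,nz")
        assert "HETATM" in pdb.read_text()
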
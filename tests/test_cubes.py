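import numpy as np
import pytest

from sbemkit import cubes
from sbemkit.cubes import (CacheState, CubeAddress, CubeStore, LocalSource,
                           NeighborhoodSpec, StackGeometry, build_cubes,
                           build_pyramid, cubes_in_neighborhood,
                           load_neighborhood, read_subvolume, reslice_plane)
from sbemkit.errors import FetchError, ParameterError


def _random_volume(dims_xyz, seed=0):
    nx, ny, nz = dims_xyz
    rng = np.random.default_rng(seed)
    return rng.integers(0, 256, (nz, ny, nx)).astype(np.uint8)


def brute_force_neighborhood(geometry, spec):
    """Every cube whose box intersects the extent box, by triple loop."""
    out = set()
    e = geometry.cube_edge
    ext = spec.extent3()
    for level in sorted(set(spec.levels)):
        gx, gy, gz = geometry.cube_grid(level)
        f = [v / 2 ** level for v in spec.focal_point]
        for cz in range(gz):
            for cy in range(gy):
                for cx in range(gx):
                    lo = (cx * e, cy * e, cz * e)
                    hi = ((cx + 1) * e, (cy + 1) * e, (cz + 1) * e)
                    if all(lo[i] < f[i] + ext[i] / 2 and
                           hi[i] > f[i] - ext[i] / 2 for i in range(3)):
                        out.add(CubeAddress(cx, cy, cz, level))
    return out


class TestBuildAndRead:
    @pytest.mark.parametrize("dims,edge", [
        ((64, 64, 64), 64),      # single padded cube
        ((110, 90, 70), 32),     # partial boundary cubes
        ((45, 33, 21), 16),      # odd sizes, small edge
    ])
    def test_round_trip_bit_exact(self, tmp_path, dims, edge):
        vol = _random_volume(dims, seed=dims[0])
        geom = StackGeometry(dimensions=dims, cube_edge=edge)
        store = build_cubes(vol, geom, tmp_path / "store")
        assert np.array_equal(store.read_level(0), vol)

    def test_cube_file_count(self, tmp_path):
        dims, edge = (70, 70, 70), 32   # ceil(70/32) = 3 per axis
        store = build_cubes(_random_volume(dims), StackGeometry(dims, cube_edge=edge),
                            tmp_path / "store")
        files = list((tmp_path / "store").rglob("cube.raw"))
        assert len(files) == 27

    def test_section_stream_input(self, tmp_path):
        vol = _random_volume((40, 30, 20), seed=1)
        geom = StackGeometry((40, 30, 20), cube_edge=16)
        store = build_cubes((vol[z] for z in range(20)), geom, tmp_path / "s")
        assert np.array_equal(store.read_level(0), vol)

    def test_inconsistent_section_named_in_error(self, tmp_path):
        vol = _random_volume((32, 32, 4), seed=2)
        sections = [vol[0], vol[1], vol[2][:16], vol[3]]
        with pytest.raises(ParameterError, match="section 2"):
            build_cubes(iter(sections), StackGeometry((32, 32, 4), cube_edge=16),
                        tmp_path / "s")

    def test_non_uint8_rejected(self, tmp_path):
        vol = np.zeros((8, 8, 8), dtype=np.uint16)
        with pytest.raises(ParameterError):
            build_cubes(vol, StackGeometry((8, 8, 8), cube_edge=8), tmp_path / "s")

    def test_subvolume_spanning_cubes(self, tmp_path):
        vol = _random_volume((96, 96, 96), seed=3)
        store = build_cubes(vol, StackGeometry((96, 96, 96), cube_edge=32),
                            tmp_path / "s")
        sub = read_subvolume(store, (16, 16, 16), (48, 48, 48))
        assert np.array_equal(sub, vol[16:64, 16:64, 16:64])

    def test_out_of_stack_fill_and_flag(self, tmp_path):
        vol = _random_volume((32, 32, 32), seed=4)
        store = build_cubes(vol, StackGeometry((32, 32, 32), cube_edge=32),
                            tmp_path / "s")
        with pytest.warns(UserWarning):
            sub = read_subvolume(store, (100, 100, 100), (8, 8, 8))
        assert not sub.any()
        # partially outside: inside part exact, outside zero
        sub = read_subvolume(store, (24, 24, 24), (16, 16, 16))
        assert np.array_equal(sub[:8, :8, :8], vol[24:, 24:, 24:])
        assert not sub[8:].any()

    def test_nonexistent_level_errors(self, tmp_path):
        store = build_cubes(_random_volume((16, 16, 16)),
                            StackGeometry((16, 16, 16), cube_edge=16),
                            tmp_path / "s")
        with pytest.raises(ParameterError):
            read_subvolume(store, (0, 0, 0), (4, 4, 4), level=1)

    def test_conf_round_trip(self, tmp_path):
        geom = StackGeometry((48, 32, 16), voxel_size=(9.25, 9.25, 25.0),
                             cube_edge=16, name="demo")
        build_cubes(_random_volume((48, 32, 16)), geom, tmp_path / "s")
        reopened = CubeStore.open(tmp_path / "s")
        assert reopened.geometry == geom

    def test_default_cube_edge_is_128(self):
        assert StackGeometry((256, 256, 256)).cube_edge == 128


class TestPyramid:
    def test_constant_volume_stays_constant(self, tmp_path):
        vol = np.full((32, 32, 32), 77, dtype=np.uint8)
        store = build_cubes(vol, StackGeometry((32, 32, 32), cube_edge=16),
                            tmp_path / "s")
        build_pyramid(store, 3)
        for level in (1, 2):
            assert np.all(store.read_level(level) == 77)

    def test_checkerboard_averages_to_128(self, tmp_path):
        z, y, x = np.indices((32, 32, 32))
        vol = (((x + y + z) % 2) * 255).astype(np.uint8)
        store = build_cubes(vol, StackGeometry((32, 32, 32), cube_edge=16),
                            tmp_path / "s")
        build_pyramid(store, 2)
        lvl1 = store.read_level(1)
        # 8-voxel blocks hold four 0s and four 255s: mean 127.5, rounds to 128
        assert np.all(lvl1 == 128)

    def test_level_dimension_sequence(self):
        geom = StackGeometry((300, 300, 300), n_levels=4)
        assert [geom.level_dims(l)[0] for l in range(4)] == [300, 150, 75, 38]

    def test_pyramid_round_trip_values(self, tmp_path):
        vol = _random_volume((64, 48, 32), seed=5)
        store = build_cubes(vol, StackGeometry((64, 48, 32), cube_edge=16),
                            tmp_path / "s")
        build_pyramid(store, 2)
        lvl1 = store.read_level(1)
        # independent mean-pool oracle
        pooled = vol.astype(float).reshape(16, 2, 24, 2, 32, 2).mean(axis=(1, 3, 5))
        assert np.array_equal(lvl1, np.floor(pooled + 0.5).astype(np.uint8))

    def test_too_many_levels_errors(self, tmp_path):
        store = build_cubes(_random_volume((16, 16, 16)),
                            StackGeometry((16, 16, 16), cube_edge=16),
                            tmp_path / "s")
        with pytest.raises(ParameterError):
            build_pyramid(store, 10)


class TestNeighborhood:
    @pytest.mark.parametrize("focal,extent,levels", [
        ((64, 48, 32), 40, (0,)),
        ((0, 0, 0), 320, (0,)),
        ((150, 150, 150), 576, (0, 1, 2)),
        ((299, 299, 299), 448, (0, 1, 2)),
        ((64, 48, 32), (48, 96, 32), (0, 1)),
    ])
    def test_resident_set_equals_brute_force(self, tmp_path, focal, extent, levels):
        geom = StackGeometry((300, 300, 300), cube_edge=64, n_levels=3)
        spec = NeighborhoodSpec(focal, extent, levels)
        assert set(cubes_in_neighborhood(geom, spec)) == \
            brute_force_neighborhood(geom, spec)

    def test_focal_at_cube_center_single_cube(self):
        geom = StackGeometry((256, 256, 256), cube_edge=128)
        spec = NeighborhoodSpec((64, 64, 64), extent=64, levels=(0,))
        assert cubes_in_neighborhood(geom, spec) == [CubeAddress(0, 0, 0, 0)]

    def _store_and_cache(self, tmp_path, budget_cubes=100):
        vol = _random_volume((128, 96, 64), seed=6)
        geom = StackGeometry((128, 96, 64), cube_edge=32)
        build_cubes(vol, geom, tmp_path / "src")
        source = LocalSource(tmp_path / "src")
        cache = CacheState(disk_cache_root=tmp_path / "cache",
                           memory_budget=budget_cubes * 32 ** 3, source=source)
        return geom, source, cache

    def test_second_call_hits_cache(self, tmp_path):
        geom, source, cache = self._store_and_cache(tmp_path)
        spec = NeighborhoodSpec((64, 48, 32), extent=48, levels=(0,))
        load_neighborhood(geom, spec, cache)
        n = source.fetch_count
        assert n > 0
        load_neighborhood(geom, spec, cache)
        assert source.fetch_count == n

    def test_lru_eviction_respects_budget(self, tmp_path):
        geom, source, cache = self._store_and_cache(tmp_path, budget_cubes=3)
        spec = NeighborhoodSpec((64, 48, 32), extent=96, levels=(0,))
        load_neighborhood(geom, spec, cache)
        assert cache.memory_used <= cache.memory_budget
        assert len(cache.resident_cubes) == 3
        # disk copies persist beyond eviction
        assert len(list((tmp_path / "cache").rglob("cube.raw"))) > 3

    def test_missing_cube_raises_fetch_error(self, tmp_path):
        geom = StackGeometry((128, 96, 64), cube_edge=32)
        source = LocalSource(tmp_path / "empty")
        cache = CacheState(tmp_path / "cache2", 10 * 32 ** 3, source=source)
        with pytest.raises(FetchError):
            load_neighborhood(geom, NeighborhoodSpec((64, 48, 32), 48, (0,)),
                              cache)


class TestReslice:
    @pytest.fixture()
    def linear_store(self, tmp_path):
        # value = x + 2y + 3z fits uint8 for these dims and is trilinear
        nx, ny, nz = 40, 30, 20
        z, y, x = np.indices((nz, ny, nx))
        vol = (x + 2 * y + 3 * z).astype(np.uint8)
        geom = StackGeometry((nx, ny, nz), voxel_size=(9.25, 9.25, 25.0),
                             cube_edge=16)
        return build_cubes(vol, geom, tmp_path / "lin"), vol

    def test_axis_aligned_identity(self, tmp_path):
        vol = _random_volume((40, 30, 20), seed=7)
        geom = StackGeometry((40, 30, 20), voxel_size=(9.25, 9.25, 25.0),
                             cube_edge=16)
        store = build_cubes(vol, geom, tmp_path / "s")
        zi = 7
        center = ((40 - 1) / 2 * 9.25, (30 - 1) / 2 * 9.25, zi * 25.0)
        img = reslice_plane(store, center, (1, 0, 0), (0, 1, 0),
                            (40, 30), pixel_pitch=9.25)
        assert np.array_equal(img, vol[zi].T)

    def test_oblique_matches_analytic_linear_field(self, linear_store):
        store, _ = linear_store
        vox = np.array([9.25, 9.25, 25.0])
        u = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        v = np.array([-1.0, 1.0, 2.0]) / np.sqrt(6)
        center = np.array([18.0, 14.0, 9.0]) * vox
        ni, nj, pitch = 15, 15, 20.0
        img = reslice_plane(store, center, u, v, (ni, nj), pitch)
        ii, jj = np.meshgrid(np.arange(ni), np.arange(nj), indexing="ij")
        pts = (center + (ii - (ni - 1) / 2)[..., None] * pitch * u
               + (jj - (nj - 1) / 2)[..., None] * pitch * v)
        coords = pts / vox
        analytic = coords[..., 0] + 2 * coords[..., 1] + 3 * coords[..., 2]
        inside = np.all((coords >= 0) & (coords <= [39, 29, 19]), axis=-1)
        assert inside.sum() > 50
        assert np.allclose(img[inside], analytic[inside], atol=1e-6)

    def test_plane_outside_stack_is_zero(self, linear_store):
        store, _ = linear_store
        img = reslice_plane(store, (1e6, 1e6, 1e6), (1, 0, 0), (0, 1, 0),
                            (8, 8), pixel_pitch=9.25)
        assert not img.any()

    def test_rotation_consistency(self, tmp_path):
        # isotropic voxels so a 90-degree in-plane rotation is exact
        vol = _random_volume((24, 24, 24), seed=8)
        geom = StackGeometry((24, 24, 24), voxel_size=(10.0, 10.0, 10.0),
                             cube_edge=8)
        store = build_cubes(vol, geom, tmp_path / "iso")
        center = ((24 - 1) / 2 * 10.0,) * 3
        a = reslice_plane(store, center, (1, 0, 0), (0, 1, 0), (24, 24), 10.0)
        b = reslice_plane(store, center, (0, 1, 0), (-1, 0, 0), (24, 24), 10.0)
        # the 90-degree rotated basis samples the same plane, transposed
        # and flipped: b[i, j] == a[n-1-j, i]
        assert np.allclose(b, a[::-1, :].T, atol=1e-6)

    def test_non_orthonormal_basis_rejected(self, linear_store):
        store, _ = linear_store
        with pytest.raises(ParameterError):
            reslice_plane(store, (0, 0, 0), (1, 0, 0), (1, 1, 0), (4, 4), 9.25)
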
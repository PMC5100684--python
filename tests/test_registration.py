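import numpy as np
import pytest

from conftest import spatial_ncc_offset
from sbemkit import registration, simulate
from sbemkit.errors import (DisconnectedGraphError, NoSignalError,
                            ParameterError)
from sbemkit.registration import (ContrastModel, OffsetEstimate, Tile,
                                  estimate_offset, fit_contrast,
                                  normalize_contrast, solve_layout,
                                  standardize, stitch)


class TestStandardize:
    def test_rows_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        out = standardize(rng.uniform(0, 65535, (64, 64)))
        assert np.all(np.abs(out.mean(axis=1)) < 1e-6)
        assert np.all(np.abs(out.std(axis=1) - 1) < 1e-6)

    def test_constant_image_gives_zeros_with_warning(self):
        with pytest.warns(UserWarning):
            out = standardize(np.full((16, 16), 42.0))
        assert np.all(out == 0)

    def test_restandardization_keeps_row_moments(self):
        rng = np.random.default_rng(1)
        once = standardize(rng.normal(size=(32, 48)))
        twice = standardize(once)
        assert np.all(np.abs(twice.mean(axis=1)) < 1e-6)
        assert np.all(np.abs(twice.std(axis=1) - 1) < 1e-6)

    def test_too_small_image_errors(self):
        with pytest.raises(ParameterError):
            standardize(np.ones((1, 10)))


class TestEstimateOffset:
    def test_identical_images_give_zero(self, small_texture):
        tile = small_texture[:256, :256]
        est = estimate_offset(tile, tile, max_offset=32)
        assert (est.dx, est.dy) == (0, 0)

    def test_recovers_worked_example_displacement(self, worked_example_texture):
        # 1024x1024 tile pair displaced by (69, 66), zero noise
        a, b, _ = simulate.gen_tile_pair(worked_example_texture, (69, 66), 1024)
        est = estimate_offset(a, b, max_offset=256)
        assert (est.dx, est.dy) == (69, 66)
        assert est.peak_score == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_noisy_random_offsets_recovered(self, worked_example_texture, seed):
        rng = np.random.default_rng(seed)
        dx, dy = (int(v) for v in rng.integers(-100, 101, 2))
        a, b, _ = simulate.gen_tile_pair(worked_example_texture, (dx, dy),
                                         384, noise_sd=0.05, seed=seed)
        est = estimate_offset(a, b, max_offset=128)
        assert (est.dx, est.dy) == (dx, dy)

    @pytest.mark.parametrize("dx,dy", [(5, -3), (-11, 7), (0, 14)])
    def test_matches_spatial_oracle(self, dx, dy):
        tex = simulate.gen_texture(simulate.TextureSpec(128, 128, 2.0, seed=3))
        a, b, _ = simulate.gen_tile_pair(tex, (dx, dy), 96, noise_sd=0.03,
                                         seed=abs(dx) + 100 * abs(dy))
        est = estimate_offset(a, b, max_offset=16)
        assert (est.dx, est.dy) == spatial_ncc_offset(a, b, 16)

    def test_translation_covariance(self, small_texture):
        a, b, _ = simulate.gen_tile_pair(small_texture, (10, 4), 192)
        base = estimate_offset(a, b, max_offset=48)
        a2, b2, _ = simulate.gen_tile_pair(small_texture, (10 + 7, 4 - 5), 192)
        shifted = estimate_offset(a2, b2, max_offset=48)
        assert (shifted.dx - base.dx, shifted.dy - base.dy) == (7, -5)

    def test_constant_image_raises_no_signal(self):
        flat = np.full((64, 64), 7.0)
        with pytest.raises(NoSignalError):
            estimate_offset(flat, flat, max_offset=8)

    def test_shape_mismatch_and_window_validation(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(64, 64))
        with pytest.raises(ParameterError):
            estimate_offset(img, img[:32], max_offset=8)
        with pytest.raises(ParameterError):
            estimate_offset(img, img, max_offset=64)


def _bfs_layout_oracle(offsets, n_tiles, anchor=0):
    """Accumulate offsets along a BFS spanning tree (valid when the
    pairwise offsets are mutually consistent)."""
    adj = {}
    for o in offsets:
        i, j = o.pair
        adj.setdefault(i, []).append((j, (o.dx, o.dy)))
        adj.setdefault(j, []).append((i, (-o.dx, -o.dy)))
    pos = {anchor: (0.0, 0.0)}
    queue = [anchor]
    while queue:
        i = queue.pop(0)
        for j, (dx, dy) in adj.get(i, []):
            if j not in pos:
                pos[j] = (pos[i][0] + dx, pos[i][1] + dy)
                queue.append(j)
    return pos


class TestSolveLayout:
    def test_single_tile(self):
        layout = solve_layout([], n_tiles=1, anchor=0)
        assert layout.positions[0] == (0.0, 0.0)

    def test_exact_grid_matches_bfs_oracle(self):
        grid = simulate.gen_tile_grid(3, 3, 128, overlap_fraction=0.06,
                                      jitter=2, seed=5)
        pos = grid.true_positions
        offsets = []
        for r in range(3):
            for c in range(3):
                i = r * 3 + c
                for rr, cc in ((r, c + 1), (r + 1, c)):
                    if rr > 2 or cc > 2:
                        continue
                    j = rr * 3 + cc
                    offsets.append(OffsetEstimate(pos[j][0] - pos[i][0],
                                                  pos[j][1] - pos[i][1],
                                                  1.0, (i, j)))
        layout = solve_layout(offsets, 9, anchor=0)
        oracle = _bfs_layout_oracle(offsets, 9)
        for i in range(9):
            assert layout.positions[i] == pytest.approx(oracle[i], abs=1e-6)
            assert layout.residuals == pytest.approx(
                {k: 0.0 for k in layout.residuals}, abs=1e-6)

    def test_perturbed_pair_matches_normal_equations(self):
        # 2x2 grid, one offset perturbed by (4, 0)
        true = {0: (0, 0), 1: (100, 0), 2: (0, 100), 3: (100, 100)}
        pairs = [(0, 1), (0, 2), (1, 3), (2, 3)]
        offsets = []
        for k, (i, j) in enumerate(pairs):
            dx = true[j][0] - true[i][0] + (4 if k == 0 else 0)
            dy = true[j][1] - true[i][1]
            offsets.append(OffsetEstimate(dx, dy, 1.0, (i, j)))
        layout = solve_layout(offsets, 4, anchor=0)
        # dense normal-equations oracle with anchor row
        rows = []
        bx, by = [], []
        for o in offsets:
            row = np.zeros(4)
            row[o.pair[1]], row[o.pair[0]] = 1, -1
            rows.append(row)
            bx.append(o.dx)
            by.append(o.dy)
        anchor_row = np.zeros(4)
        anchor_row[0] = 1
        rows.append(anchor_row)
        bx.append(0)
        by.append(0)
        A = np.array(rows)
        px = np.linalg.solve(A.T @ A, A.T @ np.array(bx, float))
        py = np.linalg.solve(A.T @ A, A.T @ np.array(by, float))
        for i in range(4):
            assert layout.positions[i][0] == pytest.approx(px[i] - px[0], abs=1e-6)
            assert layout.positions[i][1] == pytest.approx(py[i] - py[0], abs=1e-6)

    def test_disconnected_graph_names_components(self):
        offsets = [OffsetEstimate(10, 0, 1.0, (0, 1)),
                   OffsetEstimate(10, 0, 1.0, (2, 3))]
        with pytest.raises(DisconnectedGraphError) as exc:
            solve_layout(offsets, 4, anchor=0)
        comps = {frozenset(c) for c in exc.value.components}
        assert comps == {frozenset({0, 1}), frozenset({2, 3})}


class TestContrast:
    def test_fit_recovers_generating_parameters(self):
        rng = np.random.default_rng(3)
        img = rng.normal(30000, 1000, (512, 512)).clip(0, 65535).astype(np.uint16)
        model = fit_contrast(img)
        assert model.peak == pytest.approx(30000, abs=20)
        assert model.sigma == pytest.approx(1000, abs=20)

    def test_outlier_robustness(self):
        rng = np.random.default_rng(4)
        clean = rng.normal(30000, 1000, 200000)
        clean_fit = fit_contrast(clean.clip(0, 65535).astype(np.uint16).reshape(400, 500))
        dirty = clean.copy()
        idx = rng.choice(dirty.size, dirty.size // 10, replace=False)
        dirty[idx] = rng.uniform(0, 65535, idx.size)
        dirty_fit = fit_contrast(dirty.clip(0, 65535).astype(np.uint16).reshape(400, 500))
        assert abs(dirty_fit.peak - clean_fit.peak) < clean_fit.sigma / 10

    def test_constant_image_raises(self):
        with pytest.raises(NoSignalError):
            fit_contrast(np.full((32, 32), 100, dtype=np.uint16))

    def test_k_outside_usual_range_warns(self):
        with pytest.warns(UserWarning):
            ContrastModel(peak=100.0, sigma=10.0, k=5.0)

    def test_peak_maps_to_128(self):
        model = ContrastModel(peak=30000.0, sigma=1000.0, k=2.0)
        out = normalize_contrast(np.array([[30000.0]]), model)
        assert out[0, 0] == 128  # 127.5 rounded half-up

    def test_clipping_endpoints(self):
        model = ContrastModel(peak=30000.0, sigma=1000.0, k=2.0)
        vals = np.array([[0.0, 28000.0, 32000.0, 65535.0]])
        out = normalize_contrast(vals, model)
        assert out[0, 0] == 0 and out[0, 1] == 0
        assert out[0, 2] == 255 and out[0, 3] == 255

    def test_monotone(self):
        model = ContrastModel(peak=30000.0, sigma=1000.0, k=2.0)
        xs = np.linspace(25000, 35000, 257)[None, :]
        out = normalize_contrast(xs, model).ravel()
        assert np.all(np.diff(out.astype(int)) >= 0)

    def test_renormalization_is_stable(self):
        rng = np.random.default_rng(5)
        img = rng.normal(30000, 2000, (256, 256)).clip(0, 65535).astype(np.uint16)
        first = normalize_contrast(img, fit_contrast(img))
        second = normalize_contrast(first.astype(np.uint16),
                                    fit_contrast(first.astype(np.uint16)))
        assert np.max(np.abs(second.astype(int) - first.astype(int))) <= 1


class TestStitch:
    def test_single_tile_identity(self, small_texture):
        tile = Tile(small_texture[:64, :64])
        layout = registration.SectionLayout({0: (0.0, 0.0)}, anchor_tile=0)
        mosaic, mask = stitch([tile], layout)
        assert np.array_equal(mosaic, tile.image)
        assert np.all(mask == 0)

    def test_two_tiles_reproduce_texture(self, small_texture):
        t0 = Tile(small_texture[:128, :128])
        t1 = Tile(small_texture[:128, 100:228])
        layout = registration.SectionLayout({0: (0.0, 0.0), 1: (100.0, 0.0)},
                                            anchor_tile=0)
        mosaic, mask = stitch([t0, t1], layout)
        assert mosaic.shape == (128, 228)
        assert np.array_equal(mosaic, small_texture[:128, :228])
        assert np.all(mask >= 0)

    def test_mosaic_is_bounding_box(self, small_texture):
        tiles = [Tile(small_texture[:64, :64]), Tile(small_texture[10:74, 50:114])]
        layout = registration.SectionLayout({0: (0.0, 0.0), 1: (50.0, 10.0)},
                                            anchor_tile=0)
        mosaic, _ = stitch(tiles, layout)
        assert mosaic.shape == (74, 114)

    def test_feather_preserves_single_coverage(self, small_texture):
        t0 = Tile(small_texture[:96, :96].astype(float))
        t1 = Tile(small_texture[:96, 80:176].astype(float))
        layout = registration.SectionLayout({0: (0.0, 0.0), 1: (80.0, 0.0)},
                                            anchor_tile=0)
        mosaic, mask = stitch([t0, t1], layout, blend="feather")
        # single-coverage pixels are exact
        assert np.allclose(mosaic[:, :80], t0.image[:, :80])
        assert np.allclose(mosaic[:, 96:], t1.image[:, 16:])


class TestRegisterGrid:
    def test_end_to_end_grid_recovery(self):
        grid = simulate.gen_tile_grid(3, 3, 256, overlap_fraction=0.06,
                                      jitter=2, seed=3)
        tiles = [Tile(t) for t in grid.tiles]
        _, layout = registration.register_grid(tiles, 3, 3, max_offset=64)
        gt = grid.true_positions
        for i in range(9):  # up to the anchor translation
            assert layout.positions[i][0] == pytest.approx(gt[i][0] - gt[0][0], abs=1e-6)
            assert layout.positions[i][1] == pytest.approx(gt[i][1] - gt[0][1], abs=1e-6)
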
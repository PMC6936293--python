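from __future__ import annotations

import numpy as np
import pytest

import actinmachine as am
from actinmachine.matrix import SynthSpec, _segment_voxels


class TestThreshold:
    @pytest.mark.parametrize(
        "rgb,expected",
        [
            ((41, 20, 20), True),  # all channels strictly above
            ((40, 200, 200), False),  # red not strictly > 40
            ((200, 19, 200), False),  # green not strictly > 19
            ((200, 200, 19), False),  # blue not strictly > 19
            ((0, 0, 0), False),
        ],
    )
    def test_strict_channel_rule(self, rgb, expected):
        stack = np.zeros((1, 1, 1, 3), dtype=np.uint8)
        stack[0, 0, 0] = rgb
        assert bool(am.threshold_stack(stack).grid[0, 0, 0]) is expected

    def test_all_black_stack_is_nonconductive(self):
        out = am.threshold_stack(np.zeros((4, 5, 6, 3), dtype=np.uint8))
        assert out.shape == (4, 5, 6)
        assert not out.grid.any()

    def test_idempotent_through_rgb_rendering(self):
        rng = np.random.default_rng(0)
        stack = rng.integers(0, 256, size=(6, 6, 4, 3), dtype=np.uint8)
        matrix = am.threshold_stack(stack)
        rendered = np.where(matrix.grid[..., None], 255, 0).astype(np.uint8)
        again = am.threshold_stack(np.broadcast_to(rendered, (*matrix.shape, 3)))
        assert np.array_equal(matrix.grid, again.grid)

    def test_ragged_stack_rejected(self):
        with pytest.raises(ValueError):
            am.threshold_stack(np.zeros((3, 3, 3, 2), dtype=np.uint8))


class TestCompressZ:
    def test_factor_one_is_identity(self):
        rng = np.random.default_rng(1)
        m = am.ConductiveMatrix(rng.random((5, 5, 7)) > 0.5)
        out = am.compress_z(m, 1)
        assert np.array_equal(out.grid, m.grid)

    def test_or_semantics_union(self):
        grid = np.zeros((4, 4, 2), dtype=bool)
        grid[0, 0, 0] = True
        grid[3, 3, 1] = True
        out = am.compress_z(am.ConductiveMatrix(grid), 2)
        assert out.shape == (4, 4, 1)
        assert out.grid[0, 0, 0] and out.grid[3, 3, 0]
        assert out.grid.sum() == 2

    def test_output_depth_is_ceiling(self):
        m = am.ConductiveMatrix(np.zeros((2, 2, 30), dtype=bool))
        assert am.compress_z(m, 2).shape[2] == 15
        assert am.compress_z(m, 4).shape[2] == 8  # ceil(30/4)

    @pytest.mark.parametrize("factor", [0, -1])
    def test_invalid_factor(self, factor):
        m = am.ConductiveMatrix(np.zeros((2, 2, 2), dtype=bool))
        with pytest.raises(ValueError):
            am.compress_z(m, factor)

    def test_column_count_preserved_under_or(self):
        # OR of a bin is true iff any member true: per-(x, y, bin) brute force
        rng = np.random.default_rng(2)
        for _ in range(10):
            grid = rng.random((8, 8, 8)) > 0.7
            f = int(rng.integers(1, 5))
            out = am.compress_z(am.ConductiveMatrix(grid), f)
            assert out.grid.sum() <= grid.sum()
            for x in range(8):
                for y in range(8):
                    for b in range(out.shape[2]):
                        assert out.grid[x, y, b] == grid[x, y, b * f : (b + 1) * f].any()


class TestSynth:
    def test_line_has_exact_collinear_voxels(self, line_matrix):
        assert line_matrix.n_conductive == 31
        xs, ys, zs = np.nonzero(line_matrix.grid)
        assert set(ys) == {1} and set(zs) == {1}
        assert sorted(xs) == list(range(31))

    def test_fixed_seed_is_deterministic(self):
        spec = SynthSpec(kind="delaunay", extent=(30, 30, 6), n_points=10, tube_radius=1.5, seed=5)
        assert np.array_equal(am.synth_network(spec).grid, am.synth_network(spec).grid)

    def test_ring_voxels_have_exactly_two_neighbours(self, ring_matrix):
        vox = set(zip(*np.nonzero(ring_matrix.grid)))
        for x, y, z in vox:
            n = sum(
                (x + dx, y + dy, z + dz) in vox
                for dx in (-1, 0, 1)
                for dy in (-1, 0, 1)
                for dz in (-1, 0, 1)
                if (dx, dy, dz) != (0, 0, 0)
            )
            assert n == 2

    def test_delaunay_equals_union_of_tube_rasterizations(self):
        spec = SynthSpec(kind="delaunay", extent=(25, 25, 8), n_points=8, tube_radius=1.2, seed=3)
        m = am.synth_network(spec)
        points = m.meta["points"]
        edges = m.meta["edges"]
        expected = np.zeros(spec.extent, dtype=bool)
        r2 = spec.tube_radius**2
        for a, b in edges:
            p0, p1 = points[a], points[b]
            d = p1 - p0
            l2 = d @ d
            for x in range(25):
                for y in range(25):
                    for z in range(8):
                        p = np.array([x, y, z], dtype=float)
                        t = 0.0 if l2 == 0 else float(np.clip((p - p0) @ d / l2, 0, 1))
                        if ((p - (p0 + t * d)) ** 2).sum() <= r2 + 1e-9:
                            expected[x, y, z] = True
        assert np.array_equal(m.grid, expected)

    def test_geometry_exceeding_extent_rejected(self):
        with pytest.raises(ValueError):
            am.synth_network(SynthSpec(kind="line", extent=(10, 3, 3), length=20))
        with pytest.raises(ValueError):
            am.synth_network(SynthSpec(kind="ring", extent=(6, 6, 3), ring_radius=5))


class TestIO:
    def test_matrix_roundtrip_tiff(self, tmp_path, delaunay_matrix):
        path = tmp_path / "m.tif"
        am.save_matrix(delaunay_matrix, path)
        back = am.load_matrix(path)
        assert np.array_equal(back.grid, delaunay_matrix.grid)
        assert back.provenance == "loaded"

    def test_stack_roundtrip_through_threshold(self, tmp_path):
        import tifffile

        rng = np.random.default_rng(4)
        pages = rng.integers(0, 256, size=(4, 6, 5, 3), dtype=np.uint8)  # (z, y, x, 3)
        tifffile.imwrite(tmp_path / "stack.tif", pages)
        stack = am.load_stack(tmp_path / "stack.tif")
        assert stack.shape == (5, 6, 4)
        # grid order matches page order: grid[i, j, z] == page[z, j, i]
        assert np.array_equal(stack.data[2, 3, 1], pages[1, 3, 2])
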
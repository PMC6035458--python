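import numpy as np
import pytest

from conftest import circle_stack, square_stack
from rsdmtox.geometry import (ContourError, ContourStack, DoseGrid, Slice,
                              SurfaceMesh, contours_to_mesh, sample_dose,
                              surface_area, vertex_areas)
from rsdmtox.io import (read_contours, read_dose_grid, read_ply,
                        write_contours, write_dose_grid, write_ply)
from rsdmtox.synthetic import CohortSpec, make_rectum


class TestContourStack:
    def test_duplicate_z_rejected(self):
        pts = np.array([[0, 0], [1, 0], [1, 1]], dtype=float)
        with pytest.raises(ContourError, match="strictly increasing"):
            ContourStack([Slice(0.0, pts), Slice(0.0, pts)], 1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ContourError, match=">=3"):
            ContourStack([Slice(0.0, np.array([[0, 0], [1, 1]]))], 1.0)

    def test_self_intersection_rejected(self):
        bowtie = np.array([[0, 0], [1, 1], [1, 0], [0, 1]], dtype=float)
        with pytest.raises(ContourError, match="self-intersecting"):
            ContourStack([Slice(0.0, bowtie)], 1.0)

    def test_orientation_normalized_ccw(self):
        cw = np.array([[0, 0], [0, 1], [1, 1], [1, 0]], dtype=float)
        stack = ContourStack([Slice(0.0, cw)], 1.0)
        pts = stack.slices[0].points
        x, y = pts[:, 0], pts[:, 1]
        area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        assert area > 0

    def test_start_rotated_to_posterior_most(self):
        stack = circle_stack(radius=5.0, n_points=16, n_slices=2)
        for s in stack.slices:
            assert s.points[0, 1] == pytest.approx(s.points[:, 1].min())

    def test_length_warning_outside_range(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            square_stack(n_slices=3, spacing=1.0)  # 2 mm long
        assert any("length" in r.message for r in caplog.records)


class TestContourIO:
    def test_square_tube_roundtrip(self, tmp_path):
        stack = square_stack(n_slices=3)
        path = tmp_path / "sq.txt"
        write_contours(stack, path)
        back = read_contours(path)
        assert back.n_slices == 3
        assert back.allclose(stack, atol=1e-6)

    def test_synthetic_roundtrip_field_by_field(self, tmp_path):
        stack = make_rectum(CohortSpec(seed=4), 99)
        path = tmp_path / "r.txt"
        write_contours(stack, path)
        back = read_contours(path)
        assert back.slice_spacing == pytest.approx(stack.slice_spacing,
                                                   abs=1e-6)
        for a, b in zip(stack.slices, back.slices):
            assert b.z == pytest.approx(a.z, abs=1e-6)
            np.testing.assert_allclose(b.points, a.points, atol=1e-6)

    def test_malformed_polygon_names_slice(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("z 0\n0 0\n1 0\n1 1\nz 2\n0 0\n1 1\n")
        with pytest.raises(ContourError, match="z=2"):
            read_contours(path)


class TestContoursToMesh:
    def test_two_unit_squares_prism(self):
        stack = square_stack(n_slices=2)
        mesh = contours_to_mesh(stack, samples_per_contour=None)
        assert mesh.n_vertices == 8
        assert len(mesh.faces) == 8
        assert surface_area(mesh) == pytest.approx(4.0)
        np.testing.assert_array_equal(np.unique(mesh.vertex_slice), [0, 1])

    def test_cylinder_lateral_area(self):
        stack = circle_stack(radius=10.0, n_points=64, n_slices=2,
                             spacing=2.0)
        mesh = contours_to_mesh(stack, samples_per_contour=None)
        assert surface_area(mesh) == pytest.approx(2 * np.pi * 10 * 2,
                                                   rel=0.02)

    def test_single_slice_errors(self):
        stack = square_stack(n_slices=3)
        single = ContourStack(stack.slices[:1], stack.slice_spacing)
        with pytest.raises(ContourError, match="at least 2"):
            contours_to_mesh(single)

    def test_two_boundary_loops(self, cylinder):
        _, mesh = cylinder
        assert len(mesh.boundary_loops()) == 2

    def test_area_converges_with_sampling(self):
        analytic = 2 * np.pi * 10 * 2
        errs = []
        for n in (16, 64, 256):
            stack = circle_stack(radius=10.0, n_points=max(n, 16),
                                 n_slices=2, spacing=2.0)
            mesh = contours_to_mesh(stack, samples_per_contour=n)
            errs.append(abs(surface_area(mesh) - analytic))
        assert errs[0] > errs[1] > errs[2]

    def test_resampling_keeps_vertex_count(self, cylinder):
        stack, _ = cylinder
        mesh = contours_to_mesh(stack, samples_per_contour=32)
        assert mesh.n_vertices == stack.n_slices * 32


class TestAreas:
    def test_unit_right_triangle(self):
        mesh = SurfaceMesh(np.array([[0., 0, 0], [1, 0, 0], [0, 1, 0]]),
                           np.array([[0, 1, 2]]))
        assert surface_area(mesh) == pytest.approx(0.5)

    def test_vertex_areas_partition_surface(self, cylinder):
        _, mesh = cylinder
        assert vertex_areas(mesh).sum() == pytest.approx(
            surface_area(mesh), rel=1e-6)


class TestSampleDose:
    def _grid(self, values):
        return DoseGrid(values, origin=np.array([-20., -20, -5]),
                        spacing=np.array([2., 2, 2]))

    def test_constant_grid(self, cylinder):
        _, mesh = cylinder
        grid = self._grid(np.full((25, 25, 20), 7.0))
        np.testing.assert_allclose(sample_dose(mesh, grid), 7.0)

    def test_linear_ramp_reproduced(self, cylinder):
        _, mesh = cylinder
        shape = (25, 25, 20)
        zax = -5 + 2.0 * np.arange(shape[2])
        vals = np.broadcast_to(zax + 5.0, shape).copy()  # keep >= 0
        grid = self._grid(vals)
        np.testing.assert_allclose(sample_dose(mesh, grid),
                                   mesh.vertices[:, 2] + 5.0, atol=1e-9)

    def test_matches_bruteforce_trilinear(self, cylinder, rng):
        _, mesh = cylinder
        vals = rng.uniform(0, 10, size=(25, 25, 20))
        grid = self._grid(vals)
        got = sample_dose(mesh, grid)
        axes = grid.axes()
        for k in rng.choice(mesh.n_vertices, size=40, replace=False):
            p = mesh.vertices[k]
            idx = [int(np.clip((p[i] - axes[i][0]) / grid.spacing[i], 0,
                               len(axes[i]) - 2)) for i in range(3)]
            t = [(p[i] - axes[i][idx[i]]) / grid.spacing[i] for i in range(3)]
            expect = 0.0
            for dx in (0, 1):
                for dy in (0, 1):
                    for dz in (0, 1):
                        w = ((t[0] if dx else 1 - t[0])
                             * (t[1] if dy else 1 - t[1])
                             * (t[2] if dz else 1 - t[2]))
                        expect += w * vals[idx[0] + dx, idx[1] + dy,
                                           idx[2] + dz]
            assert got[k] == pytest.approx(expect, abs=1e-9)

    def test_out_of_bounds_clamped_with_warning(self, cylinder):
        _, mesh = cylinder
        grid = DoseGrid(np.full((5, 5, 5), 3.0), origin=np.zeros(3),
                        spacing=np.ones(3))
        with pytest.warns(UserWarning, match="clamped"):
            out = sample_dose(mesh, grid)
        np.testing.assert_allclose(out, 3.0)


class TestMeshAndGridIO:
    def test_ply_roundtrip_with_dose(self, cylinder, rng, tmp_path):
        _, mesh = cylinder
        mesh.vertex_dose = rng.uniform(0, 80, mesh.n_vertices)
        path = tmp_path / "m.ply"
        write_ply(mesh, path)
        back = read_ply(path)
        np.testing.assert_allclose(back.vertices, mesh.vertices, atol=1e-6)
        np.testing.assert_array_equal(back.faces, mesh.faces)
        np.testing.assert_allclose(back.vertex_dose, mesh.vertex_dose,
                                   atol=1e-6)
        np.testing.assert_array_equal(back.vertex_slice, mesh.vertex_slice)

    def test_dose_grid_roundtrip(self, rng, tmp_path):
        grid = DoseGrid(rng.uniform(0, 10, (4, 5, 6)),
                        origin=np.array([1., 2, 3]),
                        spacing=np.array([2., 2, 2.5]))
        write_dose_grid(grid, tmp_path / "g")
        back = read_dose_grid(tmp_path / "g")
        np.testing.assert_allclose(back.values, grid.values, atol=1e-6)
        np.testing.assert_allclose(back.origin, grid.origin)
        np.testing.assert_allclose(back.spacing, grid.spacing)
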
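"""Fistula selection, design frames, contour extraction, and wound morphometry."""

import numpy as np
import pytest

from conftest import circle_contour, planar_polygon_region
from eafadapt import phantom, scan_io, wound_model
from eafadapt.scan_io import SurfaceMesh
from eafadapt.wound_model import (
    FistulaContour,
    GeometryError,
    SelectionError,
    extract_contour,
    extrude_fistula,
    fit_design_frame,
    measure_wound,
    select_fistula_region,
)


def rotation(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


class TestSelectFistulaRegion:
    def test_full_selection_of_two_triangle_square(self):
        mesh = SurfaceMesh(
            [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], [[0, 1, 2], [0, 2, 3]]
        )
        lasso = np.array([[-1, -1, 0], [2, -1, 0], [2, 2, 0], [-1, 2, 0]])
        region = select_fistula_region(mesh, lasso)
        assert len(region.face_indices) == 2
        assert region.area() == pytest.approx(1.0)

    def test_lasso_outside_mesh_is_selection_error(self):
        mesh = SurfaceMesh(
            [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], [[0, 1, 2], [0, 2, 3]]
        )
        lasso = np.array([[10, 10, 0], [11, 10, 0], [11, 11, 0], [10, 11, 0]])
        with pytest.raises(SelectionError):
            select_fistula_region(mesh, lasso)

    def test_phantom_stoma_region_area_matches_surface_integral(
        self, default_phantom, phantom_mesh, phantom_region
    ):
        _, truth = default_phantom
        s = truth.spec.stomas[0]
        r_lasso = 1.15 * s.base_radius

        def integrand(y, x):
            h = 1e-4
            gx = (truth.surface(x + h, y) - truth.surface(x - h, y)) / (2 * h)
            gy = (truth.surface(x, y + h) - truth.surface(x, y - h)) / (2 * h)
            return np.sqrt(1 + gx**2 + gy**2)

        # polar integral over the lasso disk around the stoma center
        th = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        rr = np.linspace(0, r_lasso, 400)
        R, TH = np.meshgrid(rr, th, indexing="ij")
        X = s.center[0] + R * np.cos(TH)
        Y = s.center[1] + R * np.sin(TH)
        area_truth = float(
            np.trapezoid(np.trapezoid(integrand(Y, X) * R, th, axis=1), rr)
        )
        assert phantom_region.area() == pytest.approx(area_truth, rel=0.05)


class TestDesignFrame:
    def test_planar_boundary_recovers_plane(self):
        region = planar_polygon_region(circle_contour(10, 64), z=5.0)
        frame = fit_design_frame(region)
        np.testing.assert_allclose(np.abs(frame.z_axis), [0, 0, 1], atol=1e-9)
        assert frame.origin[2] == pytest.approx(5.0)
        # right-handed orthonormal
        basis = np.vstack([frame.x_axis, frame.y_axis, frame.z_axis])
        np.testing.assert_allclose(basis @ basis.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(basis) == pytest.approx(1.0)

    def test_tilted_boundary_equivariance(self):
        region = planar_polygon_region(circle_contour(10, 64), z=0.0)
        R = rotation([1, 1, 0], np.deg2rad(30))
        flat_normal = fit_design_frame(region).z_axis
        region.mesh.vertices = region.mesh.vertices @ R.T
        tilted = fit_design_frame(region)
        expected = R @ flat_normal
        angle = np.arccos(np.clip(abs(tilted.z_axis @ expected), -1, 1))
        assert angle < 1e-6

    def test_phantom_stoma_rim_normal_near_vertical(self, phantom_region):
        frame = fit_design_frame(phantom_region)
        angle = np.degrees(np.arccos(np.clip(frame.z_axis @ [0, 0, 1], -1, 1)))
        assert angle < 2.0

    def test_collinear_boundary_rejected(self):
        region = planar_polygon_region(circle_contour(5, 16))
        region.boundary = np.arange(3)
        region.mesh.vertices[:3] = np.column_stack([np.arange(3), np.zeros(3), np.zeros(3)])
        with pytest.raises(GeometryError):
            fit_design_frame(region)


class TestExtractContour:
    @pytest.mark.parametrize(
        "loop, expected_area, expected_perimeter",
        [
            (circle_contour(10, 512), np.pi * 100, 2 * np.pi * 10),
            (np.array([[0, 0], [20, 0], [20, 20], [0, 20]], float), 400.0, 80.0),
            (
                np.stack(
                    [
                        15 * np.cos(np.linspace(0, 2 * np.pi, 512, endpoint=False)),
                        10 * np.sin(np.linspace(0, 2 * np.pi, 512, endpoint=False)),
                    ],
                    axis=1,
                ),
                np.pi * 150,
                None,
            ),
        ],
    )
    def test_closed_forms(self, loop, expected_area, expected_perimeter):
        region = planar_polygon_region(loop)
        frame = fit_design_frame(region)
        contour = extract_contour(region, frame, smooth_window=1)
        assert contour.area == pytest.approx(expected_area, rel=0.005)
        if expected_perimeter is not None:
            assert contour.perimeter == pytest.approx(expected_perimeter, rel=0.005)

    def test_resampling_error_non_increasing(self):
        region = planar_polygon_region(circle_contour(10, 2048))
        frame = fit_design_frame(region)
        errs = []
        for n in (64, 256, 1024):
            c = extract_contour(region, frame, n_samples=n, smooth_window=1)
            errs.append(abs(c.area - np.pi * 100))
        assert errs[0] >= errs[1] >= errs[2]

    def test_contour_is_ccw(self):
        from eafadapt._geometry import signed_area

        region = planar_polygon_region(circle_contour(10, 128)[::-1])
        frame = fit_design_frame(region)
        contour = extract_contour(region, frame)
        assert signed_area(contour.points) > 0


class TestExtrude:
    def test_unit_square_exact_volume(self):
        sq = FistulaContour(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        prism = extrude_fistula(sq, 0.0, 2.0)
        assert prism.volume() == pytest.approx(2.0, abs=1e-12)
        assert prism.is_watertight()

    def test_cylinder_volume_closed_form(self):
        circ = FistulaContour(circle_contour(10))
        prism = extrude_fistula(circ, 0.0, 12.0)
        assert prism.volume() == pytest.approx(np.pi * 100 * 12, rel=0.005)

    def test_degenerate_height_rejected(self):
        circ = FistulaContour(circle_contour(10))
        with pytest.raises(GeometryError):
            extrude_fistula(circ, 1.0, 1.0)

    @pytest.mark.parametrize("s", [0.5, 2.0, 3.0])
    def test_volume_scales_with_square_of_contour_scale(self, s):
        base = FistulaContour(circle_contour(10, 64))
        scaled = FistulaContour(base.points * s)
        v0 = extrude_fistula(base, 0, 5).volume()
        v1 = extrude_fistula(scaled, 0, 5).volume()
        assert v1 == pytest.approx(v0 * s**2, rel=1e-9)


class TestMeasureWound:
    def test_phantom_dimensions_recovered(self, default_phantom, phantom_mesh, phantom_region):
        _, truth = default_phantom
        meas = measure_wound(phantom_mesh, truth.wound_rim_loop(), [phantom_region])
        assert meas.length_cm == pytest.approx(truth.length_cm, rel=0.05)
        assert meas.width_cm == pytest.approx(truth.width_cm, rel=0.05)
        assert meas.depth_cm == pytest.approx(truth.depth_cm, rel=0.05)
        assert meas.length_cm >= meas.width_cm

    def test_flat_patch_depth_zero(self):
        spec = phantom.PhantomSpec(
            wound_depth=1e-9, stomas=(), noise_sigma=0.0, n_points=50_000, seed=0,
            patch_size=(60, 60), wound_semi_axes=(20, 15),
        )
        cloud, truth = phantom.generate_phantom(spec)
        mesh = scan_io.reconstruct_surface(cloud, 1.0)
        meas = measure_wound(mesh, truth.wound_rim_loop())
        assert meas.depth_cm == pytest.approx(0.0, abs=1e-6)

    def test_two_stoma_heights_recovered(self):
        spec = phantom.PhantomSpec(
            stomas=(
                phantom.StomaSpec((-20.0, 0.0), 10.0, 10.0),
                phantom.StomaSpec((18.0, 5.0), 10.0, 15.0),
            ),
            seed=11,
        )
        cloud, truth = phantom.generate_phantom(spec)
        mesh = scan_io.reconstruct_surface(cloud, 1.0)
        regions = [
            wound_model.select_fistula_region(mesh, truth.stoma_lasso(i)) for i in (0, 1)
        ]
        meas = measure_wound(mesh, truth.wound_rim_loop(), regions)
        assert meas.n_orifices == 2
        assert meas.fistula_orifice_heights_cm[0] == pytest.approx(1.0, rel=0.10)
        assert meas.fistula_orifice_heights_cm[1] == pytest.approx(1.5, rel=0.10)

    def test_rigid_motion_invariance(self, default_phantom, phantom_mesh, phantom_region):
        _, truth = default_phantom
        lasso = truth.wound_rim_loop()
        ref = measure_wound(phantom_mesh, lasso, [phantom_region])
        R = rotation([0.3, -0.5, 0.8], 1.1)
        t = np.array([40.0, -12.0, 7.0])
        moved_mesh = SurfaceMesh(phantom_mesh.vertices @ R.T + t, phantom_mesh.faces)
        moved_region = wound_model.FistulaRegion(
            mesh=moved_mesh,
            face_indices=phantom_region.face_indices,
            boundary=phantom_region.boundary,
        )
        moved = measure_wound(moved_mesh, lasso @ R.T + t, [moved_region])
        for a, b in [
            (ref.length_cm, moved.length_cm),
            (ref.width_cm, moved.width_cm),
            (ref.depth_cm, moved.depth_cm),
            (ref.fistula_orifice_heights_cm[0], moved.fistula_orifice_heights_cm[0]),
        ]:
            assert b == pytest.approx(a, rel=1e-6)

    def test_swap_axes(self, default_phantom, phantom_mesh):
        _, truth = default_phantom
        meas = measure_wound(phantom_mesh, truth.wound_rim_loop(), swap_axes=True)
        assert meas.length_cm < meas.width_cm
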
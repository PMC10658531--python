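"""Parametric adapter construction: sketches, loft, hole subtraction, reports."""

import numpy as np
import pytest

from conftest import circle_contour, random_smooth_contour
from eafadapt import scan_io
from eafadapt.adapter_design import (
    AdapterSpec,
    DesignInfeasible,
    PlaneSketch,
    build_adapter,
    build_sketches,
    fit_check,
    format_range_cm,
    ledge_report,
    loft_solid,
    offset_contour,
    resolve_middle_fraction,
    subtract_hole,
)
from eafadapt.wound_model import FistulaContour, fit_design_frame
from eafadapt.scan_io import mesh_stats, write_stl, read_mesh


class TestOffsetContour:
    def test_circle_offset_is_larger_circle(self):
        out = offset_contour(FistulaContour(circle_contour(10)), 5.0)
        assert out.area == pytest.approx(np.pi * 225, rel=0.005)

    def test_zero_offset_is_identity(self):
        c = FistulaContour(circle_contour(10))
        out = offset_contour(c, 0.0)
        assert out.area == pytest.approx(c.area, rel=1e-6)
        assert out.perimeter == pytest.approx(c.perimeter, rel=1e-6)

    def test_unit_square_minkowski_closed_form(self):
        sq = FistulaContour(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        out = offset_contour(sq, 1.0)
        assert out.area == pytest.approx(1 + 4 + np.pi, rel=0.005)

    def test_negative_offset_rejected(self):
        with pytest.raises(ValueError):
            offset_contour(FistulaContour(circle_contour(10)), -1.0)


class TestMiddleFraction:
    @pytest.mark.parametrize(
        "h, f", [(10, 0.25), (20, 0.15), (15, 0.20), (5, 0.25), (30, 0.15), (12.5, 0.225)]
    )
    def test_height_rule(self, h, f):
        assert resolve_middle_fraction(h) == pytest.approx(f)

    def test_nonpositive_height_rejected(self):
        with pytest.raises(ValueError):
            resolve_middle_fraction(0)


class TestBuildSketches:
    def test_circle_defaults_give_expected_radii_and_planes(self):
        contour = FistulaContour(circle_contour(10))
        spec = AdapterSpec(height=15, bottom_offset=5, top_offset=15)
        (bottom, middle, top), hole = build_sketches(contour, spec)
        assert bottom.z == 0 and top.z == 15
        assert middle.z == pytest.approx(0.20 * 15)
        for sk, r in [(bottom, 15), (middle, 15), (top, 25)]:
            radii = np.linalg.norm(sk.contour, axis=1)
            np.testing.assert_allclose(radii, r, rtol=0.005)
        assert hole.area == pytest.approx(np.pi * 100, rel=0.005)

    def test_excessive_eccentricity_is_infeasible(self):
        contour = FistulaContour(circle_contour(10))
        spec = AdapterSpec(height=15, top_offset=15, eccentricity=(30.0, 0.0))
        with pytest.raises(DesignInfeasible):
            build_sketches(contour, spec)

    def test_zero_eccentricity_keeps_centroids_aligned(self):
        contour = FistulaContour(random_smooth_contour(np.random.default_rng(4)))
        (bottom, _, top), _ = build_sketches(contour, AdapterSpec())
        cb = bottom.contour.mean(axis=0)
        ct = top.contour.mean(axis=0)
        np.testing.assert_allclose(cb, ct, atol=0.5)


class TestLoft:
    def test_cylinder_volume(self):
        sk = tuple(PlaneSketch(z, circle_contour(10)) for z in (0, 6, 12))
        assert loft_solid(sk).volume() == pytest.approx(np.pi * 100 * 12, rel=0.005)

    def test_frustum_volume(self):
        sk = (
            PlaneSketch(0, circle_contour(10)),
            PlaneSketch(6, circle_contour(15)),
            PlaneSketch(12, circle_contour(20)),
        )
        expected = np.pi * 12 * (100 + 10 * 20 + 400) / 3
        assert loft_solid(sk).volume() == pytest.approx(expected, rel=0.005)

    def test_square_prism_volume_exact(self):
        sq = np.array([[0, 0], [20, 0], [20, 20], [0, 20]], float)
        sk = tuple(PlaneSketch(z, sq) for z in (0, 5, 10))
        mesh = loft_solid(sk)
        assert mesh.volume() == pytest.approx(400 * 10, rel=1e-9)
        assert mesh.is_watertight()

    def test_loft_is_watertight_genus_zero(self):
        sk = (
            PlaneSketch(0, circle_contour(10)),
            PlaneSketch(3, circle_contour(12)),
            PlaneSketch(15, circle_contour(22)),
        )
        mesh = loft_solid(sk)
        assert mesh.is_watertight()
        assert mesh_stats(mesh).euler_characteristic == 2


class TestSubtractHole:
    def test_annular_cylinder_closed_form(self):
        sk = tuple(PlaneSketch(z, circle_contour(15)) for z in (0, 5, 10))
        ring = subtract_hole(loft_solid(sk), FistulaContour(circle_contour(10)), 10)
        assert ring.volume() == pytest.approx(np.pi * (225 - 100) * 10, rel=0.005)
        assert ring.is_watertight()

    def test_ring_has_euler_characteristic_zero(self):
        contour = FistulaContour(random_smooth_contour(np.random.default_rng(1)))
        adapter = build_adapter(contour, AdapterSpec())
        assert mesh_stats(adapter.mesh).euler_characteristic == 0

    def test_hole_equal_to_outer_wall_is_infeasible(self):
        sk = tuple(PlaneSketch(z, circle_contour(10)) for z in (0, 5, 10))
        with pytest.raises(DesignInfeasible):
            subtract_hole(loft_solid(sk), FistulaContour(circle_contour(10)), 10)


class TestVolumeIdentity:
    def test_identity_across_randomized_specs(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            contour = FistulaContour(random_smooth_contour(rng, r0=rng.uniform(6, 14)))
            spec = AdapterSpec(
                height=rng.uniform(10, 20),
                bottom_offset=rng.uniform(3, 7),
                top_offset=rng.uniform(8, 20),
                eccentricity=(rng.uniform(-2, 2), rng.uniform(-2, 2)),
                hole_clearance=rng.uniform(0, 1),
            )
            sketches, hole = build_sketches(contour, spec)
            loft = loft_solid(sketches)
            ring = subtract_hole(loft, hole, spec.height)
            expected = loft.volume() - hole.area * spec.height
            assert ring.volume() == pytest.approx(expected, rel=0.005)
            assert ring.is_watertight()
            assert mesh_stats(ring).euler_characteristic == 0

    def test_voxelization_oracle_agrees(self, voxel_volume_oracle):
        rng = np.random.default_rng(5)
        for _ in range(3):
            contour = FistulaContour(random_smooth_contour(rng))
            adapter = build_adapter(contour, AdapterSpec(height=12, top_offset=12))
            vox = voxel_volume_oracle(adapter.mesh, pitch=0.25)
            assert vox == pytest.approx(adapter.mesh.volume(), rel=0.01)


class TestMonotonicity:
    def test_volume_increases_with_top_offset(self):
        contour = FistulaContour(circle_contour(10))
        vols = [
            build_adapter(contour, AdapterSpec(top_offset=d)).mesh.volume()
            for d in (8, 12, 16, 20)
        ]
        assert all(b > a for a, b in zip(vols, vols[1:]))

    def test_volume_decreases_with_hole_clearance(self):
        contour = FistulaContour(circle_contour(10))
        vols = [
            build_adapter(contour, AdapterSpec(hole_clearance=c)).mesh.volume()
            for c in (0.0, 0.5, 1.0)
        ]
        assert all(b < a for a, b in zip(vols, vols[1:]))


class TestRigidInvariance:
    def test_rotating_contour_preserves_volume(self):
        rng = np.random.default_rng(3)
        pts = random_smooth_contour(rng)
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        v0 = build_adapter(FistulaContour(pts), AdapterSpec()).mesh.volume()
        v1 = build_adapter(FistulaContour(pts @ R.T), AdapterSpec()).mesh.volume()
        assert v1 == pytest.approx(v0, rel=1e-9)


class TestLedgeReport:
    def test_concentric_circles_uniform_ledge(self):
        contour = FistulaContour(circle_contour(10))
        adapter = build_adapter(
            contour, AdapterSpec(height=10, bottom_offset=10, top_offset=10)
        )
        rep = ledge_report(adapter)
        assert rep.top_ledge_cm == (1.0, 1.0)
        assert rep.bottom_ledge_cm == (1.0, 1.0)
        assert rep.as_dict()["top_ledge"] == "1"  # equal endpoints collapse

    def test_eccentric_top_gives_range(self):
        contour = FistulaContour(circle_contour(10))
        adapter = build_adapter(
            contour, AdapterSpec(height=10, bottom_offset=10, top_offset=10, eccentricity=(2.0, 0.0))
        )
        rep = ledge_report(adapter)
        assert rep.top_ledge_cm == (pytest.approx(0.8, abs=0.051), pytest.approx(1.2, abs=0.051))
        assert rep.bottom_ledge_cm == (1.0, 1.0)

    def test_range_rendering_matches_clinical_table(self):
        assert format_range_cm(0.6, 0.8) == "0.6–0.8"
        assert format_range_cm(1.0, 1.0) == "1"
        assert format_range_cm(0.2, 0.6) == "0.2–0.6"

    def test_end_to_end_ledges_reproduce_requested_offsets(
        self, default_phantom, phantom_mesh, phantom_region
    ):
        from eafadapt.wound_model import extract_contour

        frame = fit_design_frame(phantom_region)
        contour = extract_contour(phantom_region, frame)
        spec = AdapterSpec(height=15, bottom_offset=5, top_offset=15)
        adapter = build_adapter(contour, spec)
        rep = ledge_report(adapter)
        assert rep.height_cm == pytest.approx(1.5, abs=0.05)
        assert rep.bottom_ledge_cm[0] == pytest.approx(0.5, abs=0.05)
        assert rep.top_ledge_cm[0] == pytest.approx(1.5, abs=0.05)


class TestFitCheck:
    def _case(self, default_phantom, phantom_mesh, phantom_region):
        frame = fit_design_frame(phantom_region)
        from eafadapt.wound_model import extract_contour

        contour = extract_contour(phantom_region, frame)
        adapter = build_adapter(contour, AdapterSpec())
        return adapter, frame

    def test_self_consistent_design_contains_fistula(
        self, default_phantom, phantom_mesh, phantom_region
    ):
        adapter, frame = self._case(default_phantom, phantom_mesh, phantom_region)
        fit = fit_check(
            adapter, phantom_mesh, frame, fistula_region=phantom_region, rest_on_surface=True
        )
        assert fit.hole_contains_fistula
        assert fit.max_penetration_mm == 0.0

    def test_lateral_shift_breaks_containment(
        self, default_phantom, phantom_mesh, phantom_region
    ):
        adapter, frame = self._case(default_phantom, phantom_mesh, phantom_region)
        fit = fit_check(
            adapter, phantom_mesh, frame, fistula_region=phantom_region, pose_offset=(5.0, 0, 0)
        )
        assert not fit.hole_contains_fistula

    def test_floating_adapter_has_no_penetration(
        self, default_phantom, phantom_mesh, phantom_region
    ):
        adapter, frame = self._case(default_phantom, phantom_mesh, phantom_region)
        fit = fit_check(adapter, phantom_mesh, frame, pose_offset=(0, 0, 10.0))
        assert fit.max_penetration_mm == 0.0


class TestSTLRoundTrip:
    def test_adapter_survives_stl_roundtrip(self, tmp_path):
        contour = FistulaContour(random_smooth_contour(np.random.default_rng(9)))
        adapter = build_adapter(contour, AdapterSpec())
        path = write_stl(adapter.mesh, tmp_path / "a.stl")
        back = read_mesh(path)
        assert back.is_watertight()
        assert back.volume() == pytest.approx(adapter.mesh.volume(), rel=1e-6)
        assert back.n_faces == adapter.mesh.n_faces
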
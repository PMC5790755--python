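import math

import numpy as np
import pytest

from sasmorph import synthgen
from sasmorph.errors import (DegenerateGeometryError, TruncatedSegmentError,
                             ValidationError)
from sasmorph.meshing import cap_surface_mesh, min_enclosing_sphere
from sasmorph.sas_morpho import (MorphoRecord, SASMesh, ShrinkageFactors,
                                 boundary_lengths, curvature, extract_sas,
                                 feret_diameter, measure, mesh_area,
                                 mesh_perimeter, shrinkage_correct)
from sasmorph.segment import (JunctionSegment, attach_ground_truth,
                              exclude_truncated, gaussian_blur,
                              threshold_components)
from sasmorph.stack import VoxelStack

from conftest import make_cap_spec


def _rigid_transform(mesh: SASMesh, seed=0) -> SASMesh:
    rng = np.random.default_rng(seed)
    a = rng.normal(size=3)
    a /= np.linalg.norm(a)
    ang = rng.uniform(0, 2 * np.pi)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * K @ K
    t = rng.uniform(-500, 500, size=3)
    return SASMesh(vertices=mesh.vertices @ R.T + t,
                   triangles=mesh.triangles)


class TestMeshArea:
    def test_unit_square_from_two_triangles(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        f = np.array([[0, 1, 2], [0, 2, 3]])
        assert mesh_area(SASMesh(vertices=v, triangles=f)) == pytest.approx(1.0)

    def test_hemisphere_area_converges(self, hemisphere):
        assert mesh_area(hemisphere) == pytest.approx(2 * np.pi * 100**2,
                                                      rel=0.01)

    def test_similarity_scaling(self, cap60):
        doubled = SASMesh(vertices=2 * cap60.vertices, triangles=cap60.triangles)
        assert mesh_area(doubled) == pytest.approx(4 * mesh_area(cap60),
                                                   rel=1e-9)

    def test_empty_mesh_rejected(self):
        with pytest.raises(ValidationError):
            mesh_area(SASMesh(vertices=np.zeros((0, 3)),
                              triangles=np.zeros((0, 3), dtype=int)))


class TestMeshPerimeter:
    def test_unit_square_outline(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        f = np.array([[0, 1, 2], [0, 2, 3]])
        assert mesh_perimeter(SASMesh(vertices=v, triangles=f)) == \
            pytest.approx(4.0)

    def test_disc_rim(self, disc):
        assert mesh_perimeter(disc) == pytest.approx(2 * np.pi * 200, rel=0.02)

    def test_cap_rim(self, cap60):
        assert mesh_perimeter(cap60) == pytest.approx(
            2 * np.pi * 300 * math.sin(math.radians(60)), rel=0.02)

    def test_annulus_reports_inner_rim_separately(self, annulus):
        lengths = boundary_lengths(annulus)
        assert len(lengths) == 2
        assert lengths[0] == pytest.approx(2 * np.pi * 150, rel=0.02)
        assert lengths[1] == pytest.approx(2 * np.pi * 50, rel=0.05)


class TestCurvature:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_flat_disc_any_orientation_scores_zero(self, disc, seed):
        assert curvature(_rigid_transform(disc, seed)) == \
            pytest.approx(0.0, abs=0.01)

    def test_hemisphere_scores_half(self, hemisphere):
        assert curvature(hemisphere) == pytest.approx(0.5, abs=0.02)

    def test_cap60_scores_quarter(self, cap60):
        assert curvature(cap60) == pytest.approx(0.25, abs=0.02)

    def test_projection_is_contraction(self, cap60, disc, annulus):
        for mesh in (cap60, disc, annulus):
            rec = measure(mesh)
            assert rec.projected_area_nm2 <= rec.area_nm2 + 1e-9
            assert rec.curvature >= 0.0


class TestFeret:
    def test_single_point(self):
        c, r = min_enclosing_sphere(np.array([[1.0, 2.0, 3.0]]))
        assert r == 0.0

    def test_disc_feret_is_diameter(self, disc):
        assert feret_diameter(disc) == pytest.approx(400.0, rel=0.01)

    def test_hemisphere_feret_is_sphere_diameter(self, hemisphere):
        assert feret_diameter(hemisphere) == pytest.approx(200.0, rel=0.01)

    @pytest.mark.parametrize("n", [4, 8, 12])
    def test_welzl_matches_brute_force(self, n):
        from itertools import combinations
        rng = np.random.default_rng(n)
        pts = rng.uniform(-10, 10, size=(n, 3))
        _, r = min_enclosing_sphere(pts)
        best = np.inf
        for k in (2, 3, 4):
            for sub in combinations(range(n), k):
                from sasmorph.meshing import _circumsphere
                s = _circumsphere([pts[i] for i in sub])
                if s is None:
                    continue
                c, rr = s
                if np.all(np.linalg.norm(pts - c, axis=1) <= rr * (1 + 1e-9)):
                    best = min(best, rr)
        assert r == pytest.approx(best, rel=1e-6)


class TestRigidMotionInvariance:
    def test_measurements_invariant(self, cap60):
        base = measure(cap60)
        moved = measure(_rigid_transform(cap60, seed=5))
        assert moved.area_nm2 == pytest.approx(base.area_nm2, rel=1e-9)
        assert moved.perimeter_nm == pytest.approx(base.perimeter_nm, rel=1e-9)
        assert moved.curvature == pytest.approx(base.curvature, abs=1e-9)
        assert moved.feret_nm == pytest.approx(base.feret_nm, rel=1e-7)


class TestExtractSas:
    def test_flat_disc_area(self):
        spec = synthgen.PhantomSpec(sphere_radius_nm=200.0, cap_angle_rad=0.0,
                                    orientation=(0.15, -0.1, 0.98))
        from sasmorph import experiments
        res = experiments.measure_phantom(spec, seed=3, noise_sd=0.0,
                                          classify_type=False)
        assert res.record is not None, res.error
        assert res.record.area_nm2 == pytest.approx(np.pi * 200**2, rel=0.05)
        assert res.record.perimeter_nm == pytest.approx(2 * np.pi * 200,
                                                        rel=0.05)

    def test_cap_area(self, pipelined_cap):
        rec, truth = pipelined_cap.record, pipelined_cap.truth
        assert rec.area_nm2 == pytest.approx(truth.area_nm2, rel=0.05)
        assert rec.perimeter_nm == pytest.approx(truth.perimeter_nm, rel=0.05)
        assert rec.curvature == pytest.approx(truth.curvature, abs=0.02)

    def test_perforated_phantom_has_two_boundary_loops(self):
        spec = synthgen.PhantomSpec(
            shape_class="perforated", sphere_radius_nm=350.0,
            cap_angle_rad=0.6, n_perforations=1, perforation_radius_nm=50.0,
            orientation=(0.2, 0.3, 0.93))
        moved, sspec = synthgen.tight_stack_spec(spec, noise_sd=0.0, seed=8)
        stack, labels, _ = synthgen.render_stack([moved], sspec)
        blurred = gaussian_blur(stack, (7.4, 7.4, 20.0))
        segments = threshold_components(blurred)
        attach_ground_truth(segments, labels)
        mesh = extract_sas(segments[0], blurred)
        assert len(mesh.boundary_loops) == 2

    def test_truncated_segment_refused(self):
        seg = JunctionSegment(1, np.array([[0, 1, 1], [0, 1, 2]], dtype=np.int32),
                              (3.7, 3.7, 20.0), (4, 4, 4), True, 60.0, 50.0)
        stack = VoxelStack(np.zeros((4, 4, 4)), (3.7, 3.7, 20.0))
        with pytest.raises(TruncatedSegmentError):
            extract_sas(seg, stack)

    def test_tiny_segment_degenerate(self):
        seg = JunctionSegment(1, np.array([[1, 1, 1], [1, 1, 2]], dtype=np.int32),
                              (3.7, 3.7, 20.0), (4, 4, 4), False, 60.0, 50.0)
        stack = VoxelStack(np.zeros((4, 4, 4)), (3.7, 3.7, 20.0))
        with pytest.raises(DegenerateGeometryError):
            extract_sas(seg, stack)

    def test_medial_path_without_sublabels(self):
        # same phantom, no ground-truth labels attached: the thinning-based
        # medial sheet is coarser but must still land near the truth
        spec = make_cap_spec(80_000.0, 0.08, (0.1, 0.2, 0.97))
        moved, sspec = synthgen.tight_stack_spec(spec, noise_sd=0.0, seed=4)
        stack, _, _ = synthgen.render_stack([moved], sspec)
        blurred = gaussian_blur(stack, (7.4, 7.4, 20.0))
        segments = threshold_components(blurred)
        mesh = extract_sas(segments[0], blurred)
        truth = synthgen.analytic_truth(spec)
        assert mesh_area(mesh) == pytest.approx(truth.area_nm2, rel=0.15)


class TestShrinkage:
    def test_default_factors_are_mutually_consistent(self):
        f = ShrinkageFactors()
        assert f.linear ** 2 == pytest.approx(f.surface, abs=1e-12)
        assert f.linear ** 3 == pytest.approx(f.volume, abs=0.005)

    def test_area_and_length_scaled(self):
        rec = MorphoRecord(area_nm2=81.0, perimeter_nm=90.0,
                           projected_area_nm2=81.0, curvature=0.25,
                           feret_nm=90.0)
        out = shrinkage_correct(rec)
        assert out.area_nm2 == pytest.approx(100.0)
        assert out.perimeter_nm == pytest.approx(100.0)
        assert out.feret_nm == pytest.approx(100.0)
        assert out.curvature == pytest.approx(0.25)
        assert out.corrected

    def test_double_correction_refused(self):
        rec = MorphoRecord(area_nm2=81.0, perimeter_nm=90.0,
                           projected_area_nm2=81.0, curvature=0.25,
                           feret_nm=90.0)
        once = shrinkage_correct(rec)
        with pytest.raises(ValidationError):
            shrinkage_correct(once)


class TestPerimeterAreaScaling:
    def test_perimeter_scales_as_sqrt_area(self, cap60):
        # similar shapes: P ~ sqrt(A), the regression logic for outlines
        base_a = mesh_area(cap60)
        base_p = mesh_perimeter(cap60, simplify_tol_nm=0.0)
        for k in (0.5, 2.0, 3.0):
            scaled = SASMesh(vertices=k * cap60.vertices,
                             triangles=cap60.triangles)
            p_scaled = mesh_perimeter(scaled, simplify_tol_nm=0.0)
            assert p_scaled / base_p == pytest.approx(
                math.sqrt(mesh_area(scaled) / base_a), rel=1e-6)
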
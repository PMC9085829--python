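"""Anchor points, stepped profile, Feret calipers, and the scalar features."""

import math

import numpy as np
import pytest
import trimesh

from glomorph import meshing
from glomorph.morphometry import (
    AnchorPoints,
    compute_orientation,
    curve_length_L,
    extract_anchor_points,
    feret_diameters_2d,
    glomerulus_features,
    head_diameters,
    neck_diameter_nMax,
    stepped_profile,
)
from glomorph.types import SurfaceMesh
from conftest import to_surface_mesh


def _densify(tm: trimesh.Trimesh, max_edge: float = 2.5) -> trimesh.Trimesh:
    """Subdivide CAD primitives so every surface region carries vertices,
    as marching-cubes meshes do."""
    v, f = trimesh.remesh.subdivide_to_size(np.asarray(tm.vertices),
                                            np.asarray(tm.faces), max_edge)
    return trimesh.Trimesh(vertices=v, faces=f, process=False)


def capsule_mesh(radius=10.0, height=80.0) -> SurfaceMesh:
    """Capsule along the first (z) axis, centred at the origin."""
    tm = _densify(trimesh.creation.capsule(radius=radius, height=height, count=(32, 32)))
    # trimesh capsule runs along +z of its frame -> our axis 0 after flip
    return to_surface_mesh(tm)


def ellipsoid_mesh(axes=(40.0, 25.0, 15.0), subdivisions=4) -> SurfaceMesh:
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    tm.vertices = np.asarray(tm.vertices) * np.asarray(axes)[::-1]
    return to_surface_mesh(tm)


def dense_feret_oracle(points_2d: np.ndarray, n_angles: int = 3600):
    """Rotation-scan oracle for max/min caliper widths."""
    angles = np.linspace(0, math.pi, n_angles, endpoint=False)
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    proj = points_2d @ dirs.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.max()), float(widths.min())


class TestFeretCalipers:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_dense_rotation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(40, 2)) * rng.uniform(1, 8, size=2)
        dmax, dmin = feret_diameters_2d(pts)
        omax, omin = dense_feret_oracle(pts)
        # max Feret (max pairwise distance) >= directional-span maximum,
        # both converge as the angle grid refines
        assert dmax == pytest.approx(omax, rel=0.01)
        assert dmin == pytest.approx(omin, rel=0.01)

    def test_degenerate_sets(self):
        assert feret_diameters_2d(np.zeros((1, 2))) == (0.0, 0.0)
        two = np.array([[0.0, 0.0], [3.0, 4.0]])
        dmax, dmin = feret_diameters_2d(two)
        assert dmax == pytest.approx(5.0)
        assert dmin == pytest.approx(0.0)
        collinear = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        dmax, dmin = feret_diameters_2d(collinear)
        assert dmax == pytest.approx(2 * math.sqrt(2))
        assert dmin == pytest.approx(0.0, abs=1e-9)


class TestAnchorPoints:
    def test_open_capsule_base_and_tip(self):
        mesh = capsule_mesh(radius=10.0, height=80.0)
        # remove the bottom cap: open boundary where the neck was cut
        keep = ~(mesh.vertices[mesh.faces, 0] < -40.0).any(axis=1)
        open_mesh = SurfaceMesh(mesh.vertices, mesh.faces[keep])
        anchors = extract_anchor_points(open_mesh)
        assert anchors.central_base_point[0] == pytest.approx(-40.0, abs=1.5)
        assert np.allclose(anchors.central_base_point[1:], 0.0, atol=0.5)
        assert anchors.tip[0] == pytest.approx(50.0, abs=1.0)

    def test_sphere_with_south_pole_reference(self, icosphere_r10):
        anchors = extract_anchor_points(icosphere_r10, base_reference=(-10.0, 0.0, 0.0))
        assert anchors.tip[0] == pytest.approx(10.0, abs=0.5)

    def test_sphere_centroid_at_center(self, icosphere_r10):
        anchors = extract_anchor_points(icosphere_r10, base_reference=(-10.0, 0.0, 0.0))
        assert np.linalg.norm(anchors.centroid) < 1e-3 * 10.0

    def test_closed_mesh_without_reference_rejected(self, icosphere_r10):
        with pytest.raises(ValueError, match="reference"):
            extract_anchor_points(icosphere_r10)


class TestOrientation:
    def test_unit_vector_along_axis(self):
        a = AnchorPoints((0, 0, 0), (0, 0, 5), (0, 0, 9))
        assert np.allclose(compute_orientation(a), (0, 0, 1))

    def test_antisymmetry_and_normalization(self):
        rng = np.random.default_rng(2)
        p, q = rng.normal(size=3), rng.normal(size=3)
        a = AnchorPoints(p, q, q)
        b = AnchorPoints(q, p, p)
        assert np.allclose(compute_orientation(a), -compute_orientation(b))
        assert abs(np.linalg.norm(compute_orientation(a)) - 1.0) < 1e-9

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            compute_orientation(AnchorPoints((1, 1, 1), (1, 1, 1), (2, 2, 2)))


class TestSteppedProfile:
    def test_cylinder_cross_sections_circular(self):
        mesh = capsule_mesh(radius=10.0, height=80.0)
        anchors = AnchorPoints((-50.0, 0, 0), (0.0, 0, 0), (50.0, 0, 0))
        prof = stepped_profile(mesh, (1.0, 0, 0), anchors, step_height=5.0)
        interior = [s for s in prof.nonempty() if 15.0 < s.t_center < 85.0]
        assert interior
        for s in interior:
            assert s.max_diameter == pytest.approx(20.0, rel=0.03)
            assert s.min_diameter == pytest.approx(20.0, rel=0.03)

    def test_prolate_ellipsoid_thickest_step(self):
        mesh = ellipsoid_mesh(axes=(40.0, 25.0, 15.0))
        anchors = AnchorPoints((-40.0, 0, 0), (0.0, 0, 0), (40.0, 0, 0))
        prof = stepped_profile(mesh, (1.0, 0, 0), anchors, step_height=2.0)
        thickest = max(prof.nonempty(), key=lambda s: s.max_diameter)
        assert thickest.max_diameter == pytest.approx(50.0, rel=0.02)
        assert thickest.min_diameter == pytest.approx(30.0, rel=0.02)

    def test_single_step_degenerate_binning(self, icosphere_r10):
        anchors = AnchorPoints((-10.0, 0, 0), (0.0, 0, 0), (10.0, 0, 0))
        prof = stepped_profile(icosphere_r10, (1.0, 0, 0), anchors, step_height=100.0)
        assert len(prof.nonempty()) == 1
        assert prof.nonempty()[0].n_vertices == icosphere_r10.n_vertices


class TestCurveLength:
    def test_straight_capsule(self):
        mesh = capsule_mesh(radius=10.0, height=100.0)
        anchors = AnchorPoints((-60.0, 0, 0), (0.0, 0, 0), (60.0, 0, 0))
        prof = stepped_profile(mesh, (1.0, 0, 0), anchors, step_height=5.0)
        L = curve_length_L(prof)
        assert L == pytest.approx(120.0, abs=5.0)

    def test_circular_arc_matches_closed_form(self):
        # place step centres directly on a circular arc
        from glomorph.morphometry import ProfileStep, SteppedProfile

        R, theta = 50.0, math.pi / 2
        n = 200
        angs = np.linspace(0, theta, n)
        centers = np.stack([R * np.sin(angs), R * (1 - np.cos(angs)), np.zeros(n)], axis=1)
        steps = [ProfileStep(i, 10, c, float(c[0]), 1.0, 1.0) for i, c in enumerate(centers)]
        prof = SteppedProfile(1.0, np.zeros(3), np.array([1.0, 0, 0]), steps)
        assert curve_length_L(prof) == pytest.approx(R * theta, rel=0.01)

    def test_requires_two_steps(self):
        from glomorph.morphometry import ProfileStep, SteppedProfile

        prof = SteppedProfile(1.0, np.zeros(3), np.array([1.0, 0, 0]),
                              [ProfileStep(0, 5, np.zeros(3), 0.0, 1.0, 1.0)])
        with pytest.raises(ValueError):
            curve_length_L(prof)


def sphere_on_neck_mesh(head_r=20.0, neck_r=6.0, neck_len=30.0):
    """Analytic union mesh: capsule neck + icosphere head along +z axis."""
    head = trimesh.creation.icosphere(subdivisions=4, radius=head_r)
    head.vertices = np.asarray(head.vertices) + [0, 0, neck_len + head_r * 0.9]
    neck = _densify(trimesh.creation.cylinder(radius=neck_r, height=neck_len + head_r,
                                              sections=48))
    neck.vertices = np.asarray(neck.vertices) + [0, 0, (neck_len + head_r) / 2]
    blob = trimesh.util.concatenate([head, neck])
    return to_surface_mesh(blob)


class TestHeadAndNeckDiameters:
    def _profiled(self, mesh, base, centroid, tip, step=2.0):
        anchors = AnchorPoints(base, centroid, tip)
        orient = compute_orientation(anchors)
        prof = stepped_profile(mesh, orient, anchors, step)
        return prof, anchors, orient

    def test_sphere_head_diameters(self):
        mesh = sphere_on_neck_mesh(head_r=20.0, neck_r=6.0, neck_len=30.0)
        base = (0.0, 0.0, 0.0)
        centroid = (48.0 - 2.0, 0.0, 0.0)  # head centre minus a bit of neck mass
        tip = (68.0, 0.0, 0.0)
        # axis 0 of the flipped frame is trimesh z
        mesh_z = SurfaceMesh(mesh.vertices[:, ::-1][:, [2, 1, 0]], mesh.faces)
        prof, anchors, orient = self._profiled(mesh, base, centroid, tip)
        hmin, hmax = head_diameters(prof, anchors, orient)
        assert hmax == pytest.approx(40.0, rel=0.05)
        assert hmin == pytest.approx(40.0, rel=0.05)
        assert hmax >= hmin

    def test_cylindrical_neck_nmax(self):
        mesh = sphere_on_neck_mesh(head_r=20.0, neck_r=8.0, neck_len=30.0)
        prof, anchors, orient = self._profiled(mesh, (0, 0, 0), (46.0, 0, 0), (68.0, 0, 0))
        nmax = neck_diameter_nMax(prof, anchors, orient)
        assert nmax == pytest.approx(16.0, rel=0.05)
        _, hmax = head_diameters(prof, anchors, orient)
        assert nmax < hmax

    def test_conical_neck_widest_at_base(self):
        # truncated cone neck (diameter 20 at base -> 10 at head) + sphere head
        cone = _densify(trimesh.creation.cone(radius=10.0, height=60.0, sections=64))
        head = trimesh.creation.icosphere(subdivisions=4, radius=15.0)
        head.vertices = np.asarray(head.vertices) + [0, 0, 40.0]
        blob = to_surface_mesh(trimesh.util.concatenate([cone, head]))
        prof, anchors, orient = self._profiled(blob, (0, 0, 0), (38.0, 0, 0), (55.0, 0, 0))
        nmax = neck_diameter_nMax(prof, anchors, orient)
        assert nmax == pytest.approx(20.0, rel=0.06)


class TestGlomerulusFeatures:
    def test_identical_meshes_identical_records(self):
        mesh = sphere_on_neck_mesh()
        r1 = glomerulus_features(mesh, base_reference=(0, 0, 0), step_height=2.0)
        r2 = glomerulus_features(mesh.copy(), base_reference=(0, 0, 0), step_height=2.0)
        assert r1.to_dict() == r2.to_dict()

    def test_rigid_rotation_invariance_within_1pct(self):
        mesh = sphere_on_neck_mesh()
        rec = glomerulus_features(mesh, base_reference=(0, 0, 0), step_height=2.0)
        rng = np.random.default_rng(5)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ])
        rotated = SurfaceMesh(mesh.vertices @ R.T, mesh.faces)
        rec_r = glomerulus_features(rotated, base_reference=(0, 0, 0), step_height=2.0)
        for attr in ("volume_um3", "hmax_um", "hmin_um", "nmax_um", "L_um"):
            assert getattr(rec_r, attr) == pytest.approx(getattr(rec, attr), rel=0.01)

    def test_feature_invariants(self):
        rec = glomerulus_features(sphere_on_neck_mesh(), base_reference=(0, 0, 0),
                                  step_height=2.0)
        assert rec.hmax_um >= rec.hmin_um > 0
        assert rec.nmax_um > 0
        assert rec.L_um > 0
        assert abs(np.linalg.norm(rec.orientation) - 1) < 1e-9

    def test_stage_errors_carry_stage_name(self, icosphere_r10):
        with pytest.raises(RuntimeError, match="extract_anchor_points"):
            glomerulus_features(icosphere_r10, base_reference=None)
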
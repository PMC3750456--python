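"""Surface extraction, mirroring, and ROI-restricted rigid registration."""

import numpy as np
import pytest

from orbitqc.registration import (RegistrationParams, RoiSelector,
                                  estimate_midsagittal, extract_surface,
                                  icp_register, landmark_prealign, reflect_mesh)
from orbitqc.types import LandmarkSet, OrbitMask, Plane, RigidTransform, SurfaceMesh

from test_types import random_transform


class TestExtractSurface:
    def test_single_voxel_closed_cube(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = True
        mesh = extract_surface(OrbitMask(m, "right", (1.0, 1.0, 1.0), clipped=True))
        vol = mesh.signed_volume()
        # marching cubes turns an isolated cell into an octahedron through
        # the face midpoints: 1/6 mm^3 is the expected discretized volume
        assert 0.1 < vol < 1.5
        # closed surface: Euler characteristic of a sphere
        edges = {tuple(sorted(e)) for f in mesh.faces
                 for e in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0]))}
        assert mesh.n_vertices - len(edges) + mesh.n_faces == 2

    def test_voxelized_sphere_volume(self):
        r, s = 10.0, 0.5
        n = int(2 * (r + 2) / s)
        coords = (np.arange(n) - n / 2 + 0.5) * s
        X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij")
        m = X**2 + Y**2 + Z**2 <= r**2
        mesh = extract_surface(OrbitMask(m, "right", (s, s, s), clipped=True))
        assert mesh.signed_volume() == pytest.approx(4188.79, rel=0.02)

    def test_mesh_volume_close_to_voxel_volume(self, default_masks):
        from orbitqc.segmentation import compute_volume

        mask = default_masks["unaffected_left"]
        for sigma in (0.0, 1.0):
            mesh = extract_surface(mask, smooth_sigma_vox=sigma)
            assert mesh.signed_volume() / 1000.0 == pytest.approx(
                compute_volume(mask), rel=0.03)

    def test_phantom_mesh_watertight(self, mirror_setup):
        mesh = mirror_setup["target"]
        edges = {}
        for f in mesh.faces:
            for e in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                edges[tuple(sorted(e))] = edges.get(tuple(sorted(e)), 0) + 1
        assert set(edges.values()) == {2}  # every edge shared by two faces

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty"):
            extract_surface(OrbitMask(np.zeros((4, 4, 4), dtype=bool), "left",
                                      (1, 1, 1), clipped=True))


class TestMidsagittal:
    def test_exact_plane_through_x0_points(self):
        lms = LandmarkSet(midline=[[0, 0, 0], [0, 10, 0], [0, 0, 10]])
        plane = estimate_midsagittal(lms)
        assert np.allclose(np.abs(plane.normal), [1, 0, 0], atol=1e-12)

    def test_collinear_points_rejected(self):
        lms = LandmarkSet(midline=[[0, 0, 0], [0, 1, 0], [0, 2, 0]])
        with pytest.raises(ValueError, match="collinear"):
            estimate_midsagittal(lms)

    def test_normal_oriented_left_to_right(self):
        lms = LandmarkSet(midline=[[0.1, 0, 0], [0, 10, 0], [-0.1, 0, 10],
                                   [0, -20, 5]])
        assert estimate_midsagittal(lms).normal[0] > 0

    def test_noisy_midline_normal_within_one_degree(self):
        """Monte-Carlo: sigma = 0.2 mm landmark noise, 100 replicates."""
        rng = np.random.default_rng(12)
        base = np.array([[0, 5, 15], [0, -30, 18], [0, 5, -12], [0, -42, 2.0]],
                        dtype=float)
        angles = []
        for _ in range(100):
            pts = base + rng.normal(0, 0.2, size=base.shape)
            plane = estimate_midsagittal(LandmarkSet(midline=pts))
            angles.append(np.degrees(np.arccos(np.clip(abs(plane.normal[0]), 0, 1))))
        assert np.mean(angles) < 1.0

    def test_phantom_mirror_plane_matches_truth(self, default_phantom):
        truth = default_phantom["truth"]
        plane = estimate_midsagittal(truth.landmarks)
        assert np.allclose(plane.normal, truth.mirror_plane.normal, atol=1e-6)
        assert abs(truth.mirror_plane.signed_distance(plane.point)) < 1e-6


class TestReflectMesh:
    @pytest.fixture
    def mesh(self):
        import trimesh

        return SurfaceMesh.from_trimesh(trimesh.creation.icosphere(2, 5.0))

    def test_double_reflection_is_identity(self, mesh):
        plane = Plane([1, 0.3, -0.2], [2.0, 1.0, 0.0])
        back = reflect_mesh(reflect_mesh(mesh, plane), plane)
        assert np.allclose(back.vertices, mesh.vertices, atol=1e-9)
        assert np.array_equal(back.faces, mesh.faces)

    def test_vertex_on_plane_is_fixed(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        mesh = SurfaceMesh(verts, [[0, 1, 2]])
        out = reflect_mesh(mesh, Plane([1, 0, 0], [0, 0, 0]))
        assert np.allclose(out.vertices[0], [0, 0, 0])

    def test_signed_volume_preserved(self, mesh):
        plane = Plane([1, 0, 0], [10.0, 0, 0])
        assert reflect_mesh(mesh, plane).signed_volume() == pytest.approx(
            mesh.signed_volume())


class TestPrealign:
    def test_recovers_known_transform(self):
        t = random_transform(42)
        src = np.random.default_rng(0).normal(scale=20, size=(4, 3))
        fit = landmark_prealign(src, t.apply(src))
        assert np.allclose(fit.to_matrix(), t.to_matrix(), atol=1e-9)

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            landmark_prealign([[0, 0, 0], [1, 1, 1]], [[0, 0, 0], [1, 1, 1]])


class TestIcp:
    def test_self_registration_is_identity(self, mirror_setup):
        template = mirror_setup["template"]
        roi = RoiSelector(include=np.ones(template.n_vertices, dtype=bool))
        t, report = icp_register(template, roi, template)
        assert report["rms_mm"] < 1e-9
        assert t.rotation_angle_deg() < 1e-6
        assert np.linalg.norm(t.translation) < 1e-6

    def test_known_transform_recovery(self, mirror_setup):
        """A 5-degree / (2, 1, 0.5) mm perturbation is recovered tightly."""
        target = mirror_setup["target"]
        theta = np.radians(5.0)
        rz = np.array([[np.cos(theta), -np.sin(theta), 0],
                       [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        t0 = RigidTransform(rz, [2.0, 1.0, 0.5])
        moved = SurfaceMesh(t0.apply(target.vertices), target.faces)
        roi = RoiSelector(include=np.ones(target.n_vertices, dtype=bool))
        fit, report = icp_register(target, roi,  moved,
                                   RegistrationParams(max_iterations=200))
        err = fit.inverse() @ t0
        assert err.rotation_angle_deg() < 0.05
        assert np.linalg.norm(err.translation) < 0.01
        assert report["rms_mm"] < 0.05

    def test_rigidity_preserves_pairwise_distances(self, mirror_setup):
        template = mirror_setup["template"]
        roi = mirror_setup["roi"]
        t, _ = icp_register(template, roi, mirror_setup["target"])
        pts = template.vertices[::500]
        moved = t.apply(pts)
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d1 = np.linalg.norm(moved[:, None] - moved[None, :], axis=-1)
        assert np.allclose(d0, d1, atol=1e-9)

    def test_deterministic(self, mirror_setup):
        args = (mirror_setup["template"], mirror_setup["roi"],
                mirror_setup["target"])
        t1, r1 = icp_register(*args)
        t2, r2 = icp_register(*args)
        assert np.array_equal(t1.to_matrix(), t2.to_matrix())
        assert r1 == r2

    def test_roi_excludes_reconstructed_wall(self, mirror_setup):
        labels = mirror_setup["labeling"].labels
        roi = mirror_setup["roi"]
        floor = np.char.startswith(labels.astype(str), "floor_")
        assert not np.any(roi.include & floor)
        assert roi.include.sum() >= 100

    def test_tiny_roi_rejected(self):
        with pytest.raises(ValueError, match="ROI"):
            RoiSelector(include=np.zeros(500, dtype=bool))


class TestRoiExclusionEffect:
    def test_floor_deviation_not_absorbed(self, mirror_setup):
        """Registering without the deformed floor keeps the injected
        deviation visible; this is the reason the matching ROI is
        restricted to unaffected bone."""
        from orbitqc.deviation import signed_distance

        template = mirror_setup["template"]
        target = mirror_setup["target"]
        truth = mirror_setup["truth"]
        t, report = icp_register(template, mirror_setup["roi"], target)
        assert report["rms_mm"] < 0.05  # unaffected bone aligns tightly
        moved = SurfaceMesh(t.apply(template.vertices), template.faces)
        dev = signed_distance(moved, target)
        floor = np.char.startswith(mirror_setup["labeling"].labels.astype(str),
                                   "floor_")
        peak = np.nanmax(dev.values[floor])
        amp = truth.residual_amplitude_mm
        assert abs(peak - amp) <= 0.1 * amp
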
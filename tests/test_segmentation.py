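"""Cavity segmentation, anterior clipping and voxel-count volumetry."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from orbitqc.segmentation import (LeakError, SegmentationError, SegmentationParams,
                                  anterior_clip_plane, clip_anterior, compute_volume,
                                  per_slice_profile, seed_from_landmarks,
                                  segment_cavity, threshold_bone)
from orbitqc.types import OrbitMask, Plane, VolumeImage

from conftest import segment_side


def brute_force_volume_ml(mask: OrbitMask) -> float:
    """Independent oracle: explicit loop over every voxel."""
    count = 0
    m = mask.mask
    for i in range(m.shape[0]):
        for j in range(m.shape[1]):
            for k in range(m.shape[2]):
                if m[i, j, k]:
                    count += 1
    sx, sy, sz = mask.spacing
    cell_mm3 = sx * sy * sz
    return count * cell_mm3 / 1000.0


def random_mask(seed, shape=(12, 11, 10), spacing=(0.5, 0.5, 0.5)):
    rng = np.random.default_rng(seed)
    return OrbitMask(mask=rng.random(shape) < 0.4, side="right",
                     spacing=spacing, origin=(0, 0, 0), clipped=True)


class TestComputeVolume:
    @given(st.integers(0, 1000))
    def test_matches_brute_force_exactly(self, seed):
        mask = random_mask(seed)
        assert compute_volume(mask) == brute_force_volume_ml(mask)

    def test_8000_half_mm_voxels_is_one_ml(self):
        m = np.zeros((25, 25, 25), dtype=bool)
        m[:20, :20, :20] = True
        mask = OrbitMask(m, "right", (0.5, 0.5, 0.5), clipped=True)
        assert compute_volume(mask) == 1.0

    def test_empty_mask_is_zero(self):
        mask = OrbitMask(np.zeros((4, 4, 4), dtype=bool), "left",
                         (0.5, 0.5, 0.5), clipped=True)
        assert compute_volume(mask) == 0.0

    def test_requires_clipped_mask(self):
        mask = OrbitMask(np.ones((4, 4, 4), dtype=bool), "left",
                         (0.5, 0.5, 0.5), clipped=False)
        with pytest.raises(ValueError, match="clip"):
            compute_volume(mask)


class TestThresholdBone:
    def test_exact_on_noiseless_phantom(self, noiseless_phantom):
        vol = noiseless_phantom["unaffected"]
        mask = threshold_bone(vol, SegmentationParams(bone_threshold=300))
        # noiseless phantom: mask is exactly the voxels at bone intensity
        assert np.array_equal(mask, vol.data >= 300)
        assert set(np.unique(vol.data[mask])) == {1200.0}

    def test_uniform_zero_volume_errors(self):
        vol = VolumeImage(np.zeros((4, 4, 4)), (0.5, 0.5, 0.5))
        with pytest.raises(SegmentationError, match="no bone"):
            threshold_bone(vol, SegmentationParams(bone_threshold=300))

    def test_threshold_below_minimum_saturates(self):
        vol = VolumeImage(np.full((4, 4, 4), 100.0), (0.5, 0.5, 0.5))
        mask = threshold_bone(vol, SegmentationParams(bone_threshold=-1e6))
        assert mask.all()


class TestSegmentCavity:
    def test_intact_volume_within_two_percent_of_truth(self, default_phantom):
        truth = default_phantom["truth"]
        mask = segment_side(default_phantom["unaffected"], truth, "right")
        measured = compute_volume(mask)
        expected = truth.volumes_ml["unaffected_right"]
        assert measured == pytest.approx(expected, rel=0.02)

    def test_fracture_leaks_without_closing(self, default_phantom):
        truth = default_phantom["truth"]
        vol = default_phantom["affected"]
        params = SegmentationParams(cavity_seed=truth.seeds["right"],
                                    closing_radius_mm=0.0)
        bone = threshold_bone(vol, params)
        with pytest.raises(LeakError, match="closing_radius_mm"):
            segment_cavity(vol, bone, params, "right")

    def test_closing_bridges_the_gap_and_volume_grows(self, default_phantom):
        truth = default_phantom["truth"]
        gap = default_phantom["spec"].fracture.defect_gap_mm
        m_aff = segment_side(default_phantom["affected"], truth, "right",
                             closing_mm=gap)
        m_una = segment_side(default_phantom["affected"], truth, "left",
                             closing_mm=gap)
        assert compute_volume(m_aff) >= compute_volume(m_una)

    def test_seed_inside_bone_rejected(self, noiseless_phantom):
        vol = noiseless_phantom["unaffected"]
        params = SegmentationParams(cavity_seed=(0, 0, 0))
        bone = threshold_bone(vol, params)
        # craft a seed on a bone voxel
        idx = tuple(np.argwhere(bone)[0])
        with pytest.raises(SegmentationError, match="bone"):
            segment_cavity(vol, bone, SegmentationParams(cavity_seed=idx), "right")

    def test_seed_from_landmarks_lands_in_cavity(self, default_phantom):
        truth = default_phantom["truth"]
        vol = default_phantom["unaffected"]
        seed = seed_from_landmarks(vol, truth.landmarks, "right")
        assert truth.cavity_masks["right"][seed]


class TestAnteriorClip:
    def test_axis_aligned_plane(self):
        plane = anterior_clip_plane([30.0, 40.0, 0.0], [-2.0, 40.0, 0.0])
        assert np.allclose(plane.normal, [0, 1, 0])
        assert plane.signed_distance([0, 40.0, 0]) == pytest.approx(0.0)

    def test_oblique_plane_contains_both_rim_points(self):
        L = np.array([30.0, 42.0, 1.0])
        M = np.array([-2.0, 38.0, -1.0])
        plane = anterior_clip_plane(L, M)
        assert abs(plane.signed_distance(L)) < 1e-9
        assert abs(plane.signed_distance(M)) < 1e-9

    def test_degenerate_axial_direction(self):
        with pytest.raises(ValueError, match="parallel"):
            anterior_clip_plane([0, 0, 0], [0, 0, 5.0], axial_direction=(0, 0, 1))

    def test_phantom_rim_plane_matches_truth(self, default_phantom):
        truth = default_phantom["truth"]
        pts = truth.landmarks.sides["right"]
        plane = anterior_clip_plane(pts["L"], pts["M"])
        tp = truth.rim_planes["right"]
        assert np.allclose(plane.normal, tp.normal, atol=1e-6)
        assert abs(tp.signed_distance(plane.point)) < 1e-6

    def test_halfspace_clip_is_exact(self):
        m = np.ones((10, 10, 4), dtype=bool)
        mask = OrbitMask(m, "right", (1.0, 1.0, 1.0), origin=(0.0, 35.5, 0.0))
        plane = Plane([0, 1, 0], [0, 40.0, 0])
        clipped = clip_anterior(mask, plane)
        idx = np.argwhere(m)
        centers_y = 35.5 + idx[:, 1] * 1.0
        expected = (centers_y < 40.0).sum()
        assert clipped.voxel_count == expected

    def test_mask_fully_posterior_unchanged(self):
        m = np.ones((4, 4, 4), dtype=bool)
        mask = OrbitMask(m, "left", (1.0, 1.0, 1.0), origin=(0, -10.0, 0))
        clipped = clip_anterior(mask, Plane([0, 1, 0], [0, 0, 0]))
        assert clipped.voxel_count == mask.voxel_count
        assert clipped.clipped

    def test_clip_never_increases_volume(self, default_phantom):
        truth = default_phantom["truth"]
        vol = default_phantom["unaffected"]
        params = SegmentationParams(cavity_seed=truth.seeds["left"])
        raw = segment_cavity(vol, threshold_bone(vol, params), params, "left")
        pts = truth.landmarks.sides["left"]
        clipped = clip_anterior(raw, anterior_clip_plane(pts["L"], pts["M"]))
        assert clipped.voxel_count <= raw.voxel_count

    def test_clip_that_empties_mask_errors(self):
        m = np.ones((4, 4, 4), dtype=bool)
        mask = OrbitMask(m, "left", (1.0, 1.0, 1.0), origin=(0, 10.0, 0))
        with pytest.raises(SegmentationError, match="entire"):
            clip_anterior(mask, Plane([0, 1, 0], [0, 0, 0]))


class TestPerSliceProfile:
    @given(st.integers(0, 500))
    def test_partition_identity(self, seed):
        mask = random_mask(seed)
        profile = per_slice_profile(mask)
        assert profile["subvolume_ml"].sum() == pytest.approx(
            compute_volume(mask), abs=1e-12)

    def test_single_slice(self):
        m = np.zeros((6, 6, 5), dtype=bool)
        m[1:4, 2:5, 2] = True
        mask = OrbitMask(m, "right", (0.5, 0.5, 0.5), clipped=True)
        profile = per_slice_profile(mask)
        assert len(profile) == 1
        assert profile["area_mm2"].iloc[0] == 9 * 0.25

    def test_phantom_profile_rises_then_falls(self, default_masks):
        profile = per_slice_profile(default_masks["unaffected_left"])
        area = profile["area_mm2"].to_numpy()
        peak = int(np.argmax(area))
        # convex cavity: monotone up to the peak, then monotone down
        assert np.all(np.diff(area[: peak + 1]) >= 0)
        assert np.all(np.diff(area[peak:]) <= 0)


class TestScaleConsistency:
    def test_halved_spacing_changes_volume_below_one_percent(self):
        from orbitqc.phantom import PhantomSpec, generate_phantom

        vols = {}
        for spacing in (1.0, 0.5):
            spec = PhantomSpec(spacing=spacing, fracture=None,
                               reconstruction=None, seed=5)
            una, _, _, truth = generate_phantom(spec)
            mask = segment_side(una, truth, "right")
            vols[spacing] = compute_volume(mask)
        assert abs(vols[0.5] - vols[1.0]) / vols[0.5] < 0.01
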
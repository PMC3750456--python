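"""Shared fixtures: session-scoped phantoms and derived segmentations.

Phantom rasterization and segmentation are the expensive steps, so the
suite builds each phantom once and shares masks/meshes across tests. All
randomness is seeded; hypothesis runs derandomized.
"""

import pytest
from hypothesis import HealthCheck, settings

from orbitqc.phantom import ModalityProfile, PhantomSpec, generate_phantom
from orbitqc.registration import (RoiSelector, estimate_midsagittal,
                                  extract_surface, reflect_mesh)
from orbitqc.regions import label_regions
from orbitqc.segmentation import (SegmentationParams, anterior_clip_plane,
                                  clip_anterior, segment_cavity, threshold_bone)

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def segment_side(volume, truth, side, threshold=300.0, closing_mm=1.0):
    """Segment + clip one cavity using phantom truth seeds/landmarks."""
    params = SegmentationParams(bone_threshold=threshold,
                                cavity_seed=truth.seeds[side],
                                closing_radius_mm=closing_mm)
    mask = segment_cavity(volume, threshold_bone(volume, params), params, side)
    pts = truth.landmarks.sides[side]
    return clip_anterior(mask, anterior_clip_plane(pts["L"], pts["M"]))


@pytest.fixture(scope="session")
def default_phantom():
    """Default study conditions: 0.5 mm voxels, CT/CBCT noise, 3.4 ml
    posterior-ledge enlargement, 1.5 mm anterior-floor residual, implant."""
    spec = PhantomSpec(seed=11)
    una, aff, rec, truth = generate_phantom(spec)
    return {"spec": spec, "unaffected": una, "affected": aff,
            "reconstructed": rec, "truth": truth}


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Same geometry without imaging noise (for registration accuracy)."""
    spec = PhantomSpec(
        seed=7,
        modality_preop=ModalityProfile("CT", 1.0, 0.0),
        modality_postop=ModalityProfile("CBCT", 0.6, 0.0),
    )
    una, aff, rec, truth = generate_phantom(spec)
    return {"spec": spec, "unaffected": una, "affected": aff,
            "reconstructed": rec, "truth": truth}


@pytest.fixture(scope="session")
def default_masks(default_phantom):
    ph = default_phantom
    return {
        "unaffected_left": segment_side(ph["affected"], ph["truth"], "left"),
        "affected_right": segment_side(ph["affected"], ph["truth"], "right"),
        "reconstructed_right": segment_side(ph["reconstructed"], ph["truth"],
                                            "right", threshold=180.0),
        "unaffected_left_post": segment_side(ph["reconstructed"], ph["truth"],
                                             "left", threshold=180.0),
    }


@pytest.fixture(scope="session")
def mirror_setup(noiseless_phantom):
    """Mirrored template + reconstructed target + labeling + ROI.

    Template and target both come from the noiseless post-operative
    volume, so their only true difference is the injected residual floor
    deviation.
    """
    ph = noiseless_phantom
    truth = ph["truth"]
    m_left = segment_side(ph["reconstructed"], truth, "left", threshold=180.0)
    m_right = segment_side(ph["reconstructed"], truth, "right", threshold=180.0)
    plane = estimate_midsagittal(truth.landmarks)
    template = reflect_mesh(extract_surface(m_left, smooth_sigma_vox=1.0), plane)
    target = extract_surface(m_right, smooth_sigma_vox=1.0)
    labeling = label_regions(template, truth.landmarks, plane, "right")
    roi = RoiSelector.from_labels(labeling.labels, exclude_walls=("floor",))
    return {"template": template, "target": target, "labeling": labeling,
            "roi": roi, "plane": plane, "truth": truth,
            "mask_left": m_left, "mask_right": m_right}


@pytest.fixture(scope="session")
def case_run(default_phantom, tmp_path_factory):
    """One full pipeline run on the default phantom, shared by tests."""
    from orbitqc import io as qio
    from orbitqc.pipeline import PipelineConfig, run_case

    ph = default_phantom
    root = tmp_path_factory.mktemp("case")
    qio.write_volume(ph["affected"], root / "preop.nii.gz")
    qio.write_volume(ph["reconstructed"], root / "postop.nii.gz")
    qio.write_landmarks(ph["truth"].landmarks, root / "landmarks.json")
    cfg = PipelineConfig(
        preop_volume=str(root / "preop.nii.gz"),
        postop_volume=str(root / "postop.nii.gz"),
        landmarks=str(root / "landmarks.json"),
        output_dir=str(root / "out"),
        case_id="phantom_case",
        affected_side="right",
    )
    report = run_case(cfg)
    return {"config": cfg, "report": report, "out": root / "out",
            "root": root, "truth": ph["truth"]}
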